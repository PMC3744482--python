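"""Windowed dynamic complexity of short bounded time series.

Dynamic complexity flags critical instability in daily process data.  For a
window of m consecutive values on a scale with theoretical range R it is the
product of two unitless fractions:

* **Fluctuation intensity F** — amplitude and frequency of direction
  changes.  The window is segmented into maximal monotone runs delimited by
  strict direction reversals; a run with amplitude ``a_k = |x_end - x_start|``
  and duration ``d_k`` steps contributes ``a_k / d_k``, and
  ``F = sum_k (a_k / d_k) / (R * (m - 1))``.  A constant window has F = 0; a
  full-range zig-zag saturates F = 1.

* **Distribution degree D** — evenness of coverage of the theoretical
  range.  With the window sorted ascending as ``y_1..y_m``, every span of
  width ``c`` is compared with its ideal width under perfectly even coverage
  ``I_c = c * R / (m - 1)``; shortfalls accumulate as
  ``D = 1 - sum max(0, I_c - (y_b - y_a)) / sum I_c``.  Identical values give
  D = 0; a perfectly even full-range spread gives D = 1.

``C = F * D`` is computed per item on a right-aligned moving window
(default 7 days) and averaged across items; maxima of the averaged curve
mark candidate order transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import RatingScale, RatingSeries

__all__ = [
    "ComplexityMatrix",
    "fluctuation_intensity",
    "distribution_degree",
    "dynamic_complexity",
    "complexity_series",
    "mean_complexity",
]

DEFAULT_WINDOW = 7


def _check_window(window: np.ndarray, scale: RatingScale) -> np.ndarray:
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or len(window) < 2:
        raise ValueError("window must be 1-d with at least 2 values")
    if np.isnan(window).any():
        return window  # caller propagates missing
    if np.any((window < scale.min_value) | (window > scale.max_value)):
        raise ValueError("window value outside declared scale")
    return window


def fluctuation_intensity(window, scale: RatingScale) -> float:
    """Fluctuation intensity F of one window; NaN if the window has missing values.

    Plateaus (equal consecutive values) extend the current monotone run; a
    run ends only at a strict direction reversal, with the turning point at
    the last extremal value, so F is 0 for constant windows and continuous
    in the data.
    """
    x = _check_window(window, scale)
    if np.isnan(x).any():
        return float("nan")
    m = len(x)
    diffs = np.diff(x)
    signs = np.sign(diffs)
    total = 0.0
    run_start = 0
    direction = 0.0
    for i, s in enumerate(signs):
        if s == 0:
            continue
        if direction == 0:
            direction = s
        elif s != direction:
            # strict reversal: close the run at the last extremal value
            turn = i  # index of last value before this opposing step
            a = abs(x[turn] - x[run_start])
            d = turn - run_start
            if d > 0:
                total += a / d
            run_start = turn
            direction = s
    # close the final run at the window end
    if direction != 0:
        a = abs(x[m - 1] - x[run_start])
        d = (m - 1) - run_start
        if d > 0:
            total += a / d
    return total / (scale.range * (m - 1))


def distribution_degree(window, scale: RatingScale, *, spans: str = "all") -> float:
    """Distribution degree D of one window; NaN if the window has missing values.

    ``spans="all"`` (default) compares every sorted span (y_b - y_a) for all
    widths c = b - a against the ideal c*R/(m-1); ``spans="adjacent"``
    restricts to neighbouring sorted values (c = 1).  Only shortfalls
    (under-dispersion) count, so D = 1 exactly for an even full-range spread
    and D = 0 when all values coincide.
    """
    y = _check_window(window, scale)
    if np.isnan(y).any():
        return float("nan")
    m = len(y)
    y = np.sort(y)
    R = scale.range
    unit = R / (m - 1)
    dev_sum = 0.0
    ideal_sum = 0.0
    widths = range(1, 2) if spans == "adjacent" else range(1, m)
    if spans not in ("all", "adjacent"):
        raise ValueError(f"unknown spans variant {spans!r}")
    for c in widths:
        ideal = c * unit
        actual = y[c:] - y[: m - c]
        dev_sum += np.maximum(0.0, ideal - actual).sum()
        ideal_sum += ideal * len(actual)
    return 1.0 - dev_sum / ideal_sum


def dynamic_complexity(window, scale: RatingScale, *, spans: str = "all") -> float:
    """Composite complexity C = F * D for one window (NaN-propagating)."""
    f = fluctuation_intensity(window, scale)
    if np.isnan(f):
        return float("nan")
    return f * distribution_degree(window, scale, spans=spans)


@dataclass
class ComplexityMatrix:
    """Day × item complexity values plus the item-averaged curve.

    The value at day t derives from the right-aligned window
    [t - m + 1, t]; the first m - 1 days are NaN, as is any day whose
    window contains missing ratings.
    """

    subject_id: str
    window_width: int
    items: list[str]
    day_index: np.ndarray
    values: np.ndarray  # (n_days, n_items), NaN where undefined

    @property
    def mean_curve(self) -> np.ndarray:
        return mean_complexity(self)


def complexity_series(
    series: RatingSeries,
    window_width: int = DEFAULT_WINDOW,
    *,
    spans: str = "all",
) -> ComplexityMatrix:
    """Moving-window complexity for every item of a rating series.

    The window is right-aligned: the value stamped on day t summarises the
    m days ending at t, so a complexity peak precedes or coincides with the
    pattern change it signals.
    """
    m = int(window_width)
    if m < 2:
        raise ValueError("window_width must be >= 2")
    if series.n_days < m:
        raise ValueError(
            f"series of {series.n_days} days shorter than window {m}"
        )
    n_days, n_items = series.values.shape
    out = np.full((n_days, n_items), np.nan)
    for j, item in enumerate(series.items):
        scale = series.scales[item]
        col = series.values[:, j]
        for t in range(m - 1, n_days):
            w = col[t - m + 1 : t + 1]
            if np.isnan(w).any():
                continue
            out[t, j] = dynamic_complexity(w, scale, spans=spans)
    return ComplexityMatrix(
        subject_id=series.subject_id,
        window_width=m,
        items=list(series.items),
        day_index=series.day_index.copy(),
        values=out,
    )


def mean_complexity(matrix: ComplexityMatrix) -> np.ndarray:
    """Unweighted per-day mean of C across items, skipping missing items.

    Items are commensurable without reweighting because C is already
    range-normalised per item.  A day where every item is missing stays NaN.
    """
    if matrix.values.shape[1] < 1:
        raise ValueError("need at least one item")
    vals = matrix.values
    with np.errstate(invalid="ignore"):
        counts = (~np.isnan(vals)).sum(axis=1)
        sums = np.nansum(vals, axis=1)
    curve = np.full(len(vals), np.nan)
    ok = counts > 0
    curve[ok] = sums[ok] / counts[ok]
    return curve
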