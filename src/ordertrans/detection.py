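"""Order-transition detection and inter-scan interval labelling.

An order transition — a discontinuous qualitative change of the client's
pattern — is operationalised as a maximum of the item-averaged dynamic
complexity curve: critical fluctuations precede self-organised pattern
change, so peak complexity marks the transition period.  The global maximum
is always a transition; further local maxima qualify if high enough
relative to the global peak and sufficiently separated in time.

Detected transitions then label the intervals between repeated fMRI scans:
patient intervals containing a transition are OT, the rest NOT; control
intervals (no treatment, no diary) are all ISI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .timeseries import ScanSchedule

__all__ = [
    "TransitionSet",
    "IntervalLabel",
    "DetectionConfig",
    "detect_transitions",
    "label_intervals",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    """Secondary-maximum acceptance rule.

    A local maximum beyond the global one is accepted when its height is at
    least ``secondary_fraction`` of the global peak and it lies at least
    ``min_separation`` days from every already-accepted transition;
    candidates are considered in decreasing peak order.
    """

    secondary_fraction: float = 0.9
    min_separation: int = 14


@dataclass
class TransitionSet:
    subject_id: str
    transitions: list[tuple[int, float]] = field(default_factory=list)
    # (day index, peak mean-complexity value), ordered by day

    @property
    def days(self) -> list[int]:
        return [d for d, _ in self.transitions]


def _local_maxima(days: np.ndarray, vals: np.ndarray) -> list[tuple[int, float]]:
    """Indices of local maxima among non-missing points; plateaus collapse
    to their earliest day."""
    peaks = []
    n = len(vals)
    i = 0
    while i < n:
        # extent of the plateau starting at i
        j = i
        while j + 1 < n and vals[j + 1] == vals[i]:
            j += 1
        left_ok = i == 0 or vals[i - 1] < vals[i]
        right_ok = j == n - 1 or vals[j + 1] < vals[i]
        if left_ok and right_ok:
            peaks.append((int(days[i]), float(vals[i])))
        i = j + 1
    return peaks


def detect_transitions(
    mean_curve: np.ndarray,
    day_index: np.ndarray | None = None,
    config: DetectionConfig = DetectionConfig(),
    *,
    subject_id: str = "",
) -> TransitionSet:
    """Detect order transitions on an item-averaged complexity curve.

    The curve may contain NaN (days before the first full window or with
    missing ratings); detection runs on the non-missing support.  The global
    maximum day is always a transition, ties breaking to the earliest day —
    earlier instability is the theoretically meaningful event.
    """
    curve = np.asarray(mean_curve, dtype=float)
    if day_index is None:
        day_index = np.arange(1, len(curve) + 1)
    day_index = np.asarray(day_index, dtype=int)
    ok = ~np.isnan(curve)
    if not ok.any():
        raise ValueError("all-missing complexity curve: nothing to detect")
    days, vals = day_index[ok], curve[ok]

    g_idx = int(np.argmax(vals))  # argmax returns the earliest tie
    g_day, g_val = int(days[g_idx]), float(vals[g_idx])

    accepted = [(g_day, g_val)]
    candidates = [
        (d, v) for d, v in _local_maxima(days, vals) if d != g_day
    ]
    # decreasing peak order; earliest day breaks ties
    for d, v in sorted(candidates, key=lambda t: (-t[1], t[0])):
        if v < config.secondary_fraction * g_val:
            continue
        if all(abs(d - ad) >= config.min_separation for ad, _ in accepted):
            accepted.append((d, v))
    accepted.sort()
    return TransitionSet(subject_id=subject_id, transitions=accepted)


@dataclass(frozen=True)
class IntervalLabel:
    """Label of the interval between scan k and scan k+1 (1-based k)."""

    subject_id: str
    interval: int
    label: str  # "OT" | "NOT" | "ISI"
    transition_day: int | None = None


def _interval_for_day(scan_days: tuple[int, ...], t: int) -> int:
    """Half-open assignment (scan_k, scan_{k+1}]; out-of-range days snap to
    the nearest interval ("shortly before or after" a scan)."""
    if t <= scan_days[0]:
        return 1
    for k in range(len(scan_days) - 1):
        if scan_days[k] < t <= scan_days[k + 1]:
            return k + 1
    return len(scan_days) - 1


def label_intervals(
    schedule: ScanSchedule, transitions: TransitionSet | None
) -> list[IntervalLabel]:
    """Map detected transitions onto inter-scan intervals.

    Controls get ISI for every interval.  For patients, each transition day
    labels one interval OT; two transitions falling in the same interval
    collapse to a single OT (the earlier day is kept) with a warning.
    """
    sid = schedule.subject_id
    if schedule.group == "control":
        return [
            IntervalLabel(sid, k + 1, "ISI") for k in range(schedule.n_intervals)
        ]
    if schedule.n_intervals < 1:
        raise ValueError("patient schedule needs at least 2 scans")

    ot_day: dict[int, int] = {}
    if transitions is not None:
        for t, _ in transitions.transitions:
            k = _interval_for_day(schedule.scan_days, t)
            if k in ot_day:
                warnings.warn(
                    f"subject {sid!r}: transitions on days {ot_day[k]} and {t} "
                    f"both fall in interval {k}; collapsing to one OT",
                    stacklevel=2,
                )
            else:
                ot_day[k] = t
    return [
        IntervalLabel(sid, k, "OT", ot_day[k]) if k in ot_day
        else IntervalLabel(sid, k, "NOT")
        for k in range(1, schedule.n_intervals + 1)
    ]
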