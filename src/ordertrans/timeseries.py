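"""Data model and I/O for daily process ratings and scan schedules.

Daily self-ratings (e.g. Therapy Process Questionnaire items on 7-point
Likert or visual-analogue scales) arrive as long-format delimited text with
one row per (subject, day, item, value).  Each item carries a declared
theoretical scale range; the range — not the empirically realised range —
is what the downstream complexity measures normalise against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RatingScale",
    "RatingSeries",
    "ScanSchedule",
    "GapReport",
    "load_ratings",
    "load_scales",
    "load_schedules",
    "write_ratings",
    "prepare_series",
]


@dataclass(frozen=True)
class RatingScale:
    """Theoretical range of a rating item.

    The range ``R = max_value - min_value`` is the normaliser for the
    fluctuation and distribution measures; values outside the range are
    invalid by definition of the instrument.
    """

    min_value: float
    max_value: float
    discrete: bool = True  # Likert grid vs continuous visual-analogue

    def __post_init__(self) -> None:
        if not np.isfinite(self.min_value) or not np.isfinite(self.max_value):
            raise ValueError("scale bounds must be finite")
        if self.max_value <= self.min_value:
            raise ValueError(
                f"max_value ({self.max_value}) must exceed min_value ({self.min_value})"
            )

    @property
    def range(self) -> float:
        return self.max_value - self.min_value

    def contains(self, value: float) -> bool:
        return self.min_value <= value <= self.max_value


@dataclass
class RatingSeries:
    """One subject's day-by-item grid of bounded ratings.

    ``values`` is a (n_days, n_items) float array with NaN marking missing
    ratings.  ``day_index`` is 1-based and consecutive: the analysis assumes
    equally spaced daily observations, so absent days appear as NaN rows
    rather than being dropped.
    """

    subject_id: str
    items: list[str]
    scales: dict[str, RatingScale]
    values: np.ndarray
    day_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d day × item grid")
        n_days, n_items = self.values.shape
        if n_items != len(self.items):
            raise ValueError("item list does not match value columns")
        if n_days < 1:
            raise ValueError("series needs at least one day")
        if self.day_index is None:
            self.day_index = np.arange(1, n_days + 1)
        self.day_index = np.asarray(self.day_index, dtype=int)
        if len(self.day_index) != n_days:
            raise ValueError("day_index length does not match value rows")
        if np.any(np.diff(self.day_index) <= 0):
            raise ValueError("day_index must be strictly increasing")
        missing_scale = [it for it in self.items if it not in self.scales]
        if missing_scale:
            raise ValueError(f"no scale declared for items: {missing_scale}")
        for j, item in enumerate(self.items):
            col = self.values[:, j]
            sc = self.scales[item]
            bad = ~np.isnan(col) & ((col < sc.min_value) | (col > sc.max_value))
            if np.any(bad):
                day = int(self.day_index[np.argmax(bad)])
                raise ValueError(
                    f"value out of scale for subject {self.subject_id!r}, "
                    f"day {day}, item {item!r}"
                )

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    def item_values(self, item: str) -> np.ndarray:
        return self.values[:, self.items.index(item)]


@dataclass(frozen=True)
class ScanSchedule:
    """Ordered scan days for one subject (2-4 repeated measurements)."""

    subject_id: str
    scan_days: tuple[int, ...]
    group: str  # "patient" | "control"

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        if not 2 <= len(self.scan_days) <= 4:
            raise ValueError("2-4 scans required")
        if any(b <= a for a, b in zip(self.scan_days, self.scan_days[1:])):
            raise ValueError("scan_days must be strictly increasing")

    @property
    def n_intervals(self) -> int:
        return len(self.scan_days) - 1


@dataclass
class GapReport:
    """Missing-data runs that prepare_series left untreated."""

    subject_id: str
    untreated: list[dict] = field(default_factory=list)

    def add(self, item: str, start_day: int, length: int) -> None:
        self.untreated.append(
            {"item": item, "start_day": start_day, "length": length}
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"subject_id": self.subject_id, "untreated": self.untreated},
                indent=2,
            )
        )


def load_scales(path: str | Path) -> dict[str, RatingScale]:
    """Read per-item scale bounds from a YAML/JSON sidecar.

    Expected layout: ``{item: {min: ..., max: ..., discrete: bool}}`` or the
    shorthand ``{item: [min, max]}``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ValueError("scales file must map item ids to bounds")
    scales = {}
    for item, entry in raw.items():
        if isinstance(entry, Mapping):
            scales[str(item)] = RatingScale(
                float(entry["min"]), float(entry["max"]),
                bool(entry.get("discrete", True)),
            )
        else:
            lo, hi = entry
            scales[str(item)] = RatingScale(float(lo), float(hi))
    return scales


_REQUIRED_COLUMNS = ("subject", "day", "item", "value")


def load_ratings(
    path: str | Path,
    scales: Mapping[str, RatingScale],
    *,
    delimiter: str = ",",
    columns: Mapping[str, str] | None = None,
) -> dict[str, RatingSeries]:
    """Read long-format ratings into one :class:`RatingSeries` per subject.

    Parameters
    ----------
    path
        Delimited text with columns subject, day, item, value (rename via
        ``columns``, mapping canonical name -> file column).
    scales
        Declared scale per item id; every item in the file must be covered.

    Rows are grouped by subject, pivoted to a day × item grid on the full
    1..max(day) daily axis, and validated against the item scales.
    """
    df = pd.read_csv(path, sep=delimiter)
    if df.empty:
        raise ValueError(f"no rating rows in {path}")
    colmap = {c: c for c in _REQUIRED_COLUMNS}
    if columns:
        colmap.update(columns)
    missing = [c for c in _REQUIRED_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})
    df["day"] = df["day"].astype(int)

    unknown = sorted(set(df["item"].astype(str)) - set(scales))
    if unknown:
        raise ValueError(f"no scale declared for items: {unknown}")

    out: dict[str, RatingSeries] = {}
    for subject, grp in df.groupby("subject", sort=True):
        grp = grp.sort_values(["day", "item"])
        items = sorted(grp["item"].astype(str).unique())
        n_days = int(grp["day"].max())
        if grp["day"].min() < 1:
            raise ValueError(f"day index must start at >= 1 (subject {subject!r})")
        grid = np.full((n_days, len(items)), np.nan)
        for _, row in grp.iterrows():
            grid[int(row["day"]) - 1, items.index(str(row["item"]))] = float(
                row["value"]
            )
        out[str(subject)] = RatingSeries(
            subject_id=str(subject),
            items=items,
            scales={it: scales[it] for it in items},
            values=grid,
        )
    return out


def write_ratings(
    series_map: Mapping[str, RatingSeries], path: str | Path, *, delimiter: str = ","
) -> None:
    """Write series back to the long format read by :func:`load_ratings`."""
    rows = []
    for sid in sorted(series_map):
        s = series_map[sid]
        for i, day in enumerate(s.day_index):
            for j, item in enumerate(s.items):
                v = s.values[i, j]
                if not np.isnan(v):
                    rows.append((sid, int(day), item, v))
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(
        path, sep=delimiter, index=False
    )


def load_schedules(path: str | Path, *, delimiter: str = ",") -> dict[str, ScanSchedule]:
    """Read a scan schedule CSV with columns ``subject,group,scan_day``."""
    df = pd.read_csv(path, sep=delimiter)
    need = {"subject", "group", "scan_day"}
    if not need.issubset(df.columns):
        raise ValueError(f"schedule file needs columns {sorted(need)}")
    out = {}
    for subject, grp in df.groupby("subject", sort=True):
        days = tuple(int(d) for d in sorted(grp["scan_day"]))
        group = str(grp["group"].iloc[0])
        out[str(subject)] = ScanSchedule(str(subject), days, group)
    return out


def prepare_series(series: RatingSeries, max_gap: int = 1) -> tuple[RatingSeries, GapReport]:
    """Fill short internal missing runs by linear interpolation.

    Runs of consecutive missing days of length <= ``max_gap`` that are
    flanked by observed values are linearly interpolated; leading/trailing
    missing values and longer runs are left missing and listed in the
    returned :class:`GapReport`.  Observed values are never altered, and
    interpolated values cannot leave the item scale (convexity).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    filled = series.values.copy()
    report = GapReport(series.subject_id)
    for j, item in enumerate(series.items):
        col = filled[:, j]
        isna = np.isnan(col)
        if not isna.any():
            continue
        n = len(col)
        i = 0
        while i < n:
            if not isna[i]:
                i += 1
                continue
            start = i
            while i < n and isna[i]:
                i += 1
            end = i  # exclusive
            length = end - start
            interior = start > 0 and end < n
            if interior and length <= max_gap:
                lo, hi = col[start - 1], col[end]
                for k in range(start, end):
                    frac = (k - start + 1) / (length + 1)
                    col[k] = lo + frac * (hi - lo)
            else:
                report.add(item, int(series.day_index[start]), length)
    out = RatingSeries(
        subject_id=series.subject_id,
        items=list(series.items),
        scales=dict(series.scales),
        values=filled,
        day_index=series.day_index.copy(),
    )
    return out, report
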