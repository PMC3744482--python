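"""ROI activation bookkeeping: inter-scan changes, weighted percentages,
and inter-ROI correlation structure.

The input is a panel of significant-voxel counts per subject × scan × ROI
for the symptom-provocation > neutral contrast, over a fixed ordered set of
eight regions implicated in obsessive-compulsive processing.  Analyses use
the absolute inter-scan change in counts and, to offset scanner-sensitivity
differences, a per-subject weighted percentage that normalises every cell
by the subject's single largest ROI × scan count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detection import IntervalLabel
from .stats import StatResult, paired_t_test

__all__ = [
    "ROI_LABELS",
    "RoiPanel",
    "weighted_percent",
    "interscan_changes",
    "mean_intercorrelation",
    "compare_intercorrelation",
]

ROI_LABELS: tuple[str, ...] = (
    "CC/SMA",
    "DLPFC r",
    "DLPFC l",
    "Insula r",
    "Insula l",
    "Parietal r",
    "Parietal l",
    "Cuneus",
)


@dataclass
class RoiPanel:
    """Subject × scan × ROI significant-voxel counts.

    ``counts[subject]`` is an (n_scans, n_rois) array of non-negative
    integers; scan counts per subject must match the scan schedule.
    ``groups`` maps subject -> "patient" | "control".  Voxelwise threshold
    metadata (heterogeneous across field strengths) may ride along but is
    not used in any computation here.
    """

    rois: tuple[str, ...] = ROI_LABELS
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, arr in self.counts.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != len(self.rois):
                raise ValueError(
                    f"subject {sid!r}: counts must be (n_scans, {len(self.rois)})"
                )
            if np.any(arr < 0):
                raise ValueError(f"subject {sid!r}: negative voxel count")
            self.counts[sid] = arr

    @property
    def subjects(self) -> list[str]:
        return sorted(self.counts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (sid, self.groups.get(sid, "patient"), s + 1, roi, self.counts[sid][s, r])
            for sid in self.subjects
            for s in range(self.counts[sid].shape[0])
            for r, roi in enumerate(self.rois)
        ]
        return pd.DataFrame(rows, columns=["subject", "group", "scan", "roi", "voxels"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rois: Sequence[str] = ROI_LABELS) -> "RoiPanel":
        counts, groups = {}, {}
        for sid, grp in df.groupby("subject", sort=True):
            n_scans = int(grp["scan"].max())
            arr = np.zeros((n_scans, len(rois)))
            for _, row in grp.iterrows():
                arr[int(row["scan"]) - 1, list(rois).index(row["roi"])] = row["voxels"]
            counts[str(sid)] = arr
            groups[str(sid)] = str(grp["group"].iloc[0])
        return cls(rois=tuple(rois), counts=counts, groups=groups)


def weighted_percent(panel: RoiPanel) -> dict[str, np.ndarray]:
    """Per-subject weighted percentages of voxel counts.

    Every cell is divided by the subject's single largest count over all
    ROIs and scans and multiplied by 100, so the maximum cell is exactly
    100 and high-count regions carry more statistical weight.  Invariant to
    rescaling a subject's counts by a positive constant.
    """
    out = {}
    for sid in panel.subjects:
        arr = panel.counts[sid]
        peak = arr.max()
        if peak <= 0:
            warnings.warn(f"subject {sid!r}: all-zero counts; weighted % set to 0",
                          stacklevel=2)
            out[sid] = np.zeros_like(arr)
        else:
            out[sid] = 100.0 * arr / peak
    return out


def interscan_changes(
    panel: RoiPanel, labels: Mapping[str, Sequence[IntervalLabel]]
) -> pd.DataFrame:
    """Absolute change across each inter-scan interval, per ROI.

    Returns one row per subject × interval × ROI with columns ``subject,
    group, interval, label, roi, diff_voxels, diff_weighted``.  Changes are
    magnitudes |Δ| — activation may rise or fall across a transition; its
    size is the quantity of interest.
    """
    wp = weighted_percent(panel)
    rows = []
    for sid in panel.subjects:
        arr = panel.counts[sid]
        warr = wp[sid]
        if sid not in labels:
            raise ValueError(f"no interval labels for subject {sid!r}")
        sub_labels = {lab.interval: lab for lab in labels[sid]}
        group = panel.groups.get(sid, "patient")
        n_scans = arr.shape[0]
        for k in range(1, n_scans):
            if k not in sub_labels:
                warnings.warn(
                    f"subject {sid!r}: interval {k} unlabelled; skipped",
                    stacklevel=2,
                )
                continue
            lab = sub_labels[k].label
            for r, roi in enumerate(panel.rois):
                rows.append(
                    (
                        sid,
                        group,
                        k,
                        lab,
                        roi,
                        abs(arr[k, r] - arr[k - 1, r]),
                        abs(warr[k, r] - warr[k - 1, r]),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "subject", "group", "interval", "label", "roi",
            "diff_voxels", "diff_weighted",
        ],
    )


def _scan_matrix(
    panel: RoiPanel,
    scan: int | str,
    subjects: Sequence[str],
    use_weighted: bool,
) -> np.ndarray:
    """(n_subjects, n_rois) activation at one scan position.

    ``scan`` is a 1-based index, or "first"/"last" to take each subject's
    first or final scan regardless of how many they had.
    """
    wp = weighted_percent(panel) if use_weighted else None
    rows = []
    for sid in subjects:
        arr = wp[sid] if use_weighted else panel.counts[sid]
        if scan == "first":
            rows.append(arr[0])
        elif scan == "last":
            rows.append(arr[-1])
        else:
            s = int(scan) - 1
            if s >= arr.shape[0]:
                raise ValueError(f"subject {sid!r} has no scan {scan}")
            rows.append(arr[s])
    return np.asarray(rows)


def mean_intercorrelation(
    panel: RoiPanel,
    scan: int | str,
    *,
    subjects: Sequence[str] | None = None,
    use_weighted: bool = False,
) -> tuple[float, float, pd.Series]:
    """Mean pairwise Pearson correlation of the 8 ROI activation vectors.

    Correlations are computed across subjects for each of the
    8·7/2 = 28 ROI pairs at the given scan position (so the later paired
    comparison has df = 27).  Raw counts are the default; pass
    ``use_weighted=True`` to correlate weighted percentages instead.
    Zero-variance ROIs yield missing pairs, excluded from mean/SD.
    """
    subjects = list(subjects) if subjects is not None else panel.subjects
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for correlations")
    mat = _scan_matrix(panel, scan, subjects, use_weighted)
    n_rois = mat.shape[1]
    pairs = {}
    for a in range(n_rois):
        for b in range(a + 1, n_rois):
            key = f"{panel.rois[a]}|{panel.rois[b]}"
            if np.std(mat[:, a]) == 0 or np.std(mat[:, b]) == 0:
                warnings.warn(
                    f"zero-variance ROI in pair {key}; correlation missing",
                    stacklevel=2,
                )
                pairs[key] = np.nan
            else:
                pairs[key] = float(sps.pearsonr(mat[:, a], mat[:, b])[0])
    ser = pd.Series(pairs, name=f"scan_{scan}")
    vals = ser.dropna()
    return float(vals.mean()), float(vals.std(ddof=1)), ser


def compare_intercorrelation(pairs_a: pd.Series, pairs_b: pd.Series) -> StatResult:
    """Paired t-test over the 28 ROI-pair correlations at two time points.

    With 8 ROIs both series carry 28 pairs and the test has df = 27.  The
    pair ordering must match; pairs missing in either series are dropped
    pairwise.
    """
    if len(pairs_a) != len(pairs_b):
        raise ValueError("pair lists differ in length")
    if list(pairs_a.index) != list(pairs_b.index):
        raise ValueError("pair lists differ in ordering")
    ok = ~(pairs_a.isna() | pairs_b.isna())
    return paired_t_test(pairs_a[ok].to_numpy(), pairs_b[ok].to_numpy())
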