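"""Inferential layer: t-tests, exact Wilcoxon tests, point-biserial effect
sizes, the two-factor ANOVA interaction, BCa bootstrap intervals, and the
OT/NOT/ISI contrast driver.

All significance tests are two-sided.  Paired comparisons (within-patient
OT vs NOT) use the paired t; between-group comparisons (patients vs
controls) use Welch's unequal-variance t with Satterthwaite fractional
degrees of freedom.  Every parametric result can be validated by the
corresponding non-parametric Wilcoxon test, exact for small samples.
Point-biserial correlations quantify effect size with the conventional
bands: small <= .20, medium .21-.35, large > .35.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "paired_t_test",
    "welch_t_test",
    "wilcoxon_paired",
    "wilcoxon_ranksum",
    "point_biserial",
    "effect_band",
    "two_way_anova_interaction",
    "bca_ci",
    "contrast_report",
    "group_mean_difference",
    "holm_adjust",
]

_P_FLOOR = np.finfo(float).tiny


@dataclass(frozen=True)
class StatResult:
    """Uniform result record for every test in this module."""

    estimate: float
    statistic: float
    df: float | None
    p: float
    method: str
    effect_size: float | None = None
    note: str = ""


def _as1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if np.isnan(a).any():
        raise ValueError("missing values not allowed in test input")
    return a


def paired_t_test(x, y) -> StatResult:
    """Two-sided paired t-test on matched observations (df = n - 1)."""
    x, y = _as1d(x), _as1d(y)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    est = float(d.mean())
    if np.std(d, ddof=1) == 0:
        if est == 0:
            return StatResult(0.0, 0.0, n - 1, 1.0, "paired t")
        return StatResult(
            est, math.inf, n - 1, _P_FLOOR, "paired t",
            note="zero variance of differences; p at machine floor",
        )
    res = sps.ttest_rel(x, y)
    return StatResult(est, float(res.statistic), float(n - 1), float(res.pvalue),
                      "paired t")


def welch_t_test(x, y) -> StatResult:
    """Two-sided unequal-variance t-test with Welch-Satterthwaite df."""
    x, y = _as1d(x), _as1d(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.std(x, ddof=1) == 0 and np.std(y, ddof=1) == 0:
        raise ValueError("zero variance in both groups: degenerate input")
    res = sps.ttest_ind(x, y, equal_var=False)
    df = float(res.df)
    return StatResult(
        float(x.mean() - y.mean()), float(res.statistic), df, float(res.pvalue),
        "Welch t",
    )


def wilcoxon_paired(x, y, *, exact_max_n: int = 25) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on matched pairs.

    Zero differences are dropped (Wilcoxon's original rule).  The p-value is
    exact when the remaining n is at most ``exact_max_n`` and the absolute
    differences are tie-free; otherwise a tie-corrected normal approximation
    is used.  The method label records which route was taken.
    """
    x, y = _as1d(x), _as1d(y)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return StatResult(0.0, 0.0, None, 1.0, "Wilcoxon signed-rank (degenerate)",
                          note="all differences zero")
    ties = len(np.unique(np.abs(d))) < n
    use_exact = n <= exact_max_n and not ties
    method = "exact" if use_exact else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(d, method=method, correction=not use_exact,
                           zero_method="wilcox")
    return StatResult(
        float(np.median(d)), float(res.statistic), None, float(res.pvalue),
        f"Wilcoxon signed-rank ({method})",
    )


def wilcoxon_ranksum(x, y, *, exact_max_n: int = 15) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null enumeration when min(n1, n2) <= ``exact_max_n`` and the
    pooled sample is tie-free; tie-corrected normal approximation otherwise.
    """
    x, y = _as1d(x), _as1d(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return StatResult(0.0, float(len(x) * len(y) / 2), None, 1.0,
                          "Wilcoxon rank-sum (degenerate)",
                          note="all observations identical")
    ties = len(np.unique(pooled)) < len(pooled)
    use_exact = min(len(x), len(y)) <= exact_max_n and not ties
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return StatResult(
        float(np.median(x) - np.median(y)), float(res.statistic), None,
        float(res.pvalue),
        f"Wilcoxon rank-sum ({'exact' if use_exact else 'approx'})",
    )


def point_biserial(values, labels) -> StatResult:
    """Point-biserial correlation: Pearson r between values and a 0/1 coding.

    ``labels`` is any two-level dichotomy; the lexicographically larger
    level is coded 1 (so "OT" is 1 against "NOT" or "ISI", and swapping the
    two labels flips the sign of r).  Used as an effect-size measure with
    the bands of :func:`effect_band`.
    """
    values = _as1d(values)
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError("labels must have exactly two levels")
    if np.std(values, ddof=0) == 0:
        return StatResult(float("nan"), float("nan"), None, float("nan"),
                          "point-biserial", effect_size=float("nan"),
                          note="zero variance of values")
    code = (labels == levels[-1]).astype(float)
    r, p = sps.pearsonr(values, code)
    return StatResult(float(r), float(r), float(len(values) - 2), float(p),
                      "point-biserial", effect_size=float(r))


def effect_band(r: float) -> str:
    """Conventional interpretation bands for point-biserial effect sizes."""
    a = abs(r)
    if a <= 0.20:
        return "small"
    if a <= 0.35:
        return "medium"
    return "large"


def two_way_anova_interaction(values, factor_group, factor_type) -> StatResult:
    """Group × transition-type interaction from a two-factor ANOVA.

    Type-III sums of squares with sum-to-zero coding, so results are
    meaningful for the unbalanced designs that small cohorts produce.
    Every non-empty cell needs at least one observation; an empty required
    cell is a design error.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "value": _as1d(values),
        "grp": np.asarray(factor_group, dtype=object),
        "ttype": np.asarray(factor_type, dtype=object),
    })
    cells = df.groupby(["grp", "ttype"], observed=True).size()
    for g in df["grp"].unique():
        for t in df["ttype"].unique():
            if (g, t) not in cells.index:
                raise ValueError(f"empty design cell: group={g!r}, type={t!r}")
    model = smf.ols("value ~ C(grp, Sum) * C(ttype, Sum)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    row = table.loc["C(grp, Sum):C(ttype, Sum)"]
    df_resid = float(table.loc["Residual", "df"])
    return StatResult(
        float(row["sum_sq"]), float(row["F"]),
        float(row["df"]), float(row["PR(>F)"]),
        "two-way ANOVA interaction (type III, sum coding)",
        note=f"df_resid={df_resid:g}",
    )


def bca_ci(
    sample,
    statistic: Callable[[np.ndarray], float],
    B: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    vectorized: bool = False,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap confidence interval.

    10,000 resamples by default; the acceleration constant comes from the
    jackknife.  Reproducible given ``seed``.  A degenerate (constant)
    sample collapses to a point interval with a warning.
    """
    arr = _as1d(sample)
    if len(arr) < 2:
        raise ValueError("need at least 2 observations")
    if B < 1000:
        raise ValueError("B must be >= 1000")
    if np.all(arr == arr[0]):
        v = float(statistic(arr))
        warnings.warn("degenerate sample: BCa interval collapses to a point",
                      stacklevel=2)
        return (v, v)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    res = sps.bootstrap(
        (arr,), statistic, n_resamples=B, confidence_level=level,
        method="BCa", vectorized=vectorized, rng=rng,
    )
    return (float(res.confidence_interval.low), float(res.confidence_interval.high))


def group_mean_difference(values_a, values_b) -> float:
    """Contrast estimate: mean of group A minus mean of group B."""
    return float(np.mean(_as1d(values_a)) - np.mean(_as1d(values_b)))


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; no correction is applied
    by default anywhere in the pipeline)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(list(pvals), method="holm")[1]


# ---------------------------------------------------------------------------
# Contrast driver

_MEAN_OF_ALL = "Mean of all"


def _per_subject_label_means(change_table: pd.DataFrame) -> pd.DataFrame:
    """One row per subject × label × scope with the mean change.

    A patient with several OT intervals contributes a single OT mean;
    likewise for NOT and for controls' ISI.  Scope is each ROI plus the
    mean over all ROIs (the subject's interval means averaged across ROIs).
    """
    per_roi = (
        change_table.groupby(["subject", "group", "label", "roi"], observed=True)[
            ["diff_voxels", "diff_weighted"]
        ]
        .mean()
        .reset_index()
        .rename(columns={"roi": "scope"})
    )
    overall = (
        per_roi.groupby(["subject", "group", "label"], observed=True)[
            ["diff_voxels", "diff_weighted"]
        ]
        .mean()
        .reset_index()
    )
    overall["scope"] = _MEAN_OF_ALL
    return pd.concat([overall, per_roi], ignore_index=True)


def _one_contrast(
    means: pd.DataFrame, scope: str, measure: str, label_a: str, label_b: str
) -> dict:
    sub = means[means["scope"] == scope]
    a = sub[sub["label"] == label_a].set_index("subject")[measure]
    b = sub[sub["label"] == label_b].set_index("subject")[measure]
    paired = {"OT", "NOT"} == {label_a, label_b}
    row = {
        "scope": scope,
        "measure": measure,
        "contrast": f"{label_a}-{label_b}",
        "mean_diff": group_mean_difference(a, b),
    }
    if paired:
        common = a.index.intersection(b.index)
        dropped = set(a.index).symmetric_difference(b.index)
        if dropped:
            warnings.warn(
                f"{scope}/{measure}: subjects {sorted(dropped)} lack one label; "
                "excluded from the paired contrast", stacklevel=3,
            )
        t = paired_t_test(a[common], b[common])
        w = wilcoxon_paired(a[common], b[common])
    elif np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        # constant groups: identical means -> no difference at all;
        # distinct means -> separation with zero spread
        diff = a.mean() - b.mean()
        t = (
            StatResult(0.0, 0.0, float(len(a) + len(b) - 2), 1.0,
                       "Welch t (degenerate)")
            if diff == 0
            else StatResult(float(diff), math.copysign(math.inf, diff),
                            float(len(a) + len(b) - 2), _P_FLOOR,
                            "Welch t (degenerate)",
                            note="zero variance in both groups")
        )
        w = wilcoxon_ranksum(a, b)
    else:
        t = welch_t_test(a, b)
        w = wilcoxon_ranksum(a, b)
    pooled = np.concatenate([a.to_numpy(), b.to_numpy()])
    codes = np.array([label_a] * len(a) + [label_b] * len(b))
    r = point_biserial(pooled, codes)
    row.update(
        t=t.statistic, df=t.df, p_t=t.p, p_wilcoxon=w.p,
        r=r.effect_size, effect=effect_band(r.effect_size) if r.effect_size == r.effect_size else "",
    )
    return row


def contrast_report(change_table: pd.DataFrame, *, adjust: str | None = None) -> pd.DataFrame:
    """OT/NOT/ISI contrasts per ROI and for the mean over all ROIs.

    Per subject, interval changes are averaged within each label; OT vs NOT
    is then tested paired within patients (t and signed-rank), OT vs ISI
    and NOT vs ISI unpaired against controls (Welch t and rank-sum), each
    for raw voxel differences and weighted-percent differences, with a
    point-biserial effect size per contrast.  No multiple-testing
    correction is applied unless ``adjust="holm"``.
    """
    need = {"OT", "NOT", "ISI"} - set(change_table["label"].unique())
    if need:
        raise ValueError(f"change table lacks label(s): {sorted(need)}")
    means = _per_subject_label_means(change_table)
    scopes = [_MEAN_OF_ALL] + sorted(
        s for s in means["scope"].unique() if s != _MEAN_OF_ALL
    )
    rows = [
        _one_contrast(means, scope, measure, la, lb)
        for scope in scopes
        for measure in ("diff_voxels", "diff_weighted")
        for la, lb in (("OT", "NOT"), ("OT", "ISI"), ("NOT", "ISI"))
    ]
    report = pd.DataFrame(rows)
    if adjust == "holm":
        report["p_t_holm"] = holm_adjust(report["p_t"])
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return report
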