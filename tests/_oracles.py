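"""Independent brute-force re-implementations used as oracles in tests.

These deliberately share no code with the package: naive O(m^2) double
loops, full permutation enumeration, and textbook closed forms.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_fluctuation(window, lo: float, hi: float) -> float:
    """O(m^2)-style fluctuation intensity: walk the sequence, splitting at
    strict direction reversals (plateaus extend the run, turning point at
    the last extremal value), then sum amplitude/duration per run."""
    x = [float(v) for v in window]
    m = len(x)
    R = hi - lo
    # indices of turning points: last extremal value before a strict reversal
    turns = [0]
    direction = 0
    for i in range(m - 1):
        step = x[i + 1] - x[i]
        s = (step > 0) - (step < 0)
        if s == 0:
            continue
        if direction == 0:
            direction = s
        elif s != direction:
            turns.append(i)
            direction = s
    turns.append(m - 1)
    total = 0.0
    for a, b in zip(turns, turns[1:]):
        if b > a:
            total += abs(x[b] - x[a]) / (b - a)
    return total / (R * (m - 1))


def naive_distribution(window, lo: float, hi: float) -> float:
    """Brute-force distribution degree: explicit double loop over all
    sorted spans, accumulating positive deviations from the even-coverage
    ideal."""
    y = sorted(float(v) for v in window)
    m = len(y)
    R = hi - lo
    dev = 0.0
    ideal_total = 0.0
    for c in range(1, m):
        ideal = c * R / (m - 1)
        for a in range(0, m - c):
            b = a + c
            dev += max(0.0, ideal - (y[b] - y[a]))
            ideal_total += ideal
    return 1.0 - dev / ideal_total


def naive_complexity(window, lo: float, hi: float) -> float:
    return naive_fluctuation(window, lo, hi) * naive_distribution(window, lo, hi)


def paired_t_by_hand(x, y):
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)), df = n-1."""
    from scipy.stats import t as tdist

    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    se = d.std(ddof=1) / math.sqrt(n)
    t = d.mean() / se
    p = 2 * tdist.sf(abs(t), n - 1)
    return t, n - 1, p


def welch_by_hand(x, y):
    """Textbook Welch t with Satterthwaite df."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def signed_rank_exact_p(d):
    """Two-sided signed-rank p by full enumeration of the 2^n sign
    configurations (tie-free |d| assumed, zeros already dropped)."""
    d = np.asarray(d, float)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for s, r in zip(signs, ranks) if s))
    stats = np.asarray(stats, float)
    extreme = np.abs(stats - mean_w) >= abs(w_obs - mean_w) - 1e-12
    return extreme.mean()


def ranksum_exact_p(x, y):
    """Two-sided rank-sum p by full enumeration of group assignments
    (tie-free pooled sample assumed)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (len(pooled) + 1) / 2
    stats = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    stats = np.asarray(stats, float)
    extreme = np.abs(stats - mean_w) >= abs(w_obs - mean_w) - 1e-12
    return extreme.mean()


def pearson_by_hand(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def balanced_anova_interaction_F(values, a, b):
    """Closed-form balanced two-way ANOVA interaction F from cell means."""
    values = np.asarray(values, float)
    a = np.asarray(a)
    b = np.asarray(b)
    lv_a, lv_b = np.unique(a), np.unique(b)
    n_cell = len(values) / (len(lv_a) * len(lv_b))
    grand = values.mean()
    ss_int = 0.0
    for ai in lv_a:
        for bi in lv_b:
            cell = values[(a == ai) & (b == bi)].mean()
            ss_int += n_cell * (
                cell - values[a == ai].mean() - values[b == bi].mean() + grand
            ) ** 2
    ss_err = sum(
        ((values[(a == ai) & (b == bi)]
          - values[(a == ai) & (b == bi)].mean()) ** 2).sum()
        for ai in lv_a for bi in lv_b
    )
    df_int = (len(lv_a) - 1) * (len(lv_b) - 1)
    df_err = len(values) - len(lv_a) * len(lv_b)
    return (ss_int / df_int) / (ss_err / df_err), df_int, df_err
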