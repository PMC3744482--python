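import numpy as np
import pandas as pd
import pytest

from ordertrans import (
    bca_ci,
    contrast_report,
    effect_band,
    group_mean_difference,
    paired_t_test,
    point_biserial,
    two_way_anova_interaction,
    welch_t_test,
    wilcoxon_paired,
    wilcoxon_ranksum,
)
from ordertrans.stats import holm_adjust

from ._oracles import (
    balanced_anova_interaction_F,
    paired_t_by_hand,
    pearson_by_hand,
    ranksum_exact_p,
    signed_rank_exact_p,
    welch_by_hand,
)


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_nine_pairs_df_eight(self, rng):
        res = paired_t_test(rng.normal(size=9), rng.normal(size=9))
        assert res.df == 8

    def test_matches_hand_formula_on_random_data(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 20))
            x, y = rng.normal(size=n), rng.normal(size=n)
            res = paired_t_test(x, y)
            t, df, p = paired_t_by_hand(x, y)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.df == df
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_zero_variance_nonzero_mean_flagged(self):
        res = paired_t_test([2, 3, 4], [1, 2, 3])
        assert res.p <= np.finfo(float).tiny
        assert "machine floor" in res.note


class TestWelchT:
    def test_identical_groups(self, rng):
        x = rng.normal(size=10)
        res = welch_t_test(x, x)
        assert res.statistic == pytest.approx(0.0)

    def test_matches_hand_formula_on_random_data(self, rng):
        for _ in range(100):
            x = rng.normal(size=int(rng.integers(3, 15)))
            y = rng.normal(2, 3, size=int(rng.integers(3, 15)))
            res = welch_t_test(x, y)
            t, df, p = welch_by_hand(x, y)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.df == pytest.approx(df, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_satterthwaite_df_bounded_by_pooled(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert welch_t_test(x, y).df <= 14 + 1e-9

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            welch_t_test([1, 1, 1], [2, 2, 2])


class TestWilcoxon:
    def test_paired_identical_p_one(self):
        res = wilcoxon_paired([1, 2, 3], [1, 2, 3])
        assert res.p == 1.0

    def test_all_positive_differences_n6_extreme(self):
        # most extreme signed-rank configuration: p = 2/2^6
        res = wilcoxon_paired([2, 3, 4, 5, 6, 7], [1, 1, 1, 1, 1, 0.5])
        assert res.p == pytest.approx(2 / 64)
        assert "exact" in res.method

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_paired_exact_equals_full_enumeration(self, rng, n):
        for _ in range(20):
            d = rng.normal(size=n)
            while len(np.unique(np.abs(d))) < n or (d == 0).any():
                d = rng.normal(size=n)
            res = wilcoxon_paired(d, np.zeros(n))
            assert res.p == pytest.approx(signed_rank_exact_p(d), abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(3, 4), (5, 5), (4, 7)])
    def test_ranksum_exact_equals_full_enumeration(self, rng, n1, n2):
        for _ in range(10):
            x, y = rng.normal(size=n1), rng.normal(1, 1, size=n2)
            res = wilcoxon_ranksum(x, y)
            assert "exact" in res.method
            assert res.p == pytest.approx(ranksum_exact_p(x, y), abs=1e-12)

    def test_ranksum_degenerate_identical(self):
        res = wilcoxon_ranksum([5, 5, 5], [5, 5, 5])
        assert res.p == 1.0

    def test_ties_fall_back_to_approximation(self):
        res = wilcoxon_paired([1, 2, 3, 4, 5, 6], [0, 1, 2, 3, 3, 4])
        assert "approx" in res.method
        assert 0 < res.p <= 1


class TestPointBiserial:
    def test_equal_group_means_give_zero(self):
        res = point_biserial([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert res.effect_size == pytest.approx(0.0)

    def test_equals_hand_pearson_on_dummy_coding(self, rng):
        vals = rng.normal(size=12)
        labs = np.array(["OT"] * 5 + ["NOT"] * 7)
        res = point_biserial(vals, labs)
        code = (labs == "OT").astype(float)
        assert res.effect_size == pytest.approx(
            pearson_by_hand(vals, code), abs=1e-12
        )

    def test_affine_invariance_and_label_swap_sign(self, rng):
        vals = rng.normal(size=10)
        labs = np.array(["a"] * 4 + ["b"] * 6)
        r = point_biserial(vals, labs).effect_size
        r_affine = point_biserial(3 * vals - 7, labs).effect_size
        assert r_affine == pytest.approx(r, abs=1e-12)
        r_swapped = point_biserial(vals, np.where(labs == "a", "b", "a")).effect_size
        assert r_swapped == pytest.approx(-r, abs=1e-12)

    @pytest.mark.parametrize(
        "r, band", [(0.1, "small"), (0.2, "small"), (0.3, "medium"),
                    (0.35, "medium"), (0.36, "large"), (-0.6, "large")]
    )
    def test_effect_bands(self, r, band):
        assert effect_band(r) == band

    def test_zero_variance_flagged(self):
        res = point_biserial([5, 5, 5, 5], list("aabb"))
        assert np.isnan(res.effect_size if res.effect_size is not None else np.nan) or \
            "zero variance" in res.note


class TestAnovaInteraction:
    def test_equal_cell_means_no_interaction(self, rng):
        vals, g, t = [], [], []
        for gi in ("patient", "control"):
            for ti in ("OT", "NOT"):
                vals += [1.0, 2.0, 3.0]
                g += [gi] * 3
                t += [ti] * 3
        res = two_way_anova_interaction(vals, g, t)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0, abs=1e-10)

    def test_balanced_design_matches_closed_form(self, rng):
        g = np.repeat(["patient", "control"], 12)
        t = np.tile(np.repeat(["OT", "NOT"], 6), 2)
        vals = rng.normal(size=24) + 2.0 * (g == "patient") * (t == "OT")
        res = two_way_anova_interaction(vals, g, t)
        F, df_int, df_err = balanced_anova_interaction_F(vals, g, t)
        assert res.statistic == pytest.approx(F, abs=1e-8)
        assert res.df == df_int

    def test_additive_cell_means_zero_interaction_ss(self):
        # cell means: grand + row effect + column effect, no product term
        vals, g, t = [], [], []
        for gi, ge in (("patient", 1.0), ("control", -1.0)):
            for ti, te in (("OT", 2.0), ("NOT", -2.0)):
                vals += [10 + ge + te] * 4
                g += [gi] * 4
                t += [ti] * 4
        res = two_way_anova_interaction(vals, g, t)
        assert res.estimate == pytest.approx(0.0, abs=1e-10)

    def test_empty_cell_is_design_error(self):
        with pytest.raises(ValueError, match="empty design cell"):
            two_way_anova_interaction(
                [1, 2, 3, 4], ["p", "p", "c", "c"], ["OT", "NOT", "NOT", "NOT"]
            )


class TestBcaCI:
    def test_constant_sample_collapses(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bca_ci([3.0, 3.0, 3.0], np.mean, B=1000)
        assert lo == hi == 3.0

    def test_reproducible_given_seed(self, rng):
        x = rng.normal(size=30)
        a = bca_ci(x, np.mean, B=2000, seed=7)
        b = bca_ci(x, np.mean, B=2000, seed=7)
        assert a == b

    def test_interval_brackets_point_estimate(self, rng):
        x = rng.normal(5, 2, size=40)
        lo, hi = bca_ci(x, np.mean, B=2000, seed=1)
        assert lo < x.mean() < hi

    def test_small_resample_count_rejected(self):
        with pytest.raises(ValueError, match="B must be"):
            bca_ci([1.0, 2.0], np.mean, B=10)


def _toy_change_table(rng, ot=7000.0, not_=2000.0, isi=500.0, jitter=0.0):
    rows = []
    for i in range(9):
        sid = f"p{i}"
        for k, lab, mean in ((1, "OT", ot), (2, "NOT", not_)):
            for roi in range(8):
                rows.append(
                    (sid, "patient", k, lab, f"roi{roi}",
                     mean + jitter * rng.normal(),
                     mean / 100 + jitter * rng.normal() / 100)
                )
    for i in range(9):
        sid = f"c{i}"
        for roi in range(8):
            rows.append(
                (sid, "control", 1, "ISI", f"roi{roi}",
                 isi + jitter * rng.normal(),
                 isi / 100 + jitter * rng.normal() / 100)
            )
    return pd.DataFrame(
        rows,
        columns=["subject", "group", "interval", "label", "roi",
                 "diff_voxels", "diff_weighted"],
    )


class TestContrastReport:
    def test_printed_group_means_reproduce_reported_differences(self, rng):
        """Feeding the reported OT/NOT/ISI group means through the contrast
        arithmetic reproduces the reported mean differences within rounding
        of the printed inputs."""
        table = _toy_change_table(rng, ot=7479, not_=1904, isi=697)
        rep = contrast_report(table).set_index(["scope", "measure", "contrast"])
        assert rep.loc[("Mean of all", "diff_voxels", "OT-NOT"), "mean_diff"] == \
            pytest.approx(5575.10, abs=1.0)
        assert rep.loc[("Mean of all", "diff_voxels", "OT-ISI"), "mean_diff"] == \
            pytest.approx(6782.13, abs=1.0)
        assert rep.loc[("Mean of all", "diff_voxels", "NOT-ISI"), "mean_diff"] == \
            pytest.approx(1207.03, abs=1.0)

    def test_identical_diffs_give_null_contrasts(self, rng):
        table = _toy_change_table(rng, ot=100.0, not_=100.0, isi=100.0)
        rep = contrast_report(table)
        assert (rep.mean_diff == 0).all()
        assert (rep.p_t == 1.0).all()

    def test_recovers_injected_effect_direction_everywhere(self, rng):
        table = _toy_change_table(rng, ot=7000, not_=2000, isi=500, jitter=200)
        rep = contrast_report(table)
        ot_not = rep[rep.contrast == "OT-NOT"]
        assert (ot_not.mean_diff > 0).all()
        assert len(rep) == 9 * 2 * 3  # 8 ROIs + mean-of-all, 2 measures, 3 contrasts

    def test_paired_df_is_eight_with_nine_patients(self, rng):
        table = _toy_change_table(rng, jitter=100)
        rep = contrast_report(table)
        assert (rep[rep.contrast == "OT-NOT"].df == 8).all()

    def test_patient_missing_a_label_excluded_from_paired(self, rng):
        table = _toy_change_table(rng, jitter=100)
        table = table[~((table.subject == "p0") & (table.label == "NOT"))]
        with pytest.warns(UserWarning, match="lack one label"):
            rep = contrast_report(table)
        assert (rep[rep.contrast == "OT-NOT"].df == 7).all()

    def test_missing_label_class_rejected(self, rng):
        table = _toy_change_table(rng)
        with pytest.raises(ValueError, match="ISI"):
            contrast_report(table[table.label != "ISI"])

    def test_holm_option_appends_adjusted_column(self, rng):
        table = _toy_change_table(rng, jitter=150)
        rep = contrast_report(table, adjust="holm")
        assert "p_t_holm" in rep.columns
        assert (rep.p_t_holm >= rep.p_t - 1e-15).all()


def test_group_mean_difference_is_plain_arithmetic():
    assert group_mean_difference([7479], [1904]) == 5575.0


def test_holm_adjust_monotone():
    p = [0.01, 0.04, 0.03, 0.5]
    adj = holm_adjust(p)
    assert (adj >= np.asarray(p) - 1e-15).all()
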