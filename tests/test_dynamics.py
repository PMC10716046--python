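"""DIP calling, YC:YR ratio statistics, trajectories and utilities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dualinit.dynamics import (
    DipParams,
    call_dips,
    class_total_chisq,
    doubling_time,
    intersect_sets,
    merge_gene_level,
    paired_ratio_test,
    qpcr_yc_estimate,
    relative_survival,
    trajectory_select,
    yc_yr_ratio,
)


def matrix_from(yc, yr, samples=None, index=None):
    yc = np.atleast_2d(yc)
    yr = np.atleast_2d(yr)
    samples = samples or [f"s{i + 1}" for i in range(yc.shape[1])]
    data = {}
    for j, s in enumerate(samples):
        data[f"yc_{s}"] = yc[:, j]
        data[f"yr_{s}"] = yr[:, j]
    idx = index or [f"p{i + 1}" for i in range(yc.shape[0])]
    return pd.DataFrame(data, index=idx)


class TestCallDips:
    def test_majority_rule_example(self):
        m = matrix_from([[1.5, 1.2, 0.4]], [[2, 3, 5]])
        assert call_dips(m) == ["p1"]  # 2 of 3 samples qualify

    def test_exact_threshold_is_not_enough(self):
        m = matrix_from([[1.0, 1.0, 1.0]], [[5, 5, 5]])
        assert call_dips(m) == []  # strict > 1 TPM

    def test_single_qualifying_sample_of_one(self):
        m = matrix_from([[2.0]], [[2.0]])
        assert call_dips(m) == ["p1"]

    def test_exact_majority_fraction_excluded(self):
        # 2 of 4 samples is not "> 0.5 * n"
        m = matrix_from([[2, 2, 0, 0]], [[2, 2, 2, 2]])
        assert call_dips(m) == []

    def test_min_samples_override(self):
        m = matrix_from([[2, 2, 0, 0]], [[2, 2, 2, 2]])
        assert call_dips(m, DipParams(min_samples=2)) == ["p1"]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_per_row_rule_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(1, 40)), int(rng.integers(1, 6))
        yc = rng.uniform(0, 3, (n, k))
        yr = rng.uniform(0, 3, (n, k))
        m = matrix_from(yc, yr)
        expected = [
            f"p{i + 1}"
            for i in range(n)
            if ((yc[i] > 1) & (yr[i] > 1)).sum() > 0.5 * k
        ]
        assert call_dips(m) == sorted(expected)


class TestYcYrRatio:
    def test_equal_components_give_unit_ratio(self):
        m = matrix_from([[4.0]], [[4.0]])
        out = yc_yr_ratio(m, 0.01)
        assert out["ratio_s1"].iloc[0] == pytest.approx(1.0)

    def test_normalized_ratio_example(self):
        m = matrix_from([[2.0, 0.5]], [[1.0, 1.0]])
        out = yc_yr_ratio(m, 1e-12)
        assert out["norm_ratio_s1"].iloc[0] == pytest.approx(1.6)
        assert out["norm_ratio_s2"].iloc[0] == pytest.approx(0.4)

    def test_pseudocount_keeps_ratio_finite(self):
        m = matrix_from([[10.0]], [[0.0]])
        out = yc_yr_ratio(m, 0.01)
        r = out["ratio_s1"].iloc[0]
        assert np.isfinite(r) and r == pytest.approx(10.01 / 0.01)

    @pytest.mark.parametrize("seed", range(10))
    def test_normalized_ratios_mean_one_per_promoter(self, seed):
        rng = np.random.default_rng(seed)
        m = matrix_from(rng.uniform(0, 20, (30, 4)), rng.uniform(0, 20, (30, 4)))
        out = yc_yr_ratio(m)
        norm = out[[c for c in out.columns if c.startswith("norm_ratio_")]]
        np.testing.assert_allclose(norm.mean(axis=1), 1.0, atol=1e-9)


class TestPairedRatioTest:
    def _table(self, cond_log2, ref_log2):
        n = len(cond_log2)
        df = pd.DataFrame(
            {
                "log2_ratio_a": cond_log2,
                "log2_ratio_b": ref_log2,
            },
            index=[f"p{i}" for i in range(n)],
        )
        return df

    def test_constant_shift_is_degenerate(self):
        t = self._table([1.0] * 5, [0.0] * 5)
        res = paired_ratio_test(t, ["a"], ["b"])
        assert res["degenerate"] and res["p"] == 0.0
        assert res["mean_log2fc"] == pytest.approx(1.0)

    def test_small_n_skips_test(self):
        t = self._table([1.0, 2.0], [0.0, 0.0])
        res = paired_ratio_test(t, ["a"], ["b"])
        assert np.isnan(res["p"]) and res["mean_log2fc"] == pytest.approx(1.5)

    def test_strong_shift_tiny_noise_highly_significant(self):
        rng = np.random.default_rng(0)
        d = 1.0 + rng.normal(0, 1e-3, 20)
        res = paired_ratio_test(self._table(d, np.zeros(20)), ["a"], ["b"])
        assert res["p"] < 1e-3

    def test_matches_closed_form_t(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.3, 1.0, 15)
        res = paired_ratio_test(self._table(d, np.zeros(15)), ["a"], ["b"])
        t_exp = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_exp = 2 * stats.t.sf(abs(t_exp), len(d) - 1)
        assert res["t"] == pytest.approx(t_exp)
        assert res["p"] == pytest.approx(p_exp)

    def test_null_type_one_error_calibrated(self):
        """Under a symmetric null the rejection rate at alpha=0.05 is ~5%."""
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 200
        for _ in range(reps):
            d = rng.normal(0, 0.5, 40)
            res = paired_ratio_test(self._table(d, np.zeros(40)), ["a"], ["b"])
            rejections += res["p"] < 0.05
        # binomial 99% CI around 0.05 with 200 reps
        assert 2 <= rejections <= 21


class TestClassTotalChisq:
    def test_equal_proportions_null(self):
        res = class_total_chisq(300, 700, 600, 1400)
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)
        assert res["odds_ratio"] == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        # brute-force Pearson formula on the 2x2 table
        a, b, c, d = 300, 700, 150, 850
        n = a + b + c + d
        expected_chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        res = class_total_chisq(a, b, c, d)
        assert res["chi2"] == pytest.approx(expected_chi2)
        assert res["odds_ratio"] == pytest.approx((a * d) / (b * c))

    def test_zero_cell_haldane_flagged(self):
        res = class_total_chisq(0, 700, 150, 850)
        assert res["haldane"]
        assert np.isfinite(res["odds_ratio"])

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            class_total_chisq(0, 0, 10, 10)


class TestTrajectorySelect:
    def _ratio_table(self, values):
        # values: promoter -> per-sample log2 ratios for samples a1,b1,c1
        df = pd.DataFrame(values).T
        df.columns = ["log2_ratio_a1", "log2_ratio_b1", "log2_ratio_c1"]
        return df

    cohorts = {"hi": ["a1"], "mid": ["b1"], "lo": ["c1"]}

    def test_monotone_selected(self):
        t = self._ratio_table({"p1": [1.0, 0.0, -1.0]})
        assert trajectory_select(t, self.cohorts, ["hi", "mid", "lo"]) == ["p1"]

    def test_non_monotone_rejected(self):
        t = self._ratio_table({"p1": [1.0, -1.3, -1.0]})
        assert trajectory_select(t, self.cohorts, ["hi", "mid", "lo"]) == []

    def test_tie_rejected_strictness(self):
        t = self._ratio_table({"p1": [1.0, 1.0, 0.0]})
        assert trajectory_select(t, self.cohorts, ["hi", "mid", "lo"]) == []

    def test_empty_cohort_errors(self):
        t = self._ratio_table({"p1": [1.0, 0.0, -1.0]})
        with pytest.raises(ValueError, match="no samples"):
            trajectory_select(t, {**self.cohorts, "lo": []}, ["hi", "mid", "lo"])

    def test_null_selection_rate_is_one_in_six(self):
        """Exchangeable cohorts: strict ordering happens for 1/3! of promoters."""
        rng = np.random.default_rng(3)
        n = 3000
        t = self._ratio_table({f"p{i}": rng.normal(0, 1, 3) for i in range(n)})
        selected = trajectory_select(t, self.cohorts, ["hi", "mid", "lo"])
        rate = len(selected) / n
        # binomial 99.7% CI around 1/6 with n=3000
        assert abs(rate - 1 / 6) < 3 * np.sqrt((1 / 6) * (5 / 6) / n)

    def test_delta_metric_orders_by_treatment_change(self):
        df = pd.DataFrame(
            {
                "log2_ratio_a1": [0.0],
                "log2_ratio_b1": [0.0],
                "log2_ratio_a1_irr": [-2.0],
                "log2_ratio_b1_irr": [-0.5],
            },
            index=["p1"],
        )
        cohorts = {"resp": ["a1"], "nonresp": ["b1"]}
        treated = {"resp": ["a1_irr"], "nonresp": ["b1_irr"]}
        # most negative change last in the order "least depleted first"
        sel = trajectory_select(
            df, cohorts, ["nonresp", "resp"], metric="delta", treatment_samples=treated
        )
        assert sel == ["p1"]


class TestIntersections:
    def test_pairwise(self):
        res = intersect_sets({"A": {"x", "y"}, "B": {"y", "z"}})
        assert res["counts"]["A+B"] == 1
        assert res["regions"]["A+B"] == ["Y"]

    def test_three_disjoint(self):
        res = intersect_sets({"A": {"a"}, "B": {"b"}, "C": {"c"}})
        for key in ("A+B", "A+C", "B+C", "A+B+C"):
            assert res["counts"][key] == 0

    def test_exclusive_regions_partition(self):
        res = intersect_sets({"A": {"1", "2", "3"}, "B": {"2", "3", "4"}, "C": {"3"}})
        assert res["counts"]["A"] == 1  # only "1"
        assert res["counts"]["A+B"] == 1  # "2" (not "3", which is in C)
        assert res["counts"]["A+B+C"] == 1  # "3"
        total = sum(res["counts"].values())
        assert total == 4  # |union|

    def test_case_normalization(self):
        res = intersect_sets({"A": {"abc"}, "B": {"ABC"}})
        assert res["counts"]["A+B"] == 1


class TestQpcrSubtraction:
    def test_simple_subtraction(self):
        res = qpcr_yc_estimate(10, 4)
        assert res["yc"] == 6 and res["ratio"] == pytest.approx(1.5)

    def test_equal_signals_give_zero_yc(self):
        res = qpcr_yc_estimate(4, 4)
        assert res["yc"] == 0 and not res["inconsistent"]

    def test_small_deficit_clipped_within_tolerance(self):
        res = qpcr_yc_estimate(3.9, 4.0, tolerance=0.05)
        assert res["yc"] == 0 and res["clipped"] and not res["inconsistent"]

    def test_large_deficit_flagged(self):
        res = qpcr_yc_estimate(3.0, 4.0, tolerance=0.05)
        assert res["yc"] == 0 and res["inconsistent"]


class TestDoublingTime:
    def test_one_doubling_in_four_days(self):
        assert doubling_time(4, 100_000) == pytest.approx(4.0)

    def test_three_doublings_in_nine_days(self):
        assert doubling_time(9, 400_000) == pytest.approx(3.0)

    def test_no_growth_errors(self):
        with pytest.raises(ValueError, match="no growth"):
            doubling_time(4, 50_000)


class TestRelativeSurvival:
    def test_equal_viability(self):
        res = relative_survival([10, 10], [10, 10])
        assert res["ratio"] == pytest.approx(1.0)

    def test_five_percent_survival(self):
        res = relative_survival([5, 5, 5], [100, 100, 100])
        assert res["ratio"] == pytest.approx(0.05)
        assert res["sem"] == pytest.approx(0.0)

    def test_single_replicate_sem_undefined(self):
        res = relative_survival([5], [100])
        assert np.isnan(res["sem"])

    def test_nonpositive_control_errors(self):
        with pytest.raises(ValueError):
            relative_survival([5], [0])


class TestGeneMerge:
    def test_clusters_of_one_gene_are_summed(self):
        m = matrix_from([[1.0], [2.0], [4.0]], [[1.0], [1.0], [1.0]],
                        index=["c1", "c2", "c3"])
        gene_ids = pd.Series({"c1": "gA", "c2": "gA", "c3": "gB"})
        merged = merge_gene_level(m, gene_ids)
        assert merged.loc["gA", "yc_s1"] == pytest.approx(3.0)
        assert merged.loc["gB", "yc_s1"] == pytest.approx(4.0)

    def test_unassigned_clusters_dropped(self):
        m = matrix_from([[1.0], [2.0]], [[1.0], [1.0]], index=["c1", "c2"])
        gene_ids = pd.Series({"c1": "gA", "c2": ""})
        merged = merge_gene_level(m, gene_ids)
        assert list(merged.index) == ["gA"]
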