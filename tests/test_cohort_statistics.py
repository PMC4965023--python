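import math

import numpy as np
import pytest
from scipy import stats

from spinemorph.cohort_statistics import (
    anova_bonferroni,
    icc_2_1,
    ks_normality,
    paired_t,
    pearson_with_regression,
    run_paper_battery,
    sample_size_two_means,
    two_sample_t,
)


class TestTwoSampleT:
    def test_identical_groups(self):
        r = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_welch_closed_form_oracle(self):
        # hand-computed Welch formula for {1,2,3} vs {4,5,6}
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        sa2 = sb2 = 1.0  # sample variances
        se = math.sqrt(sa2 / 3 + sb2 / 3)
        t_expected = (2.0 - 5.0) / se
        df_expected = (sa2 / 3 + sb2 / 3) ** 2 / ((sa2 / 3) ** 2 / 2 + (sb2 / 3) ** 2 / 2)
        p_expected = 2 * stats.t.sf(abs(t_expected), df_expected)
        r = two_sample_t(a, b)
        assert r.statistic == pytest.approx(t_expected, abs=1e-12)
        assert r.df == pytest.approx(df_expected, abs=1e-9)
        assert r.p_value == pytest.approx(p_expected, abs=1e-12)
        assert r.group_means == (2.0, 5.0)

    def test_pooled_variant(self):
        r = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 7.0], pooled=True)
        assert r.name == "pooled t"
        assert r.df == 4.0

    def test_degenerate(self):
        with pytest.raises(ValueError):
            two_sample_t([2.0, 2.0], [3.0, 3.0])
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])

    def test_type_one_error_calibration(self):
        # null simulation: rejection rate at alpha=0.05 within +-0.01
        rng = np.random.default_rng(2718)
        reps, n = 10_000, 10
        a = rng.normal(size=(n, reps))
        b = rng.normal(size=(n, reps))
        p = stats.ttest_ind(a, b, equal_var=False, axis=0).pvalue
        rate = float(np.mean(p < 0.05))
        assert rate == pytest.approx(0.05, abs=0.01)


class TestAnovaBonferroni:
    def test_three_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        r = anova_bonferroni([g, g, g])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_one_shifted_group_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30)
        c = rng.normal(5, 1, 30)
        r = anova_bonferroni({"a": a, "b": b, "c": c})
        assert r.p_value < 1e-6
        pairs = {dict(p)["pair"]: dict(p)["p_adjusted"] for p in r.pairwise}
        assert pairs["a vs b"] > 0.05
        assert pairs["a vs c"] < 0.001
        assert pairs["b vs c"] < 0.001

    def test_adjusted_never_below_raw_and_family_size(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(i * 0.1, 1, 12) for i in range(4)]
        r = anova_bonferroni(groups)
        assert len(r.pairwise) == 4 * 3 // 2
        for p in r.pairwise:
            d = dict(p)
            assert d["p_adjusted"] >= d["p_raw"]
            assert d["p_adjusted"] <= 1.0

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            anova_bonferroni([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError):
            anova_bonferroni([[1.0, 2.0], [3.0, 4.0], [5.0]])


class TestPairedT:
    def test_zero_mean_differences(self):
        r = paired_t([1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_four_pair_closed_form(self):
        a = np.array([3.0, 5.0, 4.0, 6.0])
        b = np.array([1.0, 2.0, 2.0, 3.0])
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(4))
        p_expected = 2 * stats.t.sf(abs(t_expected), 3)
        r = paired_t(a, b)
        assert r.statistic == pytest.approx(t_expected, abs=1e-12)
        assert r.p_value == pytest.approx(p_expected, abs=1e-12)
        assert r.df == 3

    def test_identical_pairs_degenerate(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPearsonRegression:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r = pearson_with_regression(x, 2.0 * x + 1.0)
        assert r.pearson_r == pytest.approx(1.0)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)

    def test_anti_linear(self):
        x = np.arange(10.0)
        assert pearson_with_regression(x, -x).pearson_r == pytest.approx(-1.0)

    def test_five_point_hand_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        sxx = np.sum((x - x.mean()) ** 2)
        syy = np.sum((y - y.mean()) ** 2)
        r = pearson_with_regression(x, y)
        assert r.pearson_r == pytest.approx(sxy / math.sqrt(sxx * syy), abs=1e-12)
        assert r.slope == pytest.approx(sxy / sxx, abs=1e-12)
        assert r.intercept == pytest.approx(y.mean() - sxy / sxx * x.mean(), abs=1e-12)
        assert r.slope_ci_low < r.slope < r.slope_ci_high

    def test_zero_variance_x(self):
        with pytest.raises(ValueError):
            pearson_with_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestIcc:
    def test_duplicated_column_is_one(self):
        x = np.array([[1.0], [3.0], [2.0], [5.0], [4.0], [6.0]])
        r = icc_2_1(np.hstack([x, x]))
        assert r.icc == pytest.approx(1.0)

    def test_hand_sized_table_vs_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        subjects = rng.normal(10, 3, 12)
        mat = np.stack([subjects + rng.normal(0, 1, 12), subjects + rng.normal(0.5, 1, 12)], axis=1)
        r = icc_2_1(mat)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile(["a", "b"], 12),
                "score": mat.ravel(),
            }
        )
        oracle = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        icc2 = oracle.set_index("Type").loc["ICC(A,1)"]  # two-way random, absolute agreement, single
        assert r.icc == pytest.approx(float(icc2["ICC"]), abs=1e-6)
        lo, hi = icc2["CI95"]
        assert r.ci_low == pytest.approx(float(lo), abs=0.02)
        assert r.ci_high == pytest.approx(float(hi), abs=0.02)

    def test_mean_squares_oracle_6x2(self):
        # ANOVA decomposition written out by hand
        x = np.array([[9.0, 10.0], [6.0, 7.0], [8.0, 8.0], [7.0, 5.0], [10.0, 11.0], [6.0, 6.0]])
        n, k = x.shape
        msr = k * np.var(x.mean(axis=1), ddof=1)
        msc = n * np.var(x.mean(axis=0), ddof=1)
        sse = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + x.mean()) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_2_1(x).icc == pytest.approx(expected, abs=1e-12)

    def test_degenerate_and_shape_checks(self):
        with pytest.raises(ValueError):
            icc_2_1(np.full((6, 2), 3.0))
        with pytest.raises(ValueError):
            icc_2_1(np.ones((3, 2)))


class TestSampleSize:
    def test_reference_calculation(self):
        # n = 2 sigma^2 (z_{0.975} + z_{0.8})^2 / (mu1-mu2)^2, evaluated
        # independently: 2 * 7.84 * (1.95996 + 0.84162)^2 / 1.69 = 72.8 -> 73
        assert sample_size_two_means(3.8, 2.5, 2.8, power=0.80, alpha=0.05) == 73

    def test_doubling_sigma_quadruples_n(self):
        n1 = sample_size_two_means(3.8, 2.5, 2.8)
        n2 = sample_size_two_means(3.8, 2.5, 5.6)
        assert n2 in (4 * n1 - 1, 4 * n1, 4 * n1 + 1)  # up to rounding

    def test_monotonicity(self):
        assert sample_size_two_means(3.8, 2.5, 2.8, power=0.9) > sample_size_two_means(3.8, 2.5, 2.8, power=0.8)
        assert sample_size_two_means(3.8, 2.5, 2.8, alpha=0.01) > sample_size_two_means(3.8, 2.5, 2.8, alpha=0.05)
        assert sample_size_two_means(3.8, 2.5, 2.8, power=0.5) < sample_size_two_means(3.8, 2.5, 2.8, power=0.8)

    @pytest.mark.parametrize("kwargs", [{"mu2": 3.8}, {"sigma": 0.0}, {"power": 1.2}, {"alpha": 0.0}])
    def test_invalid_inputs(self, kwargs):
        base = dict(mu1=3.8, mu2=2.5, sigma=2.8, power=0.8, alpha=0.05)
        base.update(kwargs)
        with pytest.raises(ValueError):
            sample_size_two_means(**base)


class TestBattery:
    def test_sign_patterns_and_significance(self, small_cohort_table):
        report = run_paper_battery(small_cohort_table)
        avc = report["ais_vs_control"]
        thor = avc["thoracic_delta_ap_percent"]
        assert thor["group_means"][0] > 0 > thor["group_means"][1]
        assert thor["p_value"] < 0.001
        lum = avc["lumbar_delta_ap_percent"]
        assert lum["group_means"][0] > lum["group_means"][1] > 0
        paired = report["apical_vs_junctional"]["apical_thoracic_vs_proximal_junctional"]
        assert paired["p_value"] < 0.001
        coup = report["standing_cobb_couplings"]
        assert coup["axial_rotation"]["per_10_deg_cobb"] == pytest.approx(5.0, rel=0.35)
        assert coup["delta_ap"]["per_10_deg_cobb"] == pytest.approx(1.2, rel=0.35)
        assert coup["ct_cobb"]["pearson_r"] > 0.7

    def test_ais_only_partial_report(self, small_cohort_table):
        ais_only = small_cohort_table[small_cohort_table.group == "ais"]
        report = run_paper_battery(ais_only)
        assert "ais_vs_control" not in report
        assert any("skipped" in w for w in report["warnings"])

    def test_deterministic(self, small_cohort_table):
        import json

        a = json.dumps(run_paper_battery(small_cohort_table), sort_keys=True)
        b = json.dumps(run_paper_battery(small_cohort_table), sort_keys=True)
        assert a == b

    def test_normality_screen_reported_not_enforced(self, small_cohort_table):
        report = run_paper_battery(small_cohort_table)
        assert report["normality"]
        for entry in report["normality"].values():
            assert 0 <= entry["p_value"] <= 1 or math.isnan(entry["p_value"])

    def test_ks_normality_on_normal_data(self):
        rng = np.random.default_rng(4)
        out = ks_normality(rng.normal(0, 1, 200))
        assert out["p_value"] > 0.01
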