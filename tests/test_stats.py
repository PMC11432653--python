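"""Association battery: frozen hand-computed examples, identity oracles,
and null-distribution sanity checks."""
import itertools

import numpy as np
import pytest
from scipy import stats as sps

from ldlprs.stats import (auc_mann_whitney, extreme_percentile_comparison,
                          hosmer_lemeshow, jonckheere_terpstra,
                          linear_fit_standardized, logistic_fit, mann_whitney,
                          nested_model_compare, odds_ratio_2x2, roc_analysis,
                          spearman_corr)


class TestOddsRatio2x2:
    def test_no_association(self):
        res = odds_ratio_2x2(10, 10, 10, 10)
        assert res.estimate == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = odds_ratio_2x2(45, 80, 8, 89)
        assert res.estimate == pytest.approx(45 * 89 / (80 * 8))

    def test_zero_cell_triggers_haldane(self):
        res = odds_ratio_2x2(10, 5, 0, 8)
        assert res.extras["haldane_corrected"]
        assert np.isfinite(res.estimate)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(0, 0, 5, 5)

    def test_marginal_flag_band(self):
        res = odds_ratio_2x2(30, 20, 22, 28)
        assert (0.05 < res.p_value <= 0.15) == res.marginal


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(125), np.zeros(97)]
        fit = logistic_fit(y, {}, add_constant=True)
        assert fit.results["const"].extras["beta"] == pytest.approx(
            np.log(125 / 97), abs=1e-6)

    def test_saturated_2x2_equals_cross_product_or(self):
        a, b, c, d = 45, 80, 8, 89
        y = np.r_[np.ones(a + b), np.zeros(c + d)]
        x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        fit = logistic_fit(y, {"x": x})
        assert fit.results["x"].estimate == pytest.approx(
            odds_ratio_2x2(a, b, c, d).estimate, abs=1e-6)

    def test_coefficient_recovery_within_wald_ci(self):
        """The Wald CI covers the generating coefficient in ~95% of draws."""
        rng = np.random.default_rng(42)
        beta = 0.4
        hits = 0
        reps = 60
        for _ in range(reps):
            x = rng.standard_normal(2000)
            p = 1 / (1 + np.exp(-(-0.3 + beta * x)))
            y = (rng.random(2000) < p).astype(float)
            r = logistic_fit(y, {"x": x}).results["x"]
            hits += np.log(r.ci_low) <= beta <= np.log(r.ci_high)
        assert hits / reps >= 0.90

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(np.ones(20), {"x": np.arange(20.0)})

    def test_collinear_design_rejected(self):
        x = np.arange(30.0)
        y = (x > 15).astype(float)
        with pytest.raises(ValueError, match="rank"):
            logistic_fit(y, {"a": x, "b": 2 * x})

    def test_classification_metrics_on_separable_data(self):
        x = np.r_[np.zeros(50), np.ones(50)]
        y = x.copy()
        y[:2] = 1  # soften perfect separation
        fit = logistic_fit(y, {"x": x})
        assert fit.accuracy >= 0.9
        assert 0 <= fit.cox_snell_r2 <= 1


class TestHosmerLemeshow:
    def test_structural_df(self, rng):
        p = rng.uniform(0.1, 0.9, 500)
        y = (rng.random(500) < p).astype(float)
        res = hosmer_lemeshow(p, y, groups=10)
        assert res.extras["df"] == 8

    def test_calibrated_fitted_model_mean_statistic_near_df(self):
        """On correctly-specified fitted models the statistic is ~ chi2_{g-2}."""
        rng = np.random.default_rng(7)
        stats_ = []
        for _ in range(120):
            x = rng.standard_normal(1000)
            p = 1 / (1 + np.exp(-(0.1 + 0.7 * x)))
            y = (rng.random(1000) < p).astype(float)
            fit = logistic_fit(y, {"x": x})
            stats_.append(hosmer_lemeshow(fit.fittedvalues, y).estimate)
        assert np.mean(stats_) == pytest.approx(8.0, abs=1.2)

    def test_equal_probabilities_merge_to_zero(self):
        p = np.full(100, 0.3)
        y = np.r_[np.ones(30), np.zeros(70)]
        res = hosmer_lemeshow(p, y)
        assert res.estimate == pytest.approx(0.0, abs=1e-9)


class TestNestedCompare:
    @staticmethod
    def _simulate(rng, beta2=0.0, n=800):
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(0.2 + 0.8 * x1 + beta2 * x2)))
        y = (rng.random(n) < p).astype(float)
        small = logistic_fit(y, {"x1": x1})
        large = logistic_fit(y, {"x1": x1, "x2": x2})
        return small, large

    def test_identical_models_give_null_result(self, rng):
        small, _ = self._simulate(rng)
        res = nested_model_compare(small, small)
        assert res.estimate == 0.0
        assert res.p_value == 1.0

    def test_true_covariate_detected(self):
        rng = np.random.default_rng(99)
        detected = 0
        for _ in range(20):
            small, large = self._simulate(rng, beta2=0.6)
            detected += nested_model_compare(small, large).p_value < 0.001
        assert detected >= 19

    def test_non_nested_rejected(self, rng):
        small, large = self._simulate(rng)
        with pytest.raises(ValueError):
            nested_model_compare(large, small)

    def test_reports_both_aucs_and_f_form(self, rng):
        small, large = self._simulate(rng, beta2=0.5)
        res = nested_model_compare(small, large)
        assert 0.5 < res.extras["auc_small"] <= res.extras["auc_large"] <= 1.0
        assert res.extras["F"] >= 0


class TestLinearFit:
    def test_identity_slope(self, rng):
        x = rng.standard_normal(50)
        res = linear_fit_standardized(x, x)
        assert res.estimate == pytest.approx(1.0)

    def test_standardized_beta_equals_pearson_r(self, rng):
        x = rng.standard_normal(200)
        y = 0.5 * x + rng.standard_normal(200)
        res = linear_fit_standardized(y, x)
        assert res.estimate == pytest.approx(sps.pearsonr(x, y)[0], abs=1e-12)

    def test_null_slope_within_two_se(self):
        rng = np.random.default_rng(17)
        x, y = rng.standard_normal((2, 1000))
        res = linear_fit_standardized(y, x)
        assert abs(res.estimate) <= 2 * res.extras["se"]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            linear_fit_standardized([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestSpearman:
    def test_hand_ranked_example(self):
        # d^2 = (1,1,1,1,0) -> rho = 1 - 6*4/(5*24) = 0.8
        res = spearman_corr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.estimate == pytest.approx(0.8)

    def test_monotone_transform_gives_one(self, rng):
        x = rng.standard_normal(30)
        res = spearman_corr(x, np.exp(x))
        assert res.estimate == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        res = spearman_corr([1, 2, 3, 4], [9, 7, 5, 3])
        assert res.estimate == pytest.approx(-1.0)


class TestMannWhitney:
    def test_fully_separated_tiny_groups_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        # U for the first sample = 0; exact two-sided p = 2 * 1/C(6,3)
        assert res.estimate == 0.0
        assert res.p_value == pytest.approx(2 / 20)
        assert "exact" in res.test_name

    def test_identical_groups_near_null(self, rng):
        a = rng.standard_normal(40)
        res = mann_whitney(a, a.copy())
        assert res.estimate == pytest.approx(40 * 40 / 2)
        assert res.p_value > 0.9

    def test_single_observations(self):
        res = mann_whitney([1.0], [2.0])
        assert res.estimate == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestJonckheereTerpstra:
    def test_two_groups_reduce_to_mann_whitney(self, rng):
        a, b = rng.standard_normal(20), rng.standard_normal(25) + 0.3
        jt = jonckheere_terpstra([a, b])
        # JT counts (a < b) pairs; scipy's U counts (a > b) pairs
        mw = mann_whitney(a, b)
        assert jt.estimate == pytest.approx(20 * 25 - mw.estimate)

    def test_perfectly_ordered_groups_attain_maximum(self):
        jt = jonckheere_terpstra([(1, 2), (3, 4), (5, 6)],
                                 alternative="increasing", seed=0)
        assert jt.estimate == 12.0
        assert "permutation" in jt.test_name  # group n < 5
        assert jt.p_value < 0.03  # exact one-sided p is 1/90

    def test_permutation_p_matches_exhaustive_enumeration(self):
        pooled = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 2.0])
        groups = [pooled[:2], pooled[2:4], pooled[4:]]
        obs = jonckheere_terpstra(groups, alternative="increasing",
                                  permutations=20_000, seed=5)
        # enumerate every assignment of the pooled values to the group sizes
        jts = []
        idx = set(range(6))
        for g1 in itertools.combinations(range(6), 2):
            rest = idx - set(g1)
            for g2 in itertools.combinations(sorted(rest), 2):
                g3 = tuple(sorted(rest - set(g2)))
                parts = [pooled[list(g)] for g in (g1, g2, g3)]
                from ldlprs.stats import _jt_statistic
                jts.append(_jt_statistic(parts))
        exact_p = np.mean([j >= obs.estimate - 1e-12 for j in jts])
        assert obs.p_value == pytest.approx(exact_p, abs=0.02)

    def test_normal_and_permutation_p_agree_for_moderate_groups(self):
        rng = np.random.default_rng(13)
        groups = [rng.standard_normal(15) + 0.2 * i for i in range(3)]
        norm = jonckheere_terpstra(groups, alternative="two-sided")
        perm = jonckheere_terpstra(groups, alternative="two-sided",
                                   force_permutation=True,
                                   permutations=20_000, seed=3)
        assert norm.p_value == pytest.approx(perm.p_value, abs=0.02)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([[1.0, 2.0]])


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == 1.0
        assert roc.operating_sensitivity == 1.0
        assert roc.operating_specificity == 1.0

    def test_auc_equals_rank_sum_identity(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = rng.integers(20, 80)
            s = rng.standard_normal(n)
            y = (rng.random(n) < 0.4).astype(int)
            if y.sum() in (0, n):
                continue
            roc = roc_analysis(s, y)
            assert roc.auc == pytest.approx(auc_mann_whitney(s, y), abs=1e-12)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        s = rng.standard_normal(300)
        y = (rng.random(300) < 0.5).astype(int)
        roc = roc_analysis(s, y)
        assert roc.auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_delong_ci_covers_null_auc(self):
        """Under label independence the DeLong 95% CI should cover 0.5 at
        close to the nominal rate."""
        rng = np.random.default_rng(8)
        covered = 0
        reps = 150
        for _ in range(reps):
            s = rng.standard_normal(400)
            y = (rng.random(400) < 0.5).astype(int)
            roc = roc_analysis(s, y)
            covered += roc.auc_ci[0] <= 0.5 <= roc.auc_ci[1]
        assert covered / reps >= 0.90

    def test_monotone_transform_invariance(self, rng):
        s = rng.standard_normal(200)
        y = (rng.random(200) < 0.3).astype(int)
        a = roc_analysis(s, y)
        b = roc_analysis(np.exp(2 * s), y)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.operating_sensitivity == pytest.approx(b.operating_sensitivity)

    def test_full_sensitivity_screening_threshold(self, rng):
        s = rng.standard_normal(300)
        y = (s + 0.5 * rng.standard_normal(300) > 0.8).astype(int)
        roc = roc_analysis(s, y, criterion="sensitivity", target_sensitivity=1.0)
        assert roc.operating_sensitivity == 1.0
        assert roc.operating_threshold < s[y == 1].min()

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], [1, 1])


class TestExtremePercentiles:
    def test_risk_ratio_arithmetic(self):
        scores = np.r_[np.zeros(20), np.ones(20) * 10]
        outcome = np.r_[(np.arange(20) < 5).astype(int),  # 25% in bottom tail
                        (np.arange(20) < 15).astype(int)]  # 75% in top tail
        res = extreme_percentile_comparison(scores, outcome, 50, 50)
        assert res.estimate == pytest.approx(3.0)

    def test_identical_tails_null(self):
        scores = np.arange(100.0)
        outcome = np.tile([0, 1], 50)
        res = extreme_percentile_comparison(scores, outcome, 90, 10)
        assert res.estimate == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)
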