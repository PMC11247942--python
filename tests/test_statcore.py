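"""Statistical primitives checked against closed forms, brute-force
enumeration, and independent reference implementations."""

import math

import numpy as np
import pytest
from scipy import stats

from rectalresponse import statcore as sc


def brute_force_fisher(a, b, c, d):
    """Two-sided Fisher p by exact enumeration of the hypergeometric
    support with rational arithmetic (independent of the implementation)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    total = math.comb(n, c1)
    probs = {x: math.comb(r1, x) * math.comb(n - r1, c1 - x) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs) / total


class TestFisherExact:
    @pytest.mark.parametrize("table,p_expected,or_expected", [
        ((3, 1, 1, 3), 34 / 70, 9.0),           # enumerated over X in 0..4
        ((5, 5, 5, 5), 1.0, 1.0),
        ((10, 0, 0, 10), 2 / 184756, (10.5 * 10.5) / (0.5 * 0.5)),
    ])
    def test_known_tables(self, table, p_expected, or_expected):
        res = sc.fisher_exact_2x2(sc.ContingencyTable2x2(*table))
        assert res.p_value == pytest.approx(p_expected, rel=1e-12)
        assert res.estimate == pytest.approx(or_expected)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 61))
            cells = rng.multinomial(n, [0.25] * 4)
            a, b, c, d = (int(x) for x in cells)
            res = sc.fisher_exact_2x2(sc.ContingencyTable2x2(a, b, c, d))
            assert res.p_value == pytest.approx(
                brute_force_fisher(a, b, c, d), rel=1e-9)

    def test_all_zero_table_rejected(self):
        with pytest.raises(sc.DegenerateInputError):
            sc.ContingencyTable2x2(0, 0, 0, 0)

    def test_haldane_only_with_zero_cell(self):
        with_zero = sc.fisher_exact_2x2(sc.ContingencyTable2x2(5, 0, 2, 7))
        assert with_zero.estimate == pytest.approx((5.5 * 7.5) / (0.5 * 2.5))
        no_zero = sc.fisher_exact_2x2(sc.ContingencyTable2x2(6, 2, 3, 7))
        assert no_zero.estimate == pytest.approx(42 / 6)


class TestChi2Yates:
    def test_zero_association(self):
        res = sc.chi2_yates(sc.ContingencyTable2x2(10, 10, 10, 10))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_correction(self):
        # O/E arithmetic done independently of the implementation
        a, b, c, d = 20, 5, 5, 20
        n = 50
        exp = np.outer([25, 25], [25, 25]) / n
        obs = np.array([[a, b], [c, d]], float)
        stat = (((np.abs(obs - exp) - 0.5) ** 2) / exp).sum()
        res = sc.chi2_yates(sc.ContingencyTable2x2(a, b, c, d))
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(stats.chi2.sf(stat, 1))

    def test_zero_margin_rejected(self):
        with pytest.raises(sc.DegenerateInputError):
            sc.chi2_yates(sc.ContingencyTable2x2(0, 0, 5, 5))


class TestBHAdjust:
    @pytest.mark.parametrize("p_in,p_out", [
        ([0.05], [0.05]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),  # step-up by hand, m=3
        ([1.0, 1.0], [1.0, 1.0]),
    ])
    def test_known_vectors(self, p_in, p_out):
        assert sc.bh_adjust(p_in) == pytest.approx(p_out)

    def test_monotone_on_sorted_input(self, rng):
        p = np.sort(rng.random(25))
        q = sc.bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-15)
        assert np.all((q >= 0) & (q <= 1))

    def test_dominates_input_and_preserves_ranks(self, rng):
        p = rng.random(40)
        q = sc.bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        # monotone when walked in ascending-p order (ties may flatten)
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-15)

    def test_fixed_point_vectors(self):
        # constant vectors are BH fixed points
        for v in ([1.0, 1.0, 1.0], [0.2, 0.2], [0.0]):
            assert sc.bh_adjust(v) == pytest.approx(v)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sc.bh_adjust([0.5, 1.5])


class TestWeightedTTest:
    def test_identical_groups(self):
        g = sc.WeightedSampleSet.unit([1.0, 2.0, 3.0])
        res = sc.weighted_ttest(g, g)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_unit_weights_reduce_to_welch(self, rng):
        for _ in range(100):
            x = rng.normal(0, 1, int(rng.integers(5, 40)))
            y = rng.normal(0.3, 1.5, int(rng.integers(5, 40)))
            res = sc.weighted_ttest(sc.WeightedSampleSet.unit(x),
                                    sc.WeightedSampleSet.unit(y))
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_mean_difference_estimate(self):
        g1 = sc.WeightedSampleSet(np.array([2.0, 2.0]), np.array([1.0, 1.0]))
        g0 = sc.WeightedSampleSet(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        assert sc.weighted_ttest(g1, g0).estimate == pytest.approx(1.0)

    def test_weight_rescaling_invariance(self, rng):
        x, y = rng.normal(size=12), rng.normal(0.5, 1, 15)
        wx, wy = rng.uniform(0.2, 2, 12), rng.uniform(0.2, 2, 15)
        a = sc.weighted_ttest(sc.WeightedSampleSet(x, wx),
                              sc.WeightedSampleSet(y, wy))
        b = sc.weighted_ttest(sc.WeightedSampleSet(x, 3.7 * wx),
                              sc.WeightedSampleSet(y, 3.7 * wy))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)


class TestLogisticMLE:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = sc.logistic_mle(np.ones((100, 1)), y)
        assert fit.coefficients[0] == pytest.approx(math.log(30 / 70), abs=1e-8)
        assert fit.converged

    def test_saturated_2x2_closed_form(self):
        # exposure/outcome table a=8 b=2 c=4 d=6 -> slope log(6)
        x = np.r_[np.ones(10), np.zeros(10)]
        y = np.r_[np.ones(8), np.zeros(2), np.ones(4), np.zeros(6)]
        fit = sc.logistic_mle(np.column_stack([np.ones(20), x]), y)
        assert fit.coefficients[1] == pytest.approx(math.log(6.0), abs=1e-7)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        X = np.column_stack([np.ones(200), rng.normal(size=200),
                             rng.binomial(1, 0.4, 200)])
        eta = -0.5 + 0.8 * X[:, 1] - 0.6 * X[:, 2]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        fit = sc.logistic_mle(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert fit.coefficients == pytest.approx(ref.params, abs=1e-6)
        assert fit.standard_errors == pytest.approx(ref.bse, rel=1e-4)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)
        assert fit.aic == pytest.approx(ref.aic, abs=1e-5)

    def test_recovers_simulation_truth(self, rng):
        X = np.column_stack([np.ones(500), rng.normal(size=500)])
        y = rng.binomial(1, 1 / (1 + np.exp(-(-1 + 0.8 * X[:, 1]))))
        fit = sc.logistic_mle(X, y)
        for j, truth in enumerate((-1.0, 0.8)):
            assert abs(fit.coefficients[j] - truth) < 2 * fit.standard_errors[j]

    def test_local_maximum_property(self, rng):
        X = np.column_stack([np.ones(80), rng.normal(size=80)])
        y = rng.binomial(1, 0.4, 80)
        fit = sc.logistic_mle(X, y)

        def loglik(beta):
            p = np.clip(1 / (1 + np.exp(-X @ beta)), 1e-12, 1 - 1e-12)
            return (y * np.log(p) + (1 - y) * np.log(1 - p)).sum()

        best = loglik(fit.coefficients)
        for _ in range(25):
            d = rng.normal(size=2)
            d *= 0.01 / np.linalg.norm(d)
            assert loglik(fit.coefficients + d) <= best + 1e-12

    def test_separation_flagged(self):
        x = np.r_[np.ones(10), np.zeros(10)]
        y = x.copy()
        with pytest.warns(sc.SeparationWarning):
            fit = sc.logistic_mle(np.column_stack([np.ones(20), x]), y)
        assert not fit.converged

    def test_rank_deficiency_names_column(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        y = rng.binomial(1, 0.5, 50)
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            sc.logistic_mle(X, y, column_names=["intercept", "x", "dup"])

    def test_aic_identity(self, rng):
        X = np.column_stack([np.ones(60), rng.normal(size=60)])
        y = rng.binomial(1, 0.5, 60)
        fit = sc.logistic_mle(X, y)
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.log_likelihood)


class TestTjurR2:
    def _fit(self, probs):
        f = sc.LogisticFit(np.zeros(1), np.zeros(1), 0.0, 2.0, len(probs),
                           True, np.asarray(probs, float))
        return f

    def test_perfect_discrimination(self):
        y = np.array([1, 1, 0, 0])
        assert sc.tjur_r2(self._fit([1, 1, 0, 0]), y) == pytest.approx(1.0)

    def test_no_discrimination(self):
        y = np.array([1, 0, 1, 0])
        assert sc.tjur_r2(self._fit([0.4] * 4), y) == pytest.approx(0.0)

    def test_arithmetic_of_means(self):
        y = np.array([1, 1, 0, 0])
        assert sc.tjur_r2(self._fit([0.8, 0.6, 0.2, 0.4]), y) == pytest.approx(0.4)

    def test_reordering_invariance(self, rng):
        y = rng.binomial(1, 0.5, 30)
        p = rng.random(30)
        perm = rng.permutation(30)
        assert sc.tjur_r2(self._fit(p), y) == pytest.approx(
            sc.tjur_r2(self._fit(p[perm]), y[perm]))

    def test_single_class_rejected(self):
        with pytest.raises(sc.DegenerateInputError):
            sc.tjur_r2(self._fit([0.5, 0.5]), np.ones(2))


class TestStandardizedDifference:
    def test_identical_groups(self):
        g = sc.WeightedSampleSet.unit([1.0, 2.0, 3.0])
        assert sc.standardized_difference(g, g) == 0.0

    def test_unit_gap_unit_variance(self):
        s = 1 / math.sqrt(2)  # two-point samples with unbiased variance 1
        g1 = sc.WeightedSampleSet.unit([1 - s, 1 + s])
        g0 = sc.WeightedSampleSet.unit([-s, s])
        assert sc.standardized_difference(g1, g0) == pytest.approx(100.0)

    def test_weight_scale_invariance(self, rng):
        x, y = rng.normal(size=15), rng.normal(0.4, 1, 18)
        wx, wy = rng.uniform(0.5, 2, 15), rng.uniform(0.5, 2, 18)
        a = sc.standardized_difference(sc.WeightedSampleSet(x, wx),
                                       sc.WeightedSampleSet(y, wy))
        b = sc.standardized_difference(sc.WeightedSampleSet(x, 5 * wx),
                                       sc.WeightedSampleSet(y, 5 * wy))
        assert a == pytest.approx(b)

    def test_binary_uses_bernoulli_variance(self):
        g1 = sc.WeightedSampleSet.unit([1, 1, 1, 0])
        g0 = sc.WeightedSampleSet.unit([1, 0, 0, 0])
        p1, p0 = 0.75, 0.25
        expected = 100 * abs(p1 - p0) / math.sqrt(
            (p1 * (1 - p1) + p0 * (1 - p0)) / 2)
        assert sc.standardized_difference(g1, g0) == pytest.approx(expected)

    def test_degenerate_unequal_means(self):
        g1 = sc.WeightedSampleSet.unit([2.0, 2.0])
        g0 = sc.WeightedSampleSet.unit([1.0, 1.0])
        assert sc.standardized_difference(g1, g0) == math.inf
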