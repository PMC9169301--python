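import numpy as np
import pytest

from fdacbr.curves import RiskCurve, RiskSeries, fit_risk_curve
from fdacbr.similarity import (
    IncomparableCasesError,
    actual_distance,
    decayed_aggregate,
    derivative_distance,
    distance_to_similarity,
    interval_combined,
    overlap_intervals,
    pairwise_similarity,
)


def constant(value, lo=0.0, hi=1.0):
    return RiskCurve(np.array([lo, hi]), 1, np.array([float(value)]))


def line(intercept, slope, lo=0.0, hi=1.0):
    return RiskCurve(np.array([lo, lo, hi, hi]), 2,
                     np.array([intercept + slope * lo, intercept + slope * hi]))


def random_cubic(seed, lo=1.0, hi=20.0):
    rng = np.random.default_rng(seed)
    t = np.arange(lo, hi + 1)
    y = rng.normal(0.0, 0.3, len(t))
    return fit_risk_curve(RiskSeries(f"c{seed}", t, y), order=4, max_basis=8)


def trapezoid_oracle(f, g, lo, hi, n=10_000, derivative=False):
    t = np.linspace(lo, hi, n)
    if derivative:
        f, g = f.derivative(), g.derivative()
    return float(np.sqrt(np.trapezoid((f(t) - g(t)) ** 2, t)))


class TestActualDistance:
    def test_identical_curves_have_zero_distance(self):
        c = random_cubic(0)
        assert actual_distance(c, c, (2, 9)) == pytest.approx(0.0, abs=1e-12)

    def test_constants_three_and_five_on_unit_interval(self):
        assert actual_distance(constant(3), constant(5), (0, 1)) == pytest.approx(2.0)

    def test_matches_dense_trapezoid_oracle(self):
        a, b = random_cubic(1), random_cubic(2)
        for lo, hi in [(1, 2), (4, 9), (1, 20)]:
            got = actual_distance(a, b, (lo, hi))
            assert got == pytest.approx(trapezoid_oracle(a, b, lo, hi), abs=1e-6)

    def test_interval_outside_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            actual_distance(constant(1), constant(2), (0.5, 1.5))

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            actual_distance(constant(1), constant(2), (0.7, 0.7))


class TestDerivativeDistance:
    def test_parallel_constants_have_zero_trend_distance(self):
        assert derivative_distance(constant(3), constant(5), (0, 1)) == 0.0

    def test_lines_with_slopes_one_and_three(self):
        got = derivative_distance(line(0, 1), line(5, 3), (0, 1))
        assert got == pytest.approx(2.0)

    def test_matches_dense_trapezoid_oracle(self):
        a, b = random_cubic(3), random_cubic(4)
        got = derivative_distance(a, b, (3, 11))
        assert got == pytest.approx(
            trapezoid_oracle(a, b, 3, 11, derivative=True), abs=1e-6)


class TestMetricProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_and_nonnegativity(self, seed):
        a, b = random_cubic(seed), random_cubic(seed + 50)
        iv = (2, 7)
        for dist in (actual_distance, derivative_distance):
            d_ab, d_ba = dist(a, b, iv), dist(b, a, iv)
            assert d_ab == pytest.approx(d_ba, rel=1e-12)
            assert d_ab >= 0

    def test_distinct_curves_have_positive_distance(self):
        a, b = random_cubic(7), random_cubic(8)
        assert actual_distance(a, b, (1, 20)) > 0


class TestIntervalCombined:
    def test_theta_one_keeps_only_the_actual_distance(self):
        assert interval_combined(1.0, 2.0, 1.0) == 1.0

    def test_theta_zero_keeps_only_the_trend_distance(self):
        assert interval_combined(1.0, 2.0, 0.0) == 2.0

    def test_selected_influence_factor(self):
        assert interval_combined(1.0, 2.0, 0.6) == pytest.approx(1.4)

    @pytest.mark.parametrize("theta", [-0.1, 1.1])
    def test_theta_outside_unit_interval_rejected(self, theta):
        with pytest.raises(ValueError, match="theta"):
            interval_combined(1.0, 2.0, theta)


class TestDecayedAggregate:
    def test_hand_computed_geometric_decay(self):
        assert decayed_aggregate([1, 2, 3], 0.5) == pytest.approx(4.25)

    def test_zero_decay_keeps_only_the_most_recent(self):
        assert decayed_aggregate([1, 2, 3], 0.0) == 3.0

    def test_unit_decay_is_a_plain_sum(self):
        assert decayed_aggregate([1, 2, 3], 1.0) == 6.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            decayed_aggregate([], 0.5)

    def test_decay_factor_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="mu"):
            decayed_aggregate([1.0], 1.5)

    def test_bounded_by_max_value_when_normalized(self):
        v = np.array([0.2, 0.9, 0.4, 0.7])
        mu = 0.8
        mass = np.power(mu, np.arange(len(v) - 1, -1, -1))
        normalized = decayed_aggregate(v, mu) / mass.sum()
        assert normalized <= v.max() + 1e-12


class TestPairwiseSimilarity:
    def test_self_similarity_is_one_hundred_percent(self):
        c = random_cubic(11)
        res = pairwise_similarity(c, c)
        assert res.percent == pytest.approx(100.0)
        assert np.allclose(res.d_act, 0.0) and np.allclose(res.d_der, 0.0)

    def test_symmetric_under_argument_swap(self):
        a, b = random_cubic(12), random_cubic(13, lo=4.0, hi=17.0)
        r1, r2 = pairwise_similarity(a, b), pairwise_similarity(b, a)
        assert r1.percent == pytest.approx(r2.percent, rel=1e-12)
        assert r1.intervals == r2.intervals

    def test_composition_matches_the_individual_operations(self):
        """The pipeline result must equal the four stages run independently."""
        a, b = random_cubic(14), random_cubic(15, lo=3.0, hi=18.0)
        theta, mu, s0 = 0.6, 0.8, 1.3
        res = pairwise_similarity(a, b, theta=theta, mu=mu, s0=s0)
        intervals = overlap_intervals(a, b)
        d_act = [actual_distance(a, b, iv, length_normalized=True)
                 for iv in intervals]
        d_der = [derivative_distance(a, b, iv, length_normalized=True)
                 for iv in intervals]
        combined = [interval_combined(x, y, theta) for x, y in zip(d_act, d_der)]
        assert np.allclose(res.combined, combined)
        assert res.raw_aggregate == pytest.approx(decayed_aggregate(combined, mu))
        sims = distance_to_similarity(np.array(combined), s0)
        mass = np.power(mu, np.arange(len(sims) - 1, -1, -1))
        assert res.similarity == pytest.approx(float(sims @ mass / mass.sum()))

    def test_partial_intervals_are_clipped_and_length_normalized(self):
        a = constant(3.0, lo=1.5, hi=3.5)
        b = constant(5.0, lo=1.0, hi=4.0)
        res = pairwise_similarity(a, b)
        assert res.intervals == [(1.5, 2.0), (2.0, 3.0), (3.0, 3.5)]
        # RMS distance between the constants is 2 on full and partial intervals
        assert np.allclose(res.d_act, 2.0)

    def test_disjoint_supports_are_incomparable_not_zero(self):
        a = constant(1.0, lo=1.0, hi=5.0)
        b = constant(1.0, lo=9.0, hi=12.0)
        with pytest.raises(IncomparableCasesError):
            pairwise_similarity(a, b)

    def test_similarity_decreases_when_any_interval_distance_grows(self):
        base = constant(0.0, lo=1.0, hi=4.0)
        mild = constant(0.5, lo=1.0, hi=4.0)
        strong = constant(1.5, lo=1.0, hi=4.0)
        s_mild = pairwise_similarity(base, mild).similarity
        s_strong = pairwise_similarity(base, strong).similarity
        assert s_strong < s_mild < 1.0

    def test_registration_shift_is_honoured(self):
        c = random_cubic(16)
        shifted = RiskCurve(c.knots, c.order, c.coef, delta=1.0)
        res = pairwise_similarity(c, shifted, use_delta=True)
        # the effective support of the shifted copy moves one slot earlier
        assert res.intervals[0][0] >= 1.0
        assert res.intervals[-1][1] <= c.support[1]
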