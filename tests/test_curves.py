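import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.interpolate import BSpline

from fdacbr.curves import (
    RiskCurve,
    RiskSeries,
    bspline_basis,
    fit_risk_curve,
    register_curves,
    risk_series,
    risk_value,
)
from fdacbr.encoding import ExamRecord
from fdacbr.weights import WeightVector, load_published_weights


class TestRiskValue:
    def test_zero_vector_scores_zero(self):
        w = WeightVector(names=tuple("abcd"), values=np.full(4, 0.25))
        assert risk_value(np.zeros(4), w) == 0.0

    def test_all_ones_with_normalized_weights_scores_one(self):
        w = WeightVector(names=tuple("abcd"), values=np.array([0.1, 0.2, 0.3, 0.4]))
        assert risk_value(np.ones(4), w) == pytest.approx(1.0)

    def test_reference_weights_hand_dot_product(self):
        """Age code 2 and diabetes present, all else zero: 2*0.301 + 0.152."""
        w = load_published_weights()
        x = np.zeros(len(w))
        x[w.names.index("age")] = 2
        x[w.names.index("diabetes")] = 1
        assert risk_value(x, w) == pytest.approx(0.754)

    @given(st.floats(min_value=-5, max_value=5, allow_nan=False))
    def test_linearity_in_the_input(self, alpha):
        w = np.array([0.5, 0.3, 0.2])
        x = np.array([1.0, 2.0, 3.0])
        assert risk_value(alpha * x, w) == pytest.approx(alpha * risk_value(x, w))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            risk_value(np.ones(3), np.ones(4))


class TestRiskSeries:
    def _exam(self, t, risk):
        return ExamRecord("r", t, {}, np.array([risk]), 0)

    def test_series_is_time_ordered_regardless_of_input_order(self):
        w = np.array([1.0])
        exams = [self._exam(t, r) for t, r in [(5, 2.0), (1, 1.0), (3, 3.0)]]
        s = risk_series(exams, w)
        assert s.times.tolist() == [1.0, 3.0, 5.0]
        assert s.risks.tolist() == [1.0, 3.0, 2.0]
        s2 = risk_series(exams[::-1], w)
        assert np.array_equal(s.risks, s2.risks)

    def test_single_exam_series(self):
        s = risk_series([self._exam(4, 7.0)], np.array([1.0]))
        assert len(s) == 1 and s.risks[0] == 7.0

    def test_reference_trajectory_scores(self, reference_series):
        """Identity weights on a 1-D code reproduce the printed trajectory."""
        exams = [self._exam(int(t), r) for t, r in
                 zip(reference_series.times, reference_series.risks)]
        s = risk_series(exams, np.array([1.0]))
        assert np.allclose(s.risks, reference_series.risks)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            RiskSeries("x", np.array([1.0, 1.0]), np.array([0.0, 1.0]))


class TestBasis:
    def test_order_one_is_the_interval_indicator(self):
        knots = np.array([0.0, 1.0, 2.0, 3.0])
        B = bspline_basis(knots, 1, np.array([0.5, 1.0, 1.5, 2.5]))
        assert B.shape == (4, 3)
        assert B[0].tolist() == [1, 0, 0]
        assert B[1].tolist() == [0, 1, 0]   # right-continuous at interior knots
        assert B[2].tolist() == [0, 1, 0]
        assert B[3].tolist() == [0, 0, 1]

    @pytest.mark.parametrize("order", [1, 2, 3, 4])
    def test_partition_of_unity_and_nonnegativity(self, order):
        rng = np.random.default_rng(0)
        interior = np.array([1.3, 2.0, 4.1])
        knots = np.r_[np.zeros(order), interior, np.full(order, 5.0)]
        t = np.r_[rng.uniform(0.0, 5.0, 1000), 0.0, 5.0, interior]
        B = bspline_basis(knots, order, t)
        assert np.all(B >= 0)
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_local_support(self):
        knots = np.r_[np.zeros(4), [1.0, 2.0, 3.0], np.full(4, 4.0)]
        t = np.linspace(0, 4, 201)
        B = bspline_basis(knots, 4, t)
        for i in range(B.shape[1]):
            lo, hi = knots[i], knots[i + 4]
            outside = (t < lo) | (t > hi)
            assert np.allclose(B[outside, i], 0.0)

    def test_matches_independent_cubic_recursion(self):
        """Cross-check the Cox-de Boor values against scipy's B-spline."""
        rng = np.random.default_rng(1)
        knots = np.r_[np.zeros(4), np.sort(rng.uniform(0.2, 3.8, 3)), np.full(4, 4.0)]
        c = rng.normal(size=len(knots) - 4)
        t = rng.uniform(0, 4, 200)
        mine = bspline_basis(knots, 4, t) @ c
        assert np.allclose(mine, BSpline(knots, c, 3)(t), atol=1e-12)

    def test_out_of_span_evaluation_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            bspline_basis(np.array([0.0, 1.0]), 1, 1.5)

    def test_decreasing_knots_rejected(self):
        with pytest.raises(ValueError, match="nondecreasing"):
            bspline_basis(np.array([1.0, 0.0]), 1, 0.5)


class TestFit:
    def test_exact_recovery_of_cubic_data(self):
        t = np.linspace(1, 10, 12)
        y = 0.3 * t**3 - t**2 + 2 * t - 5
        curve = fit_risk_curve(RiskSeries("c", t, y), order=4, knots=4)
        assert curve.smsse < 1e-8
        assert np.allclose(curve(t), y, atol=1e-6)

    def test_interpolating_fit_reproduces_the_data(self, reference_series):
        curve = fit_risk_curve(reference_series, knots="interpolating")
        assert curve.smsse < 1e-8

    def test_smsse_matches_normal_equations_oracle(self, reference_series):
        """Least-squares objective vs an independent dense solver."""
        curve = fit_risk_curve(reference_series, order=4, knots=6)
        t, y = reference_series.times, reference_series.risks
        A = np.array([
            BSpline.basis_element(curve.knots[i:i + 5], extrapolate=False)(t)
            for i in range(len(curve.coef))
        ]).T
        A = np.nan_to_num(A)
        A[-1, -1] = 1.0  # closed right endpoint of the clamped basis
        coef = np.linalg.solve(A.T @ A, A.T @ y)
        oracle_smsse = float(np.sum((y - A @ coef) ** 2))
        assert curve.smsse == pytest.approx(oracle_smsse, abs=1e-8)

    def test_fit_never_beaten_by_random_probes(self, reference_series):
        curve = fit_risk_curve(reference_series, order=4, knots=5)
        rng = np.random.default_rng(3)
        B = bspline_basis(curve.knots, curve.order, reference_series.times)
        for _ in range(200):
            probe = curve.coef + rng.normal(0, 0.5, size=curve.coef.shape)
            probe_smsse = np.sum((reference_series.risks - B @ probe) ** 2)
            assert curve.smsse <= probe_smsse + 1e-12

    def test_underdetermined_fit_instructs_reduction(self):
        s = RiskSeries("s", np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 1.0]))
        with pytest.raises(ValueError, match="reduce"):
            fit_risk_curve(s, order=4, knots=5)

    def test_short_series_fall_back_gracefully(self):
        one = fit_risk_curve(RiskSeries("a", np.array([4.0]), np.array([2.0])))
        assert one(4.0) == pytest.approx(2.0)
        two = fit_risk_curve(
            RiskSeries("b", np.array([1.0, 3.0]), np.array([1.0, 5.0])))
        assert two(2.0) == pytest.approx(3.0)  # straight line between the exams

    def test_auto_mode_never_interpolates_longer_series(self, reference_series):
        curve = fit_risk_curve(reference_series)
        assert len(curve.coef) < len(reference_series)
        assert curve.smsse > 0


class TestDerivative:
    def test_derivative_matches_scipy(self, reference_series):
        curve = fit_risk_curve(reference_series, order=4, knots=6)
        t = np.linspace(11, 20, 101)
        mine = curve.derivative()(t)
        ref = BSpline(curve.knots, curve.coef, 3).derivative()(t)
        assert np.allclose(mine, ref, atol=1e-10)

    def test_constant_curve_has_zero_derivative(self):
        c = RiskCurve(np.array([0.0, 2.0]), 1, np.array([3.0]))
        assert np.allclose(c.derivative()(np.array([0.5, 1.5])), 0.0)


class TestRegistration:
    def _curve(self, shift=0.0, seed=0):
        t = np.arange(1.0, 21.0)
        y = np.sin((t - shift) / 3.0) + 0.1 * np.cos((t - shift) / 1.7)
        return fit_risk_curve(RiskSeries(f"s{shift}", t, y), max_basis=8)

    def test_identical_curves_stay_unshifted(self):
        reg = register_curves([self._curve(), self._curve(), self._curve()])
        assert np.allclose(reg.deltas, 0.0)

    def test_exact_shift_recovered_against_grid_oracle(self):
        base = self._curve()
        shifted = RiskCurve(base.knots + 1.2, base.order, base.coef)
        reg = register_curves([base, shifted])
        recovered = reg.deltas[1] - reg.deltas[0]
        # brute-force grid search over the relative shift
        lo = max(base.support[0], shifted.support[0])
        hi = min(base.support[1], shifted.support[1])
        grid = np.linspace(lo + 2.0, hi - 2.0, 101)
        deltas = np.linspace(-2.0, 2.0, 401)
        objective = [
            float(np.mean((base.eval_clamped(grid, use_delta=False)
                           - shifted.eval_clamped(grid + d, use_delta=False)) ** 2))
            for d in deltas
        ]
        oracle = deltas[int(np.argmin(objective))]
        assert recovered == pytest.approx(oracle, abs=0.05)
        assert recovered == pytest.approx(1.2, abs=0.05)

    def test_regsse_never_increases(self):
        rng = np.random.default_rng(5)
        curves = []
        for i in range(6):
            t = np.arange(1.0, 21.0)
            y = np.sin((t - rng.uniform(-1, 1)) / 3.0) + rng.normal(0, 0.05, 20)
            curves.append(fit_risk_curve(RiskSeries(f"r{i}", t, y), max_basis=8))
        reg = register_curves(curves)
        assert all(a >= b - 1e-9 for a, b in zip(reg.regsse, reg.regsse[1:]))

    def test_disjoint_supports_rejected(self):
        a = fit_risk_curve(RiskSeries("a", np.arange(1.0, 6.0), np.ones(5)))
        b = fit_risk_curve(RiskSeries("b", np.arange(10.0, 15.0), np.ones(5)))
        with pytest.raises(ValueError, match="common support"):
            register_curves([a, b])

    def test_needs_at_least_two_curves(self):
        a = fit_risk_curve(RiskSeries("a", np.arange(1.0, 6.0), np.ones(5)))
        with pytest.raises(ValueError, match="two curves"):
            register_curves([a])


class TestSerialization:
    def test_curve_dict_round_trip(self, reference_series):
        curve = fit_risk_curve(reference_series)
        back = RiskCurve.from_dict(curve.to_dict())
        t = np.linspace(11, 20, 37)
        assert np.allclose(back(t), curve(t))
        assert back.resident_id == curve.resident_id
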