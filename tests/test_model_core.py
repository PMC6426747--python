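"""Unit and property tests for the sigmoid + reuse model core."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hystfit as hf
from hystfit.exceptions import InvalidInputError, UnsupportedTaskError

from conftest import recursion_oracle, tanh_oracle


class TestOptimalAngle:
    def test_inflection_returns_y_offset(self):
        p = hf.SigmoidParams(133.3, 39.4, 4.4, 17.2)
        assert hf.optimal_angle(p, 4.4) == pytest.approx(17.2, abs=1e-12)

    def test_flat_curve_returns_y_offset_everywhere(self):
        p = hf.SigmoidParams(0.0, 0.0, 4.4, 10.0)
        assert hf.optimal_angle(p, 9) == 10.0
        assert hf.optimal_angle(p, 1) == 10.0

    @pytest.mark.parametrize("drawer", [1, 2.5, 4.4, 7, 9])
    def test_matches_scalar_closed_form_oracle(self, drawer):
        p = hf.SigmoidParams(133.3, 39.4, 4.4, 17.2)
        expected = tanh_oracle(133.3, 39.4, 4.4, 17.2, drawer)
        assert hf.optimal_angle(p, drawer) == pytest.approx(expected, abs=1e-12)

    def test_derivative_at_inflection_equals_slope(self):
        p = hf.SigmoidParams(120.0, 35.0, 5.0, 0.0)
        h = 1e-6
        num = (hf.optimal_angle(p, 5.0 + h) - hf.optimal_angle(p, 5.0 - h)) / (2 * h)
        assert num == pytest.approx(35.0, rel=1e-6)

    def test_output_bounded_by_half_range(self):
        p = hf.SigmoidParams(100.0, 80.0, 4.0, 20.0)
        for d in np.linspace(-50, 50, 101):
            a = hf.optimal_angle(p, d)
            assert 20.0 - 50.0 <= a <= 20.0 + 50.0

    def test_non_finite_drawer_rejected(self):
        p = hf.SigmoidParams(100.0, 40.0, 4.0, 0.0)
        with pytest.raises(InvalidInputError):
            hf.optimal_angle(p, float("nan"))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(range=-1, slope=1, x_offset=4, y_offset=0),
            dict(range=1, slope=-1, x_offset=4, y_offset=0),
            dict(range=1, slope=1, x_offset=11, y_offset=0),
            dict(range=1, slope=1, x_offset=4, y_offset=181),
            dict(range=float("inf"), slope=1, x_offset=4, y_offset=0),
        ],
    )
    def test_parameter_invariants_enforced(self, kwargs):
        with pytest.raises(InvalidInputError):
            hf.SigmoidParams(**kwargs)


class TestBlend:
    def test_worked_example_thirty_percent(self):
        assert hf.blend(74.0, 40.0, 0.30) == pytest.approx(50.2, abs=1e-9)

    def test_full_reuse_keeps_previous_posture(self):
        assert hf.blend(74.0, 40.0, 1.0) == 74.0

    def test_zero_reuse_adopts_optimal(self):
        assert hf.blend(74.0, 40.0, 0.0) == 40.0

    @given(
        prev=st.floats(-180, 180),
        opt=st.floats(-180, 180),
        reuse=st.floats(0, 1),
    )
    @settings(deadline=None)
    def test_result_between_inputs(self, prev, opt, reuse):
        out = hf.blend(prev, opt, reuse)
        lo, hi = min(prev, opt), max(prev, opt)
        assert lo - 1e-9 <= out <= hi + 1e-9

    @pytest.mark.parametrize("reuse", [-0.01, 1.01, float("nan")])
    def test_reuse_out_of_range_rejected(self, reuse):
        with pytest.raises(InvalidInputError):
            hf.blend(74.0, 40.0, reuse)


class TestSimulateSequence:
    def test_zero_reuse_is_pure_optimum(self):
        p = hf.ReuseModelParams.from_values(131.9, 41.2, 4.4, 16.5, 0.0)
        seq = hf.SequenceSpec("custom", (3, 7, 1, 9, 5))
        out = hf.simulate_sequence(p, seq)
        expected = [hf.optimal_angle(p.sigmoid, d) for d in seq.drawers]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_total_persistence_repeats_first_angle(self):
        p = hf.ReuseModelParams.from_values(131.9, 41.2, 4.4, 16.5, 1.0)
        seq = hf.SequenceSpec.descending()
        out = hf.simulate_sequence(p, seq)
        np.testing.assert_allclose(out, out[0], atol=1e-12)

    def test_demonstration_values_from_six_to_five(self):
        # sigmoid solved so that optimal(6) = 74.0 and optimal(5) = 40.0
        R = 133.3
        y0 = (74.0 + 40.0) / 2.0
        x0 = 5.5
        slope = R * np.arctanh((74.0 - 40.0) / R)  # from (R/2) tanh(s/R) = 17
        p = hf.ReuseModelParams.from_values(R, slope, x0, y0, 0.30)
        assert hf.optimal_angle(p.sigmoid, 6) == pytest.approx(74.0, abs=1e-9)
        assert hf.optimal_angle(p.sigmoid, 5) == pytest.approx(40.0, abs=1e-9)
        out = hf.simulate_sequence(p, hf.SequenceSpec("custom", (6, 5)))
        np.testing.assert_allclose(out, [74.0, 50.2], atol=1e-9)

    def test_matches_naive_loop_on_random_draws(self, rng):
        for _ in range(100):
            R = rng.uniform(0.1, 300)
            s = rng.uniform(0, 100)
            x0 = rng.uniform(0, 10)
            y0 = rng.uniform(-100, 100)
            r = rng.uniform(0, 1)
            drawers = tuple(rng.integers(1, 10, size=rng.integers(1, 12)))
            p = hf.ReuseModelParams.from_values(R, s, x0, y0, r)
            out = hf.simulate_sequence(p, hf.SequenceSpec("custom", drawers))
            expected = recursion_oracle(R, s, x0, y0, r, drawers)
            np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_angles_bounded_by_sigmoid_span(self, rng):
        for _ in range(50):
            R = rng.uniform(0, 200)
            y0 = rng.uniform(-90, 90)
            p = hf.ReuseModelParams.from_values(
                R, rng.uniform(0, 80), rng.uniform(1, 9), y0, rng.uniform(0, 1)
            )
            drawers = tuple(rng.integers(1, 10, size=9))
            out = hf.simulate_sequence(p, hf.SequenceSpec("custom", drawers))
            assert np.all(out >= y0 - R / 2 - 1e-9)
            assert np.all(out <= y0 + R / 2 + 1e-9)

    def test_descending_angles_nondecreasing_in_reuse(self):
        sig = (131.9, 41.2, 4.4, 16.5)
        seq = hf.SequenceSpec.descending()
        prev = None
        for r in np.linspace(0, 1, 21):
            out = hf.simulate_sequence(
                hf.ReuseModelParams.from_values(*sig, r), seq
            )
            if prev is not None:
                assert np.all(out[1:] >= prev[1:] - 1e-12)
            prev = out

    def test_sequence_spec_direction_invariants(self):
        with pytest.raises(InvalidInputError):
            hf.SequenceSpec("ascending", (3, 2, 1))
        with pytest.raises(InvalidInputError):
            hf.SequenceSpec("descending", (1, 2))
        with pytest.raises(InvalidInputError):
            hf.SequenceSpec("custom", ())
        with pytest.raises(InvalidInputError):
            hf.SequenceSpec("custom", (0, 5))


class TestPredictTask:
    def test_zero_reuse_gives_zero_effect(self, paper_ordered_params):
        p = hf.ReuseModelParams(paper_ordered_params.sigmoid, 0.0)
        pred = hf.predict_task(p, hf.TaskSpec.ordered())
        assert pred.mean_effect == 0.0
        np.testing.assert_array_equal(pred.ascending, pred.descending)

    def test_effect_nonnegative_for_valid_parameters(self, rng):
        for _ in range(20):
            p = hf.ReuseModelParams.from_values(
                rng.uniform(10, 200), rng.uniform(1, 80), rng.uniform(2, 8),
                rng.uniform(-40, 40), rng.uniform(0, 1)
            )
            assert hf.predict_task(p, hf.TaskSpec.ordered()).mean_effect >= -1e-12

    def test_skipped_effect_exceeds_ordered_at_same_drawers(
        self, paper_ordered_params
    ):
        ordered = hf.predict_task(
            paper_ordered_params, hf.TaskSpec.ordered(), effect_drawers=(1, 3, 5, 7, 9)
        )
        skipped = hf.predict_task(paper_ordered_params, hf.TaskSpec.skipped())
        assert skipped.mean_effect > ordered.mean_effect
        # and both agree with the independent recursion
        s = paper_ordered_params.sigmoid
        asc = recursion_oracle(s.range, s.slope, s.x_offset, s.y_offset,
                               paper_ordered_params.reuse, [1, 3, 5, 7, 9])
        desc = recursion_oracle(s.range, s.slope, s.x_offset, s.y_offset,
                                paper_ordered_params.reuse, [9, 7, 5, 3, 1])
        expected = np.mean(np.array(desc[::-1]) - np.array(asc))
        assert skipped.mean_effect == pytest.approx(expected, abs=1e-12)

    def test_two_drawer_task_effect_closed_form(self):
        # over the pass (1, 9) / (9, 1) the recursion reduces algebraically
        # to a mean effect of reuse * (optimal(9) - optimal(1))
        p = hf.ReuseModelParams.from_values(131.9, 41.2, 4.4, 16.5, 0.5)
        opt1 = hf.optimal_angle(p.sigmoid, 1)
        opt9 = hf.optimal_angle(p.sigmoid, 9)
        asc = hf.simulate_sequence(p, hf.SequenceSpec.ascending((1, 9)))
        desc = hf.simulate_sequence(p, hf.SequenceSpec.descending((1, 9)))
        effect = np.mean([desc[1] - asc[0], desc[0] - asc[1]])
        assert effect == pytest.approx(0.5 * (opt9 - opt1), abs=1e-12)

    def test_randomized_task_is_unsupported(self, paper_ordered_params):
        with pytest.raises(UnsupportedTaskError):
            hf.predict_task(paper_ordered_params, hf.TaskSpec.randomized())


class TestCostCurves:
    def test_symmetric_weights_put_optimum_at_half(self):
        grid = np.linspace(0, 1, 1001)
        cc = hf.cost_curves(grid, 1.0, 1.0, 2.0)
        assert cc.argmin_reuse == pytest.approx(0.5, abs=1e-9)

    def test_heavier_mechanical_cost_lowers_optimal_reuse(self):
        grid = np.linspace(0, 1, 1001)
        cc = hf.cost_curves(grid, 0.3, 0.7, 2.0)
        assert cc.argmin_reuse < 0.5

    @pytest.mark.parametrize("w_c,w_m,p", [(0.4, 0.6, 2.0), (0.7, 0.3, 3.0)])
    def test_argmin_matches_bisection_oracle(self, w_c, w_m, p):
        # stationary point solves (u/(1-u))**(p-1) = w_c/w_m
        def g(u):
            return (u / (1 - u)) ** (p - 1) - w_c / w_m

        lo, hi = 1e-9, 1 - 1e-9
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if g(mid) < 0:
                lo = mid
            else:
                hi = mid
        u_star = 0.5 * (lo + hi)
        grid = np.arange(0, 1.0005, 0.001)
        cc = hf.cost_curves(grid, w_c, w_m, p)
        assert cc.argmin_reuse == pytest.approx(u_star, abs=0.001)

    def test_monotone_components(self):
        grid = np.linspace(0, 1, 101)
        cc = hf.cost_curves(grid, 1.0, 2.0, 2.5)
        assert np.all(np.diff(cc.cognitive) <= 1e-15)
        assert np.all(np.diff(cc.mechanical) >= -1e-15)

    def test_exponent_at_most_one_rejected(self):
        with pytest.raises(InvalidInputError):
            hf.cost_curves([0.0, 0.5, 1.0], 1.0, 1.0, 1.0)

    def test_both_weights_zero_rejected(self):
        with pytest.raises(InvalidInputError):
            hf.cost_curves([0.0, 0.5, 1.0], 0.0, 0.0, 2.0)
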