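"""Closed-form and distributional properties of the diffusion-model core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from magdiff.wiener import (
    DiffusionParams,
    expected_rt,
    fpt_defective_cdf,
    fpt_defective_density,
    mean_decision_time,
    p_correct,
    predicted_quartiles,
    signed_rt_cdf,
    simulate_trial,
    simulate_trials,
)

param_sets = st.tuples(
    st.floats(0.4, 3.5),  # a
    st.floats(-4.0, 4.0),  # v
    st.floats(0.05, 1.0),  # t0
    st.floats(0.0, 0.8),  # st0 fraction of t0
).map(lambda t: DiffusionParams(t[0], t[1], t[2], t[3] * t[2]))


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"a": 0.0, "v": 1.0},
            {"a": -1.0, "v": 1.0},
            {"a": 1.0, "v": 1.0, "t0": -0.1},
            {"a": 1.0, "v": 1.0, "t0": 0.1, "st0": 0.5},  # support below zero
            {"a": 1.0, "v": np.inf},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DiffusionParams(**{"t0": 0.0, "st0": 0.0, **kwargs})

    def test_start_point_is_midpoint(self):
        assert DiffusionParams(1.8, 1.0).z == pytest.approx(0.9)


class TestClosedForms:
    def test_zero_drift_is_chance(self):
        assert p_correct(DiffusionParams(1.5, 0.0)) == pytest.approx(0.5)

    def test_accuracy_antisymmetry_and_scale_invariance(self):
        for a, v in [(1.0, 0.7), (2.5, -1.2), (0.6, 3.0)]:
            assert p_correct(DiffusionParams(a, v)) + p_correct(
                DiffusionParams(a, -v)
            ) == pytest.approx(1.0)
            assert p_correct(DiffusionParams(a, v)) == pytest.approx(
                p_correct(DiffusionParams(2 * a, v / 2))
            )

    def test_accuracy_at_cohort_parameters(self, con_symbolic):
        assert p_correct(con_symbolic) == pytest.approx(0.9749, abs=1e-4)

    def test_mean_decision_time_values(self, con_symbolic):
        assert mean_decision_time(DiffusionParams(2.0, 1e-12)) == pytest.approx(1.0)
        assert mean_decision_time(DiffusionParams(2.0, 1.0)) == pytest.approx(
            np.tanh(1.0), abs=1e-12
        )
        assert mean_decision_time(con_symbolic) == pytest.approx(0.292, abs=5e-4)

    def test_mean_decision_time_positive_and_decreasing_in_drift(self):
        mdts = [mean_decision_time(DiffusionParams(2.0, v)) for v in (0.0, 0.5, 1.5, 3.0)]
        assert all(m > 0 for m in mdts)
        assert mdts == sorted(mdts, reverse=True)

    def test_expected_rt_adds_t0_only(self):
        p = DiffusionParams(2.0, 1.0, 0.5, 0.2)
        assert expected_rt(p) == pytest.approx(np.tanh(1.0) + 0.5, abs=1e-12)
        base = DiffusionParams(2.0, 1.0, 0.0, 0.0)
        assert expected_rt(base) == pytest.approx(mean_decision_time(base))
        shifted = DiffusionParams(2.0, 1.0, 1.0, 0.0)
        assert expected_rt(shifted) - expected_rt(base) == pytest.approx(1.0)


class TestFirstPassage:
    @pytest.mark.parametrize("a,v", [(1.0, 1.0), (1.5, 2.0), (2.0, -0.5), (0.5, 0.0)])
    def test_defective_mass_matches_accuracy(self, a, v):
        p = DiffusionParams(a, v)
        mass_c, _ = quad(lambda t: fpt_defective_density(t, p, "correct"), 0, 200, limit=300)
        mass_e, _ = quad(lambda t: fpt_defective_density(t, p, "error"), 0, 200, limit=300)
        assert mass_c == pytest.approx(p_correct(p), abs=1e-6)
        assert mass_c + mass_e == pytest.approx(1.0, abs=1e-8)

    def test_zero_drift_boundary_symmetry(self):
        p = DiffusionParams(1.2, 0.0)
        t = np.linspace(0.01, 3, 50)
        np.testing.assert_allclose(
            fpt_defective_density(t, p, "correct"), fpt_defective_density(t, p, "error")
        )

    def test_density_against_simulation_histogram(self, rng):
        # brute-force oracle: histogram density of simulated decision times
        p = DiffusionParams(1.0, 1.0)
        correct, rt = simulate_trials(p, 4 * 10**5, rng)
        dt = 0.04
        sel = (rt >= 0.3 - dt / 2) & (rt < 0.3 + dt / 2) & (correct == 1)
        est = sel.sum() / len(rt) / dt
        mc_se = np.sqrt(est / (len(rt) * dt))
        assert fpt_defective_density(0.3, p, "correct") == pytest.approx(est, abs=4 * mc_se)

    def test_cdf_limits_and_quadrature_consistency(self):
        p = DiffusionParams(1.5, 2.0)
        assert fpt_defective_cdf(0.0, p, "correct") == 0.0
        assert fpt_defective_cdf(0.0, p, "error") == 0.0
        assert fpt_defective_cdf(100.0, p, "correct") == pytest.approx(p_correct(p), abs=1e-9)
        q, _ = quad(lambda s: fpt_defective_density(s, p, "correct"), 0, 0.5, limit=200)
        assert fpt_defective_cdf(0.5, p, "correct") == pytest.approx(q, abs=1e-5)

    def test_non_finite_time_rejected(self):
        with pytest.raises(ValueError):
            fpt_defective_density(np.nan, DiffusionParams(1.0, 1.0))


class TestSignedCDF:
    def test_value_at_zero_is_error_probability(self):
        p = DiffusionParams(1.5, 2.0, 0.7, 0.2)
        assert signed_rt_cdf(0.0, p) == pytest.approx(1 - p_correct(p), abs=1e-12)

    def test_degenerate_window_is_pure_shift(self):
        p0 = DiffusionParams(1.5, 2.0, 0.0, 0.0)
        p1 = DiffusionParams(1.5, 2.0, 0.4, 0.0)
        ts = np.linspace(0.05, 3, 40)
        np.testing.assert_allclose(
            signed_rt_cdf(ts + 0.4, p1), signed_rt_cdf(ts, p0), atol=1e-12
        )

    def test_against_large_simulation(self, rng):
        p = DiffusionParams(1.5, 2.0, 0.7, 0.2)
        correct, rt = simulate_trials(p, 10**6, rng)
        x = np.sort(np.where(correct == 1, rt, -rt))
        emp = np.arange(1, len(x) + 1) / len(x)
        model = signed_rt_cdf(x, p)
        assert np.max(np.abs(model - emp)) < 0.002
        assert signed_rt_cdf(1.0, p) == pytest.approx(np.interp(1.0, x, emp), abs=0.002)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(params=param_sets)
    def test_monotone_and_bounded(self, params):
        grid = np.linspace(-6, 8, 300)
        vals = signed_rt_cdf(grid, params)
        assert np.all(np.diff(vals) >= -1e-10)
        assert vals[0] >= 0 and vals[-1] <= 1
        assert signed_rt_cdf(500.0, params) == pytest.approx(1.0, abs=1e-6)


class TestSimulation:
    def test_single_trial_outcome(self, rng, con_symbolic):
        out = simulate_trial(con_symbolic, rng)
        assert out.correct in (0, 1)
        assert out.rt > 0

    @pytest.mark.parametrize(
        "params,target_acc",
        [
            (DiffusionParams(1.5, 2.0), np.exp(3) / (1 + np.exp(3))),
            (DiffusionParams(1.5, 0.0), 0.5),
        ],
    )
    def test_accuracy_converges_to_closed_form(self, rng, params, target_acc):
        correct, _ = simulate_trials(params, 100_000, rng)
        se = np.sqrt(target_acc * (1 - target_acc) / 100_000)
        assert abs(correct.mean() - target_acc) < 3 * se

    def test_mean_rt_converges_to_closed_form(self, rng):
        p = DiffusionParams(2.0, 1.0, 0.5, 0.0)
        _, rt = simulate_trials(p, 100_000, rng)
        assert abs(rt.mean() - expected_rt(p)) < 3 * rt.std() / np.sqrt(len(rt))


class TestPredictedQuartiles:
    def test_strictly_increasing_and_shift_equivariant(self, con_symbolic):
        _, q = predicted_quartiles(con_symbolic)
        assert q[0] < q[1] < q[2]
        p0 = DiffusionParams(1.5, 2.0, 0.3, 0.0)
        p1 = DiffusionParams(1.5, 2.0, 0.8, 0.0)
        _, q0 = predicted_quartiles(p0)
        _, q1 = predicted_quartiles(p1)
        np.testing.assert_allclose(np.array(q1) - np.array(q0), 0.5, atol=1e-5)

    def test_matches_simulation(self, rng):
        p = DiffusionParams(1.5, 2.0, 0.7, 0.2)
        _, rt = simulate_trials(p, 4 * 10**5, rng)
        acc, q = predicted_quartiles(p, mode="all")
        np.testing.assert_allclose(q, np.quantile(rt, [0.25, 0.5, 0.75]), atol=0.005)

    def test_correct_only_mode(self, rng):
        p = DiffusionParams(1.0, 0.8, 0.4, 0.1)
        correct, rt = simulate_trials(p, 4 * 10**5, rng)
        _, q = predicted_quartiles(p, mode="correct")
        np.testing.assert_allclose(
            q, np.quantile(rt[correct == 1], [0.25, 0.5, 0.75]), atol=0.005
        )

    def test_unknown_mode_rejected(self, con_symbolic):
        with pytest.raises(ValueError):
            predicted_quartiles(con_symbolic, mode="median")
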