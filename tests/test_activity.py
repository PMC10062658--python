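"""Scaled activity, exact adaptation, step responses and responsiveness."""

import numpy as np
import pytest

from pthpulse import (
    ActivityCoefficients,
    a2_exact_adaptation,
    basal_activity,
    cellular_responsiveness,
    equilibrium_state,
    generate_test_stimulus,
    integrated_pulse_activity,
    scaled_activity,
    step_response,
)
from pthpulse.errors import ExactAdaptationError
from pthpulse.kinetics import ReceptorState, periodic_steady_state, _segment_propagator
from pthpulse.activity import _activity_modes, _eval_modes
from pthpulse.stimulus import SquareWaveStimulus


class TestA2Formula:
    @pytest.mark.parametrize("c", [0.0, 0.3, 1.0, 7.5])
    def test_uniform_weights_are_self_consistent(self, params, c):
        """Uniform weights give a constant activity, which trivially adapts;
        the formula must therefore return the same constant."""
        assert a2_exact_adaptation(c, c, c, params.K1, params.K2) == pytest.approx(c, rel=1e-12)

    def test_homogeneous_in_weights(self, params):
        a2 = a2_exact_adaptation(1.0, 0.2, 0.5, params.K1, params.K2)
        assert a2_exact_adaptation(3.0, 0.6, 1.5, params.K1, params.K2) == pytest.approx(3 * a2)

    def test_negative_result_is_reported_with_inputs(self, params):
        with pytest.raises(ExactAdaptationError, match="a3"):
            a2_exact_adaptation(0.0, 5.0, 0.0, params.K1, params.K2)

    @pytest.mark.parametrize("L", [0.0, 1.0, 10.0, 100.0, 3333.0])
    def test_steady_state_activity_is_ligand_independent(self, params, coeffs, L):
        """The exact-adaptation construction under detailed-balance kinetics."""
        alpha = scaled_activity(equilibrium_state(L, params), coeffs)
        alpha0 = scaled_activity(equilibrium_state(0.0, params), coeffs)
        assert alpha == pytest.approx(alpha0, abs=1e-9)

    def test_adaptation_only_approximate_without_detailed_balance(self, printed_params):
        """With the literature inactive-complex constant the cycle carries a
        net flux and the steady-state activity drifts with ligand level."""
        co = ActivityCoefficients.exact_adaptation(1.0, 0.0, 0.0, printed_params)
        drift = abs(
            scaled_activity(equilibrium_state(100.0, printed_params), co)
            - scaled_activity(equilibrium_state(0.0, printed_params), co)
        )
        assert drift > 1e-3


class TestScaledActivity:
    def test_uniform_weights_give_constant(self, rng):
        co = ActivityCoefficients(2.0, 2.0, 2.0, 2.0)
        for _ in range(10):
            state = ReceptorState.from_array(rng.dirichlet(np.ones(4)))
            assert scaled_activity(state, co) == pytest.approx(2.0, abs=1e-12)

    def test_basis_vector_picks_single_weight(self):
        co = ActivityCoefficients(1.5, 2.5, 3.5, 4.5)
        assert scaled_activity(ReceptorState(1, 0, 0, 0), co) == pytest.approx(1.5)

    def test_basal_closed_form_at_zero_ligand(self, params, coeffs):
        expected = (coeffs.a1 * params.K1 + coeffs.a4) / (params.K1 + 1)
        assert basal_activity(coeffs, params, 0.0) == pytest.approx(expected, abs=1e-12)

    def test_basal_equals_any_constant_level_steady_state(self, params, coeffs):
        assert basal_activity(coeffs, params, 50.0) == pytest.approx(
            basal_activity(coeffs, params, 0.0), abs=1e-9
        )


class TestStepResponse:
    def test_vanishing_step_has_vanishing_peak(self, params, coeffs):
        st = step_response(5.0, 5.0 * (1 + 1e-9), params, coeffs)
        assert abs(st.alpha_M_step) < 1e-6

    def test_invalid_step_rejected(self, params, coeffs):
        with pytest.raises(ValueError):
            step_response(5.0, 5.0, params, coeffs)

    def test_integrated_step_identity(self, params, coeffs):
        st = step_response(3.3, 12.0, params, coeffs)
        assert st.alpha_T_step == st.tau_a * st.alpha_M_step

    def test_peak_matches_dense_grid_oracle(self, params, coeffs):
        """Refined peak vs brute-force dense sampling of the transient."""
        gamma0, gamma1 = 3.3, 15.0
        st = step_response(gamma0, gamma1, params, coeffs)
        x0 = equilibrium_state(gamma0, params).as_array()
        lam, w = _activity_modes(x0, gamma1, params, coeffs.weights)
        ts = np.linspace(0, 200, 400001)
        alpha = _eval_modes(lam, w, ts)
        alpha_s = scaled_activity(equilibrium_state(gamma1, params), coeffs)
        peak = (alpha - alpha_s).max()
        assert st.alpha_M_step == pytest.approx(peak, rel=1e-3)

    def test_adaptation_time_decreases_with_looser_criterion(self, params, coeffs):
        tight = step_response(3.3, 12.0, params, coeffs, tau_a_criterion=0.05)
        loose = step_response(3.3, 12.0, params, coeffs, tau_a_criterion=0.5)
        assert tight.tau_a > loose.tau_a

    def test_criterion_recorded_in_result(self, params, coeffs):
        st = step_response(3.3, 12.0, params, coeffs, tau_a_criterion=0.25)
        assert st.tau_a_criterion == 0.25


class TestIntegratedPulseActivity:
    def test_constant_stimulus_integrates_to_zero(self, params, coeffs):
        stim = SquareWaveStimulus(6.0, 6.0, 2.0, 11.0)
        assert integrated_pulse_activity(stim, params, coeffs) == pytest.approx(0.0, abs=1e-9)

    def test_matches_dense_trapezoid_quadrature(self, params, coeffs):
        """Exact segment-wise integration vs dt = 0.001 min quadrature."""
        stim = SquareWaveStimulus(3.317, 11.657, 2.0, 10.0)
        exact = integrated_pulse_activity(stim, params, coeffs)
        a0 = basal_activity(coeffs, params, stim.gamma0)
        x = periodic_steady_state(stim, params).as_array()
        approx = 0.0
        for dur, level in stim.segments_in_period():
            lam, w = _activity_modes(x, level, params, coeffs.weights)
            ts = np.arange(0.0, dur + 5e-4, 1e-3)
            ex = np.maximum(_eval_modes(lam, w, ts) - a0, 0.0)
            approx += np.trapezoid(ex, ts)
            x = _segment_propagator(level, dur, params) @ x
        assert exact == pytest.approx(approx, rel=1e-6)

    def test_linear_in_coefficient_scale(self, params, coeffs):
        stim = SquareWaveStimulus(3.0, 9.0, 2.0, 12.0)
        base = integrated_pulse_activity(stim, params, coeffs)
        scaled = integrated_pulse_activity(
            stim,
            params,
            ActivityCoefficients(coeffs.a1, coeffs.a2, coeffs.a3, coeffs.a4, scale=7.0),
        )
        assert scaled == pytest.approx(7.0 * base, rel=1e-9)

    def test_signed_integral_cancels_for_small_pulses(self, params, coeffs):
        """Zero DC gain of the adapted system: the signed per-period integral
        is second-order small in the pulse amplitude, the burst area is not."""
        stim = SquareWaveStimulus(5.0, 5.05, 2.0, 12.0)
        signed = integrated_pulse_activity(stim, params, coeffs, rectified=False)
        burst = integrated_pulse_activity(stim, params, coeffs, rectified=True)
        assert burst > 0
        assert abs(signed) < 0.05 * burst


class TestCellularResponsiveness:
    def test_constant_stimulus_gives_zero_flagged(self, params, coeffs):
        res = cellular_responsiveness(SquareWaveStimulus(4.0, 4.0, 3.0, 9.0), params, coeffs)
        assert res.alpha_R == 0.0
        assert res.degenerate

    def test_step_reference_dominates_single_pulse(self, params, coeffs):
        res = cellular_responsiveness(SquareWaveStimulus(3.317, 11.657, 2.0, 10.0), params, coeffs)
        assert res.alpha_T_step > 5 * res.alpha_T

    def test_positive_for_any_pulsatile_stimulus(self, params, coeffs, rng):
        for _ in range(5):
            stim = generate_test_stimulus(rng)
            assert cellular_responsiveness(stim, params, coeffs).alpha_R > 0

    def test_invariant_under_phase_relabelling(self, params, coeffs):
        """Starting the period at the pulse or at the off-phase is a relabelling
        of the same periodic signal and cannot change the responsiveness."""

        class ShiftedWave:
            def __init__(self, stim):
                self.stim = stim

            @property
            def period(self):
                return self.stim.T

            def segments_in_period(self):
                return ((self.stim.tau0, self.stim.gamma0), (self.stim.tau1, self.stim.gamma1))

            def value(self, t):
                return self.stim.value(np.mod(np.asarray(t) + self.stim.tau1, self.stim.T))

        stim = SquareWaveStimulus(3.0, 10.0, 3.0, 13.0)
        a = cellular_responsiveness(stim, params, coeffs).alpha_R
        b = cellular_responsiveness(ShiftedWave(stim), params, coeffs).alpha_R
        assert a == pytest.approx(b, rel=1e-9)

    def test_homogeneity_in_coefficients(self, params, coeffs):
        stim = SquareWaveStimulus(3.0, 10.0, 3.0, 13.0)
        r1 = cellular_responsiveness(stim, params, coeffs)
        r2 = cellular_responsiveness(
            stim,
            params,
            ActivityCoefficients(coeffs.a1, coeffs.a2, coeffs.a3, coeffs.a4, scale=4.0),
        )
        for attr in ("alpha_0", "alpha_T", "alpha_M_step", "alpha_T_step", "alpha_R"):
            assert getattr(r2, attr) == pytest.approx(4.0 * getattr(r1, attr), rel=1e-8)
        assert r2.tau_a == pytest.approx(r1.tau_a, rel=1e-9)

    def test_definition_matches_long_run_trajectory(self, params, coeffs):
        """alpha_R recomputed from an independently integrated 50-period run."""
        from scipy.integrate import solve_ivp
        from pthpulse import rate_matrix

        stim = SquareWaveStimulus(3.317, 11.657, 2.0, 10.0)
        res = cellular_responsiveness(stim, params, coeffs)
        x0 = equilibrium_state(stim.gamma0, params).as_array()
        # long transient to reach the periodic regime, then one period densely
        n_relax = 50
        sol = solve_ivp(
            lambda t, y: rate_matrix(float(stim.value(t)), params) @ y,
            (0.0, n_relax * stim.T),
            x0,
            method="LSODA",
            rtol=1e-11,
            atol=1e-14,
            max_step=0.25,
        )
        x_start = sol.y[:, -1]
        ts = np.linspace(0.0, stim.T, 40001)
        sol2 = solve_ivp(
            lambda t, y: rate_matrix(float(stim.value(t)), params) @ y,
            (0.0, stim.T),
            x_start,
            method="LSODA",
            rtol=1e-11,
            atol=1e-14,
            max_step=0.05,
            t_eval=ts,
        )
        alpha = coeffs.weights @ sol2.y
        a0 = basal_activity(coeffs, params, stim.gamma0)
        alpha_T = np.trapezoid(np.maximum(alpha - a0, 0.0), ts)
        oracle = alpha_T**2 / (res.alpha_T_step * stim.T)
        assert res.alpha_R == pytest.approx(oracle, rel=1e-4)

    def test_result_serialises_with_criterion(self, params, coeffs):
        res = cellular_responsiveness(SquareWaveStimulus(3.0, 9.0, 2.0, 12.0), params, coeffs)
        d = res.to_dict()
        assert "tau_a_criterion" in d and "alpha_R" in d
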