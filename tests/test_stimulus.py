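"""Square waves, AUC decomposition, PK curve, reduction and superposition."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from pthpulse import (
    CombinedStimulus,
    PKParameters,
    SquareWaveStimulus,
    auc_decomposition,
    generate_test_stimulus,
    injection_square_wave,
    pk_auc,
    pk_curve,
    pk_peak,
    responsiveness_model1,
    responsiveness_model2,
    square_wave_value,
)
from pthpulse.errors import InfeasibilityError
from pthpulse.stimulus import dose_to_pmol


class TestSquareWave:
    def test_on_phase_starts_each_period(self):
        stim = SquareWaveStimulus(2.0, 8.0, 3.0, 10.0)
        assert square_wave_value(stim, 0.0) == 8.0
        assert square_wave_value(stim, 3.0 + 1e-9) == 2.0
        assert square_wave_value(stim, 10.0) == 8.0  # right-continuous restart

    def test_periodicity(self, rng):
        stim = SquareWaveStimulus(2.0, 8.0, 3.0, 10.0)
        t = rng.uniform(0, 100, 50)
        assert np.array_equal(stim.value(t), stim.value(t + stim.T))

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            SquareWaveStimulus(5.0, 4.0, 1.0, 10.0)  # peak below tonic
        with pytest.raises(ValueError):
            SquareWaveStimulus(1.0, 4.0, 11.0, 10.0)  # pulse longer than period

    def test_generated_fixtures_satisfy_invariants(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            stim = generate_test_stimulus(rng)
            assert 0 <= stim.gamma0 <= stim.gamma1
            assert 0 < stim.tau1 < stim.T <= 120.0

    def test_generator_is_deterministic(self):
        a = generate_test_stimulus(123)
        b = generate_test_stimulus(123)
        assert (a.gamma0, a.gamma1, a.tau1, a.T) == (b.gamma0, b.gamma1, b.tau1, b.T)

    def test_burst_frequency_band(self):
        """Restricting the period range yields 3-7 bursts per hour."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            stim = generate_test_stimulus(rng, ranges={"T": (8.6, 20.0), "tau1": (1.0, 7.0)})
            assert 3.0 <= 60.0 / stim.T <= 7.0


class TestAUCDecomposition:
    def test_closed_form_arithmetic(self):
        stim = SquareWaveStimulus(5.0, 10.0, 10.0, 50.0)
        dec = auc_decomposition(stim, 100.0)
        assert dec.A == pytest.approx(600.0)
        assert dec.A_puls == pytest.approx(100.0)
        assert dec.r == pytest.approx(1.0 / 6.0)
        assert dec.commensurate

    def test_constant_wave_has_no_pulsatile_share(self):
        dec = auc_decomposition(SquareWaveStimulus(5.0, 5.0, 2.0, 20.0), 40.0)
        assert dec.A_puls == 0.0 and dec.r == 0.0

    @pytest.mark.parametrize("s", [50.0, 77.3, 123.4])
    def test_matches_numeric_quadrature(self, s):
        stim = SquareWaveStimulus(2.2, 9.4, 3.7, 13.1)
        dec = auc_decomposition(stim, s)
        num = sum(
            quad(lambda t: float(stim.value(t)), a, b, limit=400)[0]
            for a, b in zip(np.arange(0, s, 13.1), np.append(np.arange(13.1, s, 13.1), s))
        )
        assert dec.A == pytest.approx(num, rel=1e-9)

    def test_incommensurate_window_is_flagged(self):
        dec = auc_decomposition(SquareWaveStimulus(2.0, 8.0, 3.0, 10.0), 14.0)
        assert not dec.commensurate
        assert dec.A == pytest.approx(2.0 * 14.0 + 6.0 * (3.0 + 3.0))


@pytest.fixture(scope="module")
def pk():
    from pthpulse import load_config

    return load_config().pk


class TestPKCurve:
    def test_zero_dose_is_identically_zero(self, pk):
        t = np.linspace(0, 500, 50)
        assert np.all(pk_curve(0.0, pk, t) == 0.0)

    def test_matches_ode_integration(self, pk):
        """Bateman closed form vs direct integration of the two-compartment cascade."""
        dose = dose_to_pmol(20.0, pk.molar_mass)
        ts = np.linspace(0.0, 720.0, 200)

        def rhs(t, y):
            depot, plasma = y
            return [-pk.k_a * depot, pk.F * pk.k_a * depot / pk.V_d - pk.k_e * plasma]

        sol = solve_ivp(rhs, (0, 720.0), [dose, 0.0], rtol=1e-11, atol=1e-14, t_eval=ts)
        closed = pk_curve(20.0, pk, ts)
        assert np.allclose(closed[1:], sol.y[1][1:], rtol=1e-8)

    def test_auc_equals_analytic_value(self, pk):
        num, _ = quad(lambda t: float(pk_curve(20.0, pk, t)), 0, np.inf, limit=400)
        assert num == pytest.approx(pk_auc(20.0, pk), rel=1e-6)

    def test_equal_rate_limit(self):
        pk_eq = PKParameters(k_a=0.05, k_e=0.05, V_d=10.0, F=1.0)
        t = np.linspace(0.001, 300, 500)
        conc = pk_curve(10.0, pk_eq, t)
        expected = dose_to_pmol(10.0) * 0.05 / 10.0 * t * np.exp(-0.05 * t)
        assert np.allclose(conc, expected, rtol=1e-12)

    def test_negative_dose_rejected(self, pk):
        with pytest.raises(ValueError):
            pk_curve(-1.0, pk, 10.0)


class TestInjectionSquareWave:
    def test_on_phase_from_auc_and_peak(self, pk):
        wave = injection_square_wave(20.0, pk, gamma0=3.3)
        peak, _ = pk_peak(20.0, pk)
        assert wave.gamma1 == pytest.approx(3.3 + peak)
        assert wave.tau1 == pytest.approx(pk_auc(20.0, pk) / peak)

    def test_reduction_preserves_auc_above_baseline(self, pk):
        wave = injection_square_wave(17.0, pk, gamma0=2.5)
        above = (wave.gamma1 - wave.gamma0) * wave.tau1
        assert above == pytest.approx(pk_auc(17.0, pk), rel=1e-9)

    def test_dose_scales_auc_not_on_phase(self, pk):
        w1 = injection_square_wave(10.0, pk, gamma0=3.3)
        w2 = injection_square_wave(20.0, pk, gamma0=3.3)
        assert w2.tau1 == pytest.approx(w1.tau1, rel=1e-12)
        assert (w2.gamma1 - 3.3) == pytest.approx(2 * (w1.gamma1 - 3.3), rel=1e-12)

    def test_toy_arithmetic(self):
        """AUC 300 above baseline at peak 10 above baseline gives a 30 min pulse."""
        pk_toy = PKParameters(k_a=0.01, k_e=0.2, V_d=1.0, F=1.0)
        dose = 300.0 / pk_auc(1.0, pk_toy)  # dose with drug AUC exactly 300
        peak, _ = pk_peak(dose, pk_toy)
        wave = injection_square_wave(dose, pk_toy, gamma0=0.0, T_inj=1440.0)
        assert wave.tau1 == pytest.approx(300.0 / peak)

    def test_pulse_longer_than_period_is_infeasible(self, pk):
        with pytest.raises(InfeasibilityError):
            injection_square_wave(20.0, pk, gamma0=3.3, T_inj=50.0)


class TestSuperpositionModels:
    def test_zero_dose_models_agree_exactly(self, config, registry):
        gland = registry["healthy"].stimulus
        m2 = responsiveness_model2(gland, None, config.params, config.coeffs)
        m1 = responsiveness_model1(CombinedStimulus(gland, None), config.params, config.coeffs)
        assert m1.alpha_R_total == m2.alpha_R_total
        assert m1.alpha_R_injection == 0.0

    def test_totals_increase_with_dose(self, config, registry):
        gland = registry["healthy"].stimulus
        totals = []
        for dose in (10.0, 20.0, 30.0):
            inj = injection_square_wave(dose, config.pk, gland.gamma0)
            totals.append(
                responsiveness_model2(gland, inj, config.params, config.coeffs).alpha_R_total
            )
        assert totals[0] < totals[1] < totals[2]

    def test_models_agree_within_interaction_bound(self, config, registry):
        """The separately-computed and combined-simulation superpositions agree
        up to receptor cross-desensitisation between drug plateau and gland
        bursts (measured at about 25% worst-case for these patterns)."""
        for name in ("healthy", "OP"):
            gland = registry[name].stimulus
            for dose in (10.0, 20.0):
                inj = injection_square_wave(dose, config.pk, gland.gamma0)
                m2 = responsiveness_model2(gland, inj, config.params, config.coeffs)
                m1 = responsiveness_model1(
                    CombinedStimulus(gland, inj), config.params, config.coeffs
                )
                rel = abs(m1.alpha_R_total - m2.alpha_R_total) / m2.alpha_R_total
                assert rel < 0.30

    def test_commensuration_rescales_within_bound(self, registry, pk):
        gland = SquareWaveStimulus(3.3, 10.0, 2.0, 9.93)  # 1440/9.93 = 145.01...
        inj = injection_square_wave(20.0, pk, 3.3)
        comb = CombinedStimulus(gland, inj)
        rescaled, n = comb.commensurate_gland()
        assert n == 145
        assert abs(rescaled.T - gland.T) / gland.T < 0.02
        assert n * rescaled.T == pytest.approx(1440.0)

    def test_segment_partition_covers_period(self, registry, pk, config):
        gland = registry["healthy"].stimulus
        inj = injection_square_wave(20.0, pk, gland.gamma0)
        comb = CombinedStimulus(gland, inj)
        segs = comb.segments_in_period()
        assert sum(d for d, _ in segs) == pytest.approx(1440.0)
        assert all(level >= 0 for _, level in segs)
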