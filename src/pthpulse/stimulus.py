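"""Ligand stimulus construction: glandular square waves and injection PK curves.

Glandular PTH secretion is idealised as a periodic square wave: a tonic level
``gamma0`` with rectangular pulses to ``gamma1`` of duration ``tau1`` every
``T`` minutes.  The area under the concentration curve (AUC) over a window
``s`` splits into a tonic part ``gamma0*s`` and a pulsatile part
``(gamma1-gamma0)*tau1*s/T``; the pulsatile fraction ``r`` of total AUC is the
quantity clinical deconvolution studies report.

A subcutaneous injection of dose ``D`` produces a plasma concentration given
by a one-compartment model with first-order absorption (the Bateman
function).  For use in the periodic receptor model the PK curve is reduced to
an equal-peak, equal-AUC square wave riding on the tonic baseline.  Combined
gland + injection stimulation is evaluated either on the summed signal in a
single simulation (model 1) or as the sum of two independently computed
responsivenesses (model 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .activity import (
    ActivityCoefficients,
    DEFAULT_TAU_A_CRITERION,
    ResponsivenessResult,
    _activity_modes,
    _positive_excess_integral,
    _stabilised,
    basal_activity,
    cellular_responsiveness,
    step_response,
)
from .errors import InfeasibilityError
from .kinetics import KineticParameters

__all__ = [
    "SquareWaveStimulus",
    "AUCDecomposition",
    "PKParameters",
    "CombinedStimulus",
    "CombinedResponsiveness",
    "PTH134_MOLAR_MASS",
    "square_wave_value",
    "auc_decomposition",
    "dose_to_pmol",
    "pk_curve",
    "pk_auc",
    "pk_peak",
    "injection_square_wave",
    "responsiveness_model1",
    "responsiveness_model2",
]

#: molar mass of PTH(1-34) (teriparatide), g/mol; converts microgram doses to pmol
PTH134_MOLAR_MASS = 4117.8


@dataclass(frozen=True)
class SquareWaveStimulus:
    """Periodic rectangular ligand signal (concentrations pmol/L, times min).

    The signal equals ``gamma1`` on ``[(n-1)T, (n-1)T + tau1)`` and ``gamma0``
    on the remainder of each period (right-continuous at the switch points).
    """

    gamma0: float
    gamma1: float
    tau1: float
    T: float

    def __post_init__(self) -> None:
        if not 0 <= self.gamma0 <= self.gamma1:
            raise ValueError(f"need 0 <= gamma0 <= gamma1, got {self.gamma0}, {self.gamma1}")
        if not 0 < self.tau1 <= self.T:
            raise ValueError(f"need 0 < tau1 <= T, got tau1={self.tau1}, T={self.T}")

    @property
    def tau0(self) -> float:
        """Off-phase duration, ``T - tau1``."""
        return self.T - self.tau1

    @property
    def period(self) -> float:
        return self.T

    @property
    def amplitude(self) -> float:
        return self.gamma1 - self.gamma0

    def segments_in_period(self) -> Sequence[tuple[float, float]]:
        if self.tau0 == 0.0:
            return ((self.tau1, self.gamma1),)
        return ((self.tau1, self.gamma1), (self.tau0, self.gamma0))

    def value(self, t):
        """Evaluate the wave at time(s) ``t`` (min), vectorised."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        phase = np.mod(t, self.T)
        out = np.where(phase < self.tau1, self.gamma1, self.gamma0)
        return out if out.ndim else float(out)

    def mean_level(self) -> float:
        """Period-averaged concentration, pmol/L."""
        return self.gamma0 + self.amplitude * self.tau1 / self.T


def square_wave_value(stim: SquareWaveStimulus, t):
    """Periodic, right-continuous evaluation of a square wave (pmol/L)."""
    return stim.value(t)


@dataclass(frozen=True)
class AUCDecomposition:
    """Split of the AUC over a window ``s`` into tonic and pulsatile parts."""

    A: float  # total integrated concentration (pmol*min/L)
    A_tonic: float
    A_puls: float
    r: float  # pulsatile fraction A_puls / A
    s: float  # window length (min)
    commensurate: bool  # whether s is an integer multiple of the period

    def __post_init__(self) -> None:
        if abs(self.A - (self.A_tonic + self.A_puls)) > 1e-9 * max(1.0, abs(self.A)):
            raise ValueError("AUC parts must sum to the total")
        if not -1e-12 <= self.r <= 1 + 1e-12:
            raise ValueError("pulsatile fraction must lie in [0, 1]")


def auc_decomposition(stim: SquareWaveStimulus, s: float) -> AUCDecomposition:
    """AUC of the square wave over ``[0, s]``, split into tonic and pulsatile parts.

    For a window that is a multiple of the period the closed form
    ``A = gamma0*s + (gamma1-gamma0)*tau1*s/T`` applies; other windows are
    integrated exactly over the partial period and flagged as incommensurate.
    """
    if s <= 0:
        raise ValueError("window must be positive")
    n_full, rem = divmod(s, stim.T)
    commensurate = rem < 1e-9 * stim.T or stim.T - rem < 1e-9 * stim.T
    if commensurate:
        A_puls = stim.amplitude * stim.tau1 * s / stim.T
    else:
        on_time = n_full * stim.tau1 + min(rem, stim.tau1)
        A_puls = stim.amplitude * on_time
    A_tonic = stim.gamma0 * s
    A = A_tonic + A_puls
    return AUCDecomposition(
        A=A, A_tonic=A_tonic, A_puls=A_puls, r=A_puls / A if A else 0.0, s=s, commensurate=commensurate
    )


@dataclass(frozen=True)
class PKParameters:
    """One-compartment subcutaneous PK parameters.

    ``k_a`` (min^-1) first-order absorption from the injection site, ``k_e``
    (min^-1) elimination from plasma, ``V_d`` (L) distribution volume and
    ``F`` the absolute bioavailability.  PTH(1-34) absorption from the
    subcutaneous depot is slower than its elimination, so the default preset
    is in the flip-flop regime (k_a < k_e).
    """

    k_a: float
    k_e: float
    V_d: float
    F: float
    molar_mass: float = PTH134_MOLAR_MASS

    def __post_init__(self) -> None:
        if min(self.k_a, self.k_e, self.V_d, self.molar_mass) <= 0:
            raise ValueError("PK rates, volume and molar mass must be positive")
        if not 0 < self.F <= 1:
            raise ValueError("bioavailability must lie in (0, 1]")


def dose_to_pmol(dose_ug: float, molar_mass: float = PTH134_MOLAR_MASS) -> float:
    """Convert a microgram dose of PTH(1-34) to pmol."""
    if dose_ug < 0:
        raise ValueError("dose must be non-negative")
    return dose_ug * 1e6 / molar_mass


def pk_curve(dose_ug: float, pk: PKParameters, t) -> np.ndarray:
    """Drug plasma concentration (pmol/L) at time(s) ``t`` minutes post-injection.

    Bateman solution of the absorption/elimination cascade; the coincident
    rate case ``k_a = k_e = k`` uses the limiting form ``k*t*exp(-k*t)``.
    """
    amount = dose_to_pmol(dose_ug, pk.molar_mass)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if math.isclose(pk.k_a, pk.k_e, rel_tol=1e-12):
        conc = (pk.F * amount * pk.k_a / pk.V_d) * t * np.exp(-pk.k_a * t)
    else:
        pref = pk.F * amount * pk.k_a / (pk.V_d * (pk.k_a - pk.k_e))
        conc = pref * (np.exp(-pk.k_e * t) - np.exp(-pk.k_a * t))
    return conc if conc.ndim else float(conc)


def pk_auc(dose_ug: float, pk: PKParameters) -> float:
    """Analytic AUC of the single-dose curve over [0, inf): ``F*dose/(V_d*k_e)``."""
    return pk.F * dose_to_pmol(dose_ug, pk.molar_mass) / (pk.V_d * pk.k_e)


def pk_peak(dose_ug: float, pk: PKParameters) -> tuple[float, float]:
    """Peak concentration (pmol/L) and its time (min) for a single dose."""
    if math.isclose(pk.k_a, pk.k_e, rel_tol=1e-12):
        t_max = 1.0 / pk.k_a
    else:
        t_max = math.log(pk.k_a / pk.k_e) / (pk.k_a - pk.k_e)
    return float(pk_curve(dose_ug, pk, t_max)), t_max


def injection_square_wave(
    dose_ug: float,
    pk: PKParameters,
    gamma0: float,
    T_inj: float = 1440.0,
) -> SquareWaveStimulus:
    """Equal-AUC, equal-peak square-wave reduction of the injection PK curve.

    The rectangle rides on the tonic baseline: its peak is
    ``gamma1 = gamma0 + max(L_PK)`` and its on-phase
    ``tau1 = AUC_PK / max(L_PK)``, so the area above ``gamma0`` over one
    dosing period matches the drug AUC exactly.  Under the linear PK model
    ``tau1`` is independent of the dose.
    """
    if dose_ug <= 0:
        raise ValueError("dose must be positive")
    c_max, _ = pk_peak(dose_ug, pk)
    if c_max <= 0:
        raise InfeasibilityError("PK peak does not rise above the tonic baseline")
    tau1 = pk_auc(dose_ug, pk) / c_max
    if tau1 > T_inj:
        raise InfeasibilityError(
            f"square-wave on-phase {tau1:.1f} min exceeds the dosing period {T_inj:.1f} min"
        )
    return SquareWaveStimulus(gamma0=gamma0, gamma1=gamma0 + c_max, tau1=tau1, T=T_inj)


@dataclass(frozen=True)
class CombinedStimulus:
    """Gland square wave with a superposed injection square wave (model 1 input).

    The summed ligand is ``L_gl(t) + L_inj(t) - gamma0`` by default: the
    injection wave's off-phase already sits at the tonic level, so the shared
    baseline must be counted once.  ``correct_baseline=False`` reproduces the
    naive sum.  The gland period is rescaled (by at most ``max_rescale``,
    default 2%) so that the injection period is an integer multiple of it.
    """

    gland: SquareWaveStimulus
    injection: SquareWaveStimulus | None
    correct_baseline: bool = True
    max_rescale: float = 0.02

    def __post_init__(self) -> None:
        if self.injection is not None and self.injection.gamma0 != self.gland.gamma0:
            raise ValueError("gland and injection waves must share the tonic baseline")

    @property
    def period(self) -> float:
        return self.gland.T if self.injection is None else self.injection.T

    def commensurate_gland(self) -> tuple[SquareWaveStimulus, int]:
        """Gland wave with period rescaled so the injection period divides it."""
        if self.injection is None:
            return self.gland, 1
        n = max(1, round(self.injection.T / self.gland.T))
        T_new = self.injection.T / n
        rel = abs(T_new - self.gland.T) / self.gland.T
        if rel > self.max_rescale:
            raise InfeasibilityError(
                f"gland period rescaling of {rel:.1%} needed for commensuration "
                f"exceeds the allowed {self.max_rescale:.1%}"
            )
        return replace(self.gland, T=T_new), n

    def segments_in_period(self) -> Sequence[tuple[float, float]]:
        """Constant segments of the summed ligand over one injection period."""
        gland, n = self.commensurate_gland()
        if self.injection is None:
            return gland.segments_in_period()
        base = self.gland.gamma0 if self.correct_baseline else 0.0
        cuts = {0.0, self.period}
        cuts.update(np.arange(n) * gland.T)
        cuts.update(np.arange(n) * gland.T + gland.tau1)
        cuts.add(min(self.injection.tau1, self.period))
        times = np.array(sorted(cuts))
        segs = []
        for t0, t1 in zip(times[:-1], times[1:]):
            if t1 - t0 < 1e-12:
                continue
            mid = 0.5 * (t0 + t1)
            level = float(gland.value(mid)) + float(self.injection.value(mid)) - base
            segs.append((t1 - t0, level))
        return segs

    def value(self, t):
        gland, _ = self.commensurate_gland()
        if self.injection is None:
            return gland.value(t)
        base = self.gland.gamma0 if self.correct_baseline else 0.0
        return gland.value(t) + self.injection.value(np.mod(t, self.period)) - base


@dataclass(frozen=True)
class CombinedResponsiveness:
    """Gland and injection responsiveness components and their total."""

    gland: ResponsivenessResult | None
    injection: ResponsivenessResult | None
    alpha_R_gland: float
    alpha_R_injection: float
    model: str

    @property
    def alpha_R_total(self) -> float:
        return self.alpha_R_gland + self.alpha_R_injection

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "alpha_R_gland": self.alpha_R_gland,
            "alpha_R_injection": self.alpha_R_injection,
            "alpha_R_total": self.alpha_R_total,
        }


def responsiveness_model2(
    gland: SquareWaveStimulus,
    injection: SquareWaveStimulus | None,
    params: KineticParameters,
    coeffs: ActivityCoefficients,
    tau_a_criterion: float = DEFAULT_TAU_A_CRITERION,
) -> CombinedResponsiveness:
    """Additive superposition: gland and injection responses computed independently.

    ``alpha_R = alpha_R(L_gl) + alpha_R(L_inj)``; with no injection the total
    is exactly the glandular responsiveness.
    """
    res_gl = cellular_responsiveness(gland, params, coeffs, tau_a_criterion)
    if injection is None:
        return CombinedResponsiveness(res_gl, None, res_gl.alpha_R, 0.0, model="model2")
    res_inj = cellular_responsiveness(injection, params, coeffs, tau_a_criterion)
    return CombinedResponsiveness(res_gl, res_inj, res_gl.alpha_R, res_inj.alpha_R, model="model2")


def responsiveness_model1(
    combined: CombinedStimulus,
    params: KineticParameters,
    coeffs: ActivityCoefficients,
    tau_a_criterion: float = DEFAULT_TAU_A_CRITERION,
) -> CombinedResponsiveness:
    """Single-simulation superposition with window-attributed responsiveness.

    The summed ligand is simulated over one injection period at the periodic
    steady state.  The activity integral over the injection on-phase
    ``[0, tau1_inj]`` is attributed to the injection and the remaining time
    to the gland, except that the burst areas of gland pulses falling inside
    the injection window (estimated from the gland-only pattern) are credited
    back to the gland — with rectified integrals those bursts do not cancel
    and would otherwise inflate the injection share.  Each component is then
    turned into a responsiveness with its own step response and period.
    """
    from .kinetics import _segment_propagator, periodic_steady_state

    gland, _ = combined.commensurate_gland()
    inj = combined.injection
    if inj is None:
        res = cellular_responsiveness(gland, params, coeffs, tau_a_criterion)
        return CombinedResponsiveness(res, None, res.alpha_R, 0.0, model="model1")
    T_inj = inj.T
    tau1_inj = inj.tau1
    alpha_0 = basal_activity(coeffs, params, gland.gamma0)

    x = periodic_steady_state(combined, params).as_array()
    w_act = coeffs.weights
    t = 0.0
    I_inj = 0.0
    I_gl = 0.0
    for dur, level in combined.segments_in_period():
        lam, w = _activity_modes(x, level, params, w_act)
        # split the segment at the injection-window boundary if it straddles it
        for t0, t1 in ((t, min(t + dur, tau1_inj)), (max(t, tau1_inj), t + dur)):
            if t1 - t0 > 1e-12:
                w_shift = w * np.exp(_stabilised(lam) * (t0 - t))
                val = _positive_excess_integral(lam, w_shift, alpha_0, t1 - t0)
                if t1 <= tau1_inj + 1e-12:
                    I_inj += val
                else:
                    I_gl += val
        x = _segment_propagator(level, dur, params) @ x
        t += dur

    # credit gland bursts inside the injection window back to the gland,
    # using the gland-only per-pulse burst area as the estimate
    from .activity import integrated_pulse_activity

    alpha_T_solo = (
        integrated_pulse_activity(gland, params, coeffs, alpha_0=alpha_0)
        if gland.gamma1 > gland.gamma0
        else 0.0
    )
    n_in_window = tau1_inj / gland.T
    I_inj -= n_in_window * alpha_T_solo
    I_gl += n_in_window * alpha_T_solo

    # glandular component: average per-pulse integral over the whole period
    n_gl_periods = T_inj / gland.T
    alpha_T_gl = I_gl / n_gl_periods if n_gl_periods > 0 else 0.0
    if gland.gamma1 > gland.gamma0:
        step_gl = step_response(gland.gamma0, gland.gamma1, params, coeffs, tau_a_criterion)
        alpha_R_gl = alpha_T_gl**2 / (step_gl.alpha_T_step * gland.T)
    else:
        alpha_R_gl = 0.0

    if tau1_inj > 0 and inj.gamma1 > inj.gamma0:
        step_inj = step_response(inj.gamma0, inj.gamma1, params, coeffs, tau_a_criterion)
        alpha_R_inj = I_inj**2 / (step_inj.alpha_T_step * T_inj)
    else:
        alpha_R_inj = 0.0
    return CombinedResponsiveness(None, None, alpha_R_gl, alpha_R_inj, model="model1")
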