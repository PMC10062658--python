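"""AUC-constrained optimisation of secretion patterns and injection dosing.

All problems hold the mean plasma PTH exposure fixed: the AUC of the stimulus
over a window ``s`` must equal a reference value ``A_ref``, and for glandular
patterns the pulsatile share must stay at the fraction ``r``.  Substituting
the square-wave closed form turns both constraints into explicit expressions

    gamma0 = gamma0_ref,      T = s * tau1 * (gamma1 - gamma0) / (r * A_ref),

leaving an unconstrained search over ``(gamma1, tau1)``; a design is feasible
only when the implied period exceeds the on-phase, i.e. when the pulse
amplitude exceeds the mean pulsatile concentration ``r * A_ref / s``.  The
searches use a Nelder-Mead simplex in log-transformed variables from a fixed
multistart grid, so results are deterministic; a coarse exhaustive grid search
is provided as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .activity import ActivityCoefficients, DEFAULT_TAU_A_CRITERION, cellular_responsiveness
from .errors import ConvergenceError, InfeasibilityError
from .kinetics import KineticParameters
from .stimulus import PKParameters, SquareWaveStimulus, auc_decomposition, injection_square_wave, pk_auc

__all__ = [
    "GlandularDesign",
    "OptimisationResult",
    "reduce_constraints",
    "maximise_glandular",
    "target_glandular",
    "maximise_injection",
    "target_injection_dose",
    "grid_oracle",
    "DEFAULT_TARGET_TOLERANCE",
]

#: absolute tolerance on |alpha_R - target| below which a target problem counts as solved
DEFAULT_TARGET_TOLERANCE = 1e-2

_PENALTY = 1e6


@dataclass(frozen=True)
class GlandularDesign:
    """A square-wave design implied by the AUC constraints.

    ``gamma1`` and ``tau1`` are the free variables; ``gamma0`` and ``T``
    follow from the constraint reduction for the window ``s``, the reference
    AUC ``A_ref`` and the pulsatile fraction ``r``.
    """

    gamma1: float
    tau1: float
    gamma0: float
    T: float
    s: float
    A_ref: float
    r: float

    @property
    def stimulus(self) -> SquareWaveStimulus:
        return SquareWaveStimulus(self.gamma0, self.gamma1, self.tau1, self.T)


@dataclass
class OptimisationResult:
    """Outcome of a pattern or dose optimisation.

    ``feasible`` is False when a target problem ends with a residual above
    tolerance or when no start satisfies the constraints; infeasibility of a
    target is a result state, not an exception.
    """

    design: dict
    stimulus: SquareWaveStimulus | None
    alpha_R: float
    objective: float
    converged: bool
    feasible: bool
    iterations: int
    restarts: int
    local_optima: list = field(default_factory=list)
    message: str = ""


def reduce_constraints(
    gamma1: float,
    tau1: float,
    gamma0_ref: float,
    r: float,
    A_ref: float,
    s: float,
) -> SquareWaveStimulus:
    """Square wave satisfying ``A = A_ref`` and ``A_puls = r * A`` exactly.

    Requires consistent inputs (``gamma0_ref * s = (1 - r) * A_ref``) and a
    pulse amplitude large enough that the implied period exceeds the
    on-phase; otherwise the design is infeasible.
    """
    if not (0 < r < 1):
        raise ValueError(f"pulsatile fraction must lie in (0, 1), got {r}")
    if min(A_ref, s, tau1) <= 0 or gamma1 <= gamma0_ref:
        raise ValueError("need A_ref, s, tau1 > 0 and gamma1 > gamma0_ref")
    if abs(gamma0_ref * s - (1.0 - r) * A_ref) > 1e-9 * A_ref:
        raise ValueError(
            "inconsistent constraint data: gamma0_ref * s must equal (1 - r) * A_ref"
        )
    T = s * tau1 * (gamma1 - gamma0_ref) / (r * A_ref)
    if T <= tau1:
        raise InfeasibilityError(
            f"implied period T={T:.4g} min does not exceed the on-phase tau1={tau1:.4g} min "
            f"(gamma1={gamma1:.4g}, amplitude below the mean pulsatile level {r * A_ref / s:.4g})"
        )
    return SquareWaveStimulus(gamma0=gamma0_ref, gamma1=gamma1, tau1=tau1, T=T)


def _glandular_constants(baseline: SquareWaveStimulus, r: float | None, s: float):
    dec = auc_decomposition(baseline, s)
    if r is None:
        r = dec.r
    # A_ref consistent with gamma0 and r so the reduction is exact
    A_ref = baseline.gamma0 * s / (1.0 - r)
    return r, A_ref


#: search box for the log-transformed design variables (min); keeps the
#: simplex away from numerically meaningless pulse shapes
_TAU1_BOX = (0.05, 1440.0)
_AMP_BOX = (1e-6, 1e5)


def _alpha_R_of_design(
    gamma1: float,
    tau1: float,
    gamma0: float,
    r: float,
    A_ref: float,
    s: float,
    params: KineticParameters,
    coeffs: ActivityCoefficients,
    tau_a_criterion: float,
) -> tuple[float, SquareWaveStimulus | None]:
    q = r * A_ref / s  # mean pulsatile concentration; amplitude must exceed it
    amp = gamma1 - gamma0
    if not (_TAU1_BOX[0] <= tau1 <= _TAU1_BOX[1]) or not (_AMP_BOX[0] <= amp <= _AMP_BOX[1]):
        return -_PENALTY * (1.0 + abs(math.log(max(tau1, 1e-300))) + abs(math.log(max(amp, 1e-300)))), None
    if amp <= q * (1.0 + 1e-12):
        return -_PENALTY * (1.0 + q - amp), None
    stim = reduce_constraints(gamma1, tau1, gamma0, r, A_ref, s)
    try:
        res = cellular_responsiveness(stim, params, coeffs, tau_a_criterion)
    except ConvergenceError:
        return -_PENALTY, None
    return res.alpha_R, stim


def _default_start_grid(gamma0: float, q: float) -> list[tuple[float, float]]:
    """3x3 multistart grid over (gamma1, tau1); amplitudes nudged into feasibility."""
    starts = []
    for f in (1.5, 3.0, 6.0):
        gamma1 = max(f * gamma0, gamma0 + 1.5 * q)
        for tau1 in (5.0, 10.0, 20.0):
            starts.append((gamma1, tau1))
    return starts


def _simplex_search(
    objective: Callable[[np.ndarray], float],
    starts: Sequence[tuple[float, float]],
    gamma0: float,
) -> tuple[np.ndarray | None, float, int, list]:
    """Minimise over u = (log(gamma1 - gamma0), log tau1) from every start."""
    best_u, best_f, total_iter, local = None, np.inf, 0, []
    for gamma1, tau1 in starts:
        u0 = np.array([math.log(gamma1 - gamma0), math.log(tau1)])
        res = minimize(
            objective,
            u0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 2000},
        )
        total_iter += res.nit
        local.append(
            {
                "gamma1": gamma0 + math.exp(res.x[0]),
                "tau1": math.exp(res.x[1]),
                "objective": float(res.fun),
                "converged": bool(res.success),
            }
        )
        if res.fun < best_f:
            best_u, best_f = res.x, float(res.fun)
    return best_u, best_f, total_iter, local


def maximise_glandular(
    baseline: SquareWaveStimulus,
    params: KineticParameters,
    coeffs: ActivityCoefficients,
    r: float | None = None,
    s: float = 1440.0,
    tau_a_criterion: float = DEFAULT_TAU_A_CRITERION,
    starts: Sequence[tuple[float, float]] | None = None,
) -> OptimisationResult:
    """Pattern of maximal responsiveness at fixed total and pulsatile AUC.

    Derivative-free simplex search over ``(gamma1, tau1)`` in log variables
    from a fixed multistart grid; the period follows from the constraint
    reduction.  The baseline pattern itself is always feasible, so the
    optimum can never fall below the baseline responsiveness.
    """
    gamma0 = baseline.gamma0
    r, A_ref = _glandular_constants(baseline, r, s)
    q = r * A_ref / s

    def objective(u: np.ndarray) -> float:
        if np.max(np.abs(u)) > 50:  # guard against simplex run-away before exp
            return _PENALTY * float(np.max(np.abs(u)))
        gamma1 = gamma0 + math.exp(u[0])
        tau1 = math.exp(u[1])
        alpha, _ = _alpha_R_of_design(gamma1, tau1, gamma0, r, A_ref, s, params, coeffs, tau_a_criterion)
        return -alpha

    starts = list(starts) if starts is not None else _default_start_grid(gamma0, q)
    best_u, best_f, iters, local = _simplex_search(objective, starts, gamma0)
    if best_u is None or best_f >= _PENALTY / 2:
        raise InfeasibilityError("no feasible design found from any start")
    gamma1 = gamma0 + math.exp(best_u[0])
    tau1 = math.exp(best_u[1])
    alpha, stim = _alpha_R_of_design(gamma1, tau1, gamma0, r, A_ref, s, params, coeffs, tau_a_criterion)
    return OptimisationResult(
        design={"gamma1": gamma1, "tau1": tau1, "T": stim.T, "gamma0": gamma0},
        stimulus=stim,
        alpha_R=alpha,
        objective=-best_f,
        converged=all(o["converged"] for o in local),
        feasible=True,
        iterations=iters,
        restarts=len(starts),
        local_optima=local,
    )


def target_glandular(
    baseline: SquareWaveStimulus,
    alphaR_target: float,
    params: KineticParameters,
    coeffs: ActivityCoefficients,
    r: float | None = None,
    s: float = 1440.0,
    tau_a_criterion: float = DEFAULT_TAU_A_CRITERION,
    tolerance: float = DEFAULT_TARGET_TOLERANCE,
    starts: Sequence[tuple[float, float]] | None = None,
) -> OptimisationResult:
    """Glandular pattern whose responsiveness matches a target value.

    Minimises the squared deviation ``(alpha_R - target)**2`` under the same
    AUC constraints as :func:`maximise_glandular`.  The problem is declared
    infeasible (``feasible=False``) when the final residual exceeds
    ``tolerance`` — e.g. when the target lies above the attainable maximum or
    below the attainable minimum responsiveness.
    """
    if alphaR_target <= 0:
        raise ValueError("target responsiveness must be positive")
    gamma0 = baseline.gamma0
    r, A_ref = _glandular_constants(baseline, r, s)
    q = r * A_ref / s

    def objective(u: np.ndarray) -> float:
        if np.max(np.abs(u)) > 50:
            return _PENALTY * float(np.max(np.abs(u)))
        gamma1 = gamma0 + math.exp(u[0])
        tau1 = math.exp(u[1])
        alpha, _ = _alpha_R_of_design(gamma1, tau1, gamma0, r, A_ref, s, params, coeffs, tau_a_criterion)
        if alpha <= -_PENALTY / 2:
            return -alpha
        return (alpha - alphaR_target) ** 2

    starts = list(starts) if starts is not None else _default_start_grid(gamma0, q)
    best_u, best_f, iters, local = _simplex_search(objective, starts, gamma0)
    if best_u is None:
        raise InfeasibilityError("no feasible design found from any start")
    gamma1 = gamma0 + math.exp(best_u[0])
    tau1 = math.exp(best_u[1])
    alpha, stim = _alpha_R_of_design(gamma1, tau1, gamma0, r, A_ref, s, params, coeffs, tau_a_criterion)
    residual = abs(alpha - alphaR_target)
    return OptimisationResult(
        design={"gamma1": gamma1, "tau1": tau1, "T": stim.T if stim else float("nan"), "gamma0": gamma0},
        stimulus=stim,
        alpha_R=alpha,
        objective=best_f,
        converged=all(o["converged"] for o in local),
        feasible=bool(residual <= tolerance),
        iterations=iters,
        restarts=len(starts),
        local_optima=local,
        message=f"|alpha_R - target| = {residual:.3g} (tolerance {tolerance:g})",
    )


def _injection_alpha_R(
    dose_ug: float,
    T: float,
    gamma0: float,
    pk: PKParameters,
    params: KineticParameters,
    coeffs: ActivityCoefficients,
    tau_a_criterion: float,
) -> tuple[float, SquareWaveStimulus]:
    stim = injection_square_wave(dose_ug, pk, gamma0, T_inj=T)
    return cellular_responsiveness(stim, params, coeffs, tau_a_criterion).alpha_R, stim


def maximise_injection(
    A_inj_ref: float,
    gamma0: float,
    pk: PKParameters,
    params: KineticParameters,
    coeffs: ActivityCoefficients,
    s: float = 1440.0,
    tau_a_criterion: float = DEFAULT_TAU_A_CRITERION,
    n_grid: int = 40,
) -> OptimisationResult:
    """Optimal per-injection dose at fixed total daily drug exposure.

    ``A_inj_ref`` is the drug AUC per window ``s`` of the reference regimen
    (e.g. 20 ug once daily).  For a candidate per-injection dose ``D`` the PK
    model fixes the square-wave reduction ``(gamma1, tau1)``, and AUC
    conservation fixes the dosing interval
    ``T = s * tau1 * (gamma1 - gamma0) / A_inj_ref``; the search is therefore
    one-dimensional over ``D`` (log-transformed, coarse grid then simplex).
    """
    if A_inj_ref <= 0:
        raise ValueError("reference injection AUC must be positive")
    auc_per_ug = pk_auc(1.0, pk)
    # feasibility: T > tau1 requires the per-dose AUC share to exceed tau1 / s
    tau1_fixed = injection_square_wave(1.0, pk, gamma0, T_inj=s).tau1
    d_min = tau1_fixed * A_inj_ref / (s * auc_per_ug)
    d_hi = 3.0 * A_inj_ref / auc_per_ug  # three reference doses per injection

    def neg_alpha(logd: np.ndarray) -> float:
        d = math.exp(float(np.atleast_1d(logd)[0]))
        T = s * auc_per_ug * d / A_inj_ref
        if T <= tau1_fixed * (1.0 + 1e-9):
            return _PENALTY * (1.0 + tau1_fixed / T)
        alpha, _ = _injection_alpha_R(d, T, gamma0, pk, params, coeffs, tau_a_criterion)
        return -alpha

    grid = np.exp(np.linspace(math.log(d_min * 1.05), math.log(d_hi), n_grid))
    vals = np.array([neg_alpha(np.array([math.log(d)])) for d in grid])
    if np.all(vals >= _PENALTY / 2):
        raise InfeasibilityError("no feasible per-injection dose in the search range")
    d0 = grid[int(np.argmin(vals))]
    res = minimize(
        neg_alpha,
        np.array([math.log(d0)]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    d_best = math.exp(float(res.x[0]))
    T_best = s * auc_per_ug * d_best / A_inj_ref
    alpha, stim = _injection_alpha_R(d_best, T_best, gamma0, pk, params, coeffs, tau_a_criterion)
    return OptimisationResult(
        design={"dose_ug": d_best, "T": T_best, "gamma1": stim.gamma1, "tau1": stim.tau1},
        stimulus=stim,
        alpha_R=alpha,
        objective=alpha,
        converged=bool(res.success),
        feasible=True,
        iterations=int(res.nit) + n_grid,
        restarts=1,
    )


def target_injection_dose(
    alphaR_ref: float,
    alphaR_ill: float,
    gamma0: float,
    pk: PKParameters,
    params: KineticParameters,
    coeffs: ActivityCoefficients,
    T_inj: float = 1440.0,
    tau_a_criterion: float = DEFAULT_TAU_A_CRITERION,
    tolerance: float = DEFAULT_TARGET_TOLERANCE,
    dose_bounds_ug: tuple[float, float] = (1e-3, 200.0),
    n_grid: int = 50,
) -> OptimisationResult:
    """Daily dose whose injection responsiveness fills the deficit to a reference.

    Solves ``min_D (alpha_R_inj(D) - (alphaR_ref - alphaR_ill))**2`` at a
    fixed dosing period (once daily by default).  A non-positive deficit
    needs no drug and returns ``D = 0``.
    """
    deficit = alphaR_ref - alphaR_ill
    if deficit <= 0:
        return OptimisationResult(
            design={"dose_ug": 0.0, "T": T_inj},
            stimulus=None,
            alpha_R=0.0,
            objective=deficit**2,
            converged=True,
            feasible=True,
            iterations=0,
            restarts=0,
            message="non-positive deficit: no injection required",
        )

    def sq_residual(logd: np.ndarray) -> float:
        d = math.exp(float(np.atleast_1d(logd)[0]))
        alpha, _ = _injection_alpha_R(d, T_inj, gamma0, pk, params, coeffs, tau_a_criterion)
        return (alpha - deficit) ** 2

    lo, hi = dose_bounds_ug
    grid = np.exp(np.linspace(math.log(lo), math.log(hi), n_grid))
    vals = np.array([sq_residual(np.array([math.log(d)])) for d in grid])
    d0 = grid[int(np.argmin(vals))]
    res = minimize(
        sq_residual,
        np.array([math.log(d0)]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
    )
    d_best = math.exp(float(res.x[0]))
    alpha, stim = _injection_alpha_R(d_best, T_inj, gamma0, pk, params, coeffs, tau_a_criterion)
    residual = abs(alpha - deficit)
    return OptimisationResult(
        design={"dose_ug": d_best, "T": T_inj, "gamma1": stim.gamma1, "tau1": stim.tau1},
        stimulus=stim,
        alpha_R=alpha,
        objective=float(res.fun),
        converged=bool(res.success),
        feasible=bool(residual <= tolerance),
        iterations=int(res.nit) + n_grid,
        restarts=1,
        message=f"|alpha_R_inj - deficit| = {residual:.3g} (tolerance {tolerance:g})",
    )


def grid_oracle(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    resolution: int | Sequence[int],
) -> tuple[np.ndarray, float]:
    """Exhaustive maximisation of ``objective`` on a regular grid.

    Deterministic independent check for the simplex searches: evaluates every
    grid point and returns the best; exact ties resolve to the
    lexicographically smallest point because the scan is in C order over
    increasing axes.
    """
    if isinstance(resolution, int):
        resolution = [resolution] * len(bounds)
    if any(r < 2 for r in resolution):
        raise ValueError("grid resolution must be at least 2 per axis")
    axes = [np.linspace(lo, hi, n) for (lo, hi), n in zip(bounds, resolution)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    vals = np.array([objective(p) for p in pts])
    best = int(np.argmax(vals))
    return pts[best], float(vals[best])
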