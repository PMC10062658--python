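"""Two-state receptor ligand-binding kinetics.

The receptor (PTH1R on osteoblastic cells) is modelled with four species:
active free receptor ``R_a``, active ligand-bound complex ``C_a``, inactive
complex ``C_i`` and inactive free receptor ``R_i``.  Working with fractions of
the total receptor pool, the state vector ``x = (r_a, c_a, c_i, r_i)`` evolves
under a linear ODE ``dx/dt = K(L) x`` whose coefficient matrix depends on the
(piecewise-constant) plasma ligand concentration ``L`` in pmol/L.  Because the
system is linear with piecewise-constant coefficients, every operation here is
carried out with matrix exponentials rather than time stepping: propagation is
exact to machine precision, conservation ``sum(x) = 1`` is inherited from the
zero column sums of ``K``, and the periodic steady state under a square-wave
stimulus is the fixed point of a one-period monodromy map.

Concentration unit is pmol/L throughout; dissociation constants quoted in
nmol/L are converted at the configuration boundary (1 nmol/L = 1000 pmol/L).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Protocol, Sequence

import numpy as np
from scipy.linalg import expm

from .errors import ConvergenceError

__all__ = [
    "KineticParameters",
    "ReceptorState",
    "Trajectory",
    "rate_matrix",
    "equilibrium_state",
    "propagate",
    "simulate",
    "periodic_steady_state",
    "NM_TO_PM",
]

#: conversion factor, 1 nmol/L expressed in pmol/L
NM_TO_PM = 1000.0

_CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the four-state receptor scheme.

    First-order conformational conversion rates (min^-1):

    * ``k1``       R_a -> R_i
    * ``k_minus1`` R_i -> R_a
    * ``k2``       C_a -> C_i
    * ``k_minus2`` C_i -> C_a

    Ligand binding/unbinding (``kr``/``k_minusr`` for the active complex,
    ``kd``/``k_minusd`` for the inactive complex); binding rates carry units
    pmol^-1 L min^-1 so that ``kr * L`` is a first-order rate.

    The ratios ``K1 = k_minus1/k1`` and ``K2 = k_minus2/k2`` are dimensionless;
    ``Kr = k_minusr/kr`` and ``Kd = k_minusd/kd`` are dissociation constants in
    pmol/L.  They are always recomputed from the rates, never stored.
    """

    k1: float = 0.012
    k_minus1: float = 0.104
    k2: float = 0.222
    k_minus2: float = 0.055
    k_minusr: float = 10.0
    k_minusd: float = 10.0
    kr: float = 10.0 / (1.0 * NM_TO_PM)
    kd: float = 10.0 / (1e3 * NM_TO_PM)

    def __post_init__(self) -> None:
        for name in ("k1", "k_minus1", "k2", "k_minus2", "k_minusr", "k_minusd", "kr", "kd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"rate constant {name} must be strictly positive")

    # -- derived dissociation constants -------------------------------------------------
    @property
    def K1(self) -> float:
        return self.k_minus1 / self.k1

    @property
    def K2(self) -> float:
        return self.k_minus2 / self.k2

    @property
    def Kr_pm(self) -> float:
        """Dissociation constant of the active complex, pmol/L."""
        return self.k_minusr / self.kr

    @property
    def Kd_pm(self) -> float:
        """Dissociation constant of the inactive complex, pmol/L."""
        return self.k_minusd / self.kd

    @property
    def Kr_nM(self) -> float:
        return self.Kr_pm / NM_TO_PM

    @property
    def Kd_nM(self) -> float:
        return self.Kd_pm / NM_TO_PM

    @classmethod
    def from_dissociation_constants(
        cls,
        *,
        k1: float = 0.012,
        k_minus1: float = 0.104,
        k2: float = 0.222,
        k_minus2: float = 0.055,
        Kr_nM: float = 1.0,
        Kd_nM: float = 1e3,
        k_minusr: float = 10.0,
        k_minusd: float = 10.0,
        detailed_balance: bool = False,
    ) -> "KineticParameters":
        """Build parameters from dissociation constants in nmol/L.

        Only the dissociation constants of the binding steps are usually
        reported; the absolute off-rates ``k_minusr`` and ``k_minusd`` set how
        fast binding equilibrates relative to the (much slower) conformational
        conversions and act as calibration knobs.  With ``detailed_balance``
        the inactive-complex constant is not taken from ``Kd_nM`` but computed
        from the thermodynamic cycle condition ``Kd = Kr * K2 / K1``, which
        makes the four-reaction loop free of net circulation at equilibrium.
        """
        K1 = k_minus1 / k1
        K2 = k_minus2 / k2
        if detailed_balance:
            Kd_nM = Kr_nM * K2 / K1
        return cls(
            k1=k1,
            k_minus1=k_minus1,
            k2=k2,
            k_minus2=k_minus2,
            k_minusr=k_minusr,
            k_minusd=k_minusd,
            kr=k_minusr / (Kr_nM * NM_TO_PM),
            kd=k_minusd / (Kd_nM * NM_TO_PM),
        )

    def with_off_rates(self, k_minusr: float, k_minusd: float | None = None) -> "KineticParameters":
        """Return a copy with rescaled binding off-rates at fixed Kr, Kd."""
        if k_minusd is None:
            k_minusd = k_minusr
        return replace(
            self,
            k_minusr=k_minusr,
            k_minusd=k_minusd,
            kr=k_minusr / self.Kr_pm,
            kd=k_minusd / self.Kd_pm,
        )


@dataclass(frozen=True)
class ReceptorState:
    """Receptor-pool fractions ``(r_a, c_a, c_i, r_i)``; they sum to one."""

    r_a: float
    c_a: float
    c_i: float
    r_i: float

    def __post_init__(self) -> None:
        vec = self.as_array()
        if np.any(vec < -1e-9) or np.any(vec > 1 + 1e-9):
            raise ValueError(f"receptor fractions must lie in [0, 1], got {vec}")
        if abs(vec.sum() - 1.0) > _CONSERVATION_TOL:
            raise ValueError(f"receptor fractions must sum to 1, got {vec.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.r_a, self.c_a, self.c_i, self.r_i])

    @classmethod
    def from_array(cls, vec: np.ndarray) -> "ReceptorState":
        vec = np.asarray(vec, dtype=float)
        # clip away harmless negative round-off before validating
        vec = np.where(np.abs(vec) < 1e-12, np.abs(vec), vec)
        return cls(*vec)


@dataclass
class Trajectory:
    """Sampled solution of the receptor ODE under a ligand signal.

    ``states`` has shape (n, 4) with columns ordered (r_a, c_a, c_i, r_i);
    ``ligand`` is the stimulus value at each sample (pmol/L).
    """

    time_min: np.ndarray
    states: np.ndarray
    ligand: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("trajectory time grid must be strictly increasing")
        resid = np.abs(self.states.sum(axis=1) - 1.0)
        if np.max(resid) > _CONSERVATION_TOL:
            raise ValueError(f"conservation violated along trajectory (max residual {resid.max():g})")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.time_min,
                "ligand_pmol_per_L": self.ligand,
                "r_a": self.states[:, 0],
                "c_a": self.states[:, 1],
                "c_i": self.states[:, 2],
                "r_i": self.states[:, 3],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class PiecewiseConstantStimulus(Protocol):
    """Any periodic, piecewise-constant ligand signal.

    Implementations provide the period, the ordered constant segments of one
    period and point evaluation; the kinetics layer needs nothing else.
    """

    @property
    def period(self) -> float: ...

    def segments_in_period(self) -> Sequence[tuple[float, float]]:
        """Ordered (duration_min, level_pmol_per_L) pairs covering one period."""
        ...

    def value(self, t): ...


def rate_matrix(L: float, params: KineticParameters) -> np.ndarray:
    """Coefficient matrix ``K(L)`` for the state ordering (r_a, c_a, c_i, r_i).

    Encodes R_a <-> R_i (k1/k_minus1), C_a <-> C_i (k2/k_minus2),
    R_a + L <-> C_a (kr/k_minusr) and R_i + L <-> C_i (kd/k_minusd).  Every
    column sums to zero, which is what preserves the receptor pool.
    """
    if L < 0:
        raise ValueError(f"ligand concentration must be non-negative, got {L}")
    p = params
    return np.array(
        [
            [-p.k1 - p.kr * L, p.k_minusr, 0.0, p.k_minus1],
            [p.kr * L, -p.k2 - p.k_minusr, p.k_minus2, 0.0],
            [0.0, p.k2, -p.k_minus2 - p.k_minusd, p.kd * L],
            [p.k1, 0.0, p.k_minusd, -p.k_minus1 - p.kd * L],
        ]
    )


@lru_cache(maxsize=4096)
def _eigenflow(L: float, params: KineticParameters):
    """Cached spectral decomposition of K(L) used for dense/in-segment evaluation."""
    K = rate_matrix(L, params)
    lam, V = np.linalg.eig(K)
    Vinv = np.linalg.inv(V)
    return lam, V, Vinv


@lru_cache(maxsize=4096)
def _segment_propagator(L: float, dt: float, params: KineticParameters) -> np.ndarray:
    return expm(rate_matrix(L, params) * dt)


def flow_modes(state_vec: np.ndarray, L: float, params: KineticParameters):
    """Spectral representation of t -> exp(K(L) t) @ state_vec.

    Returns ``(lam, modes)`` such that the solution is
    ``sum_i modes[:, i] * exp(lam[i] * t)`` (complex arithmetic; callers take
    the real part).  Used by the activity layer for vectorised evaluation of
    step responses and for exact in-segment time integrals.
    """
    lam, V, Vinv = _eigenflow(L, params)
    coeff = Vinv @ state_vec
    return lam, V * coeff[np.newaxis, :]


def equilibrium_state(L: float, params: KineticParameters) -> ReceptorState:
    """Steady state under a constant ligand level: the normalised null vector of K(L).

    The stationary distribution is unique: for ``L > 0`` the reaction graph is
    strongly connected, and at ``L = 0`` the bound states drain into the free
    ones, which balance at ``r_a / r_i = K1``.
    """
    K = rate_matrix(L, params)
    # Solve K x = 0 with sum(x) = 1 by replacing one (redundant) row.
    A = K.copy()
    A[3, :] = 1.0
    b = np.array([0.0, 0.0, 0.0, 1.0])
    x = np.linalg.solve(A, b)
    if np.any(x < -1e-10):
        raise ConvergenceError(f"stationary solve produced negative fractions: {x}")
    x = np.clip(x, 0.0, None)
    x /= x.sum()
    return ReceptorState.from_array(x)


def propagate(state: ReceptorState, L: float, dt: float, params: KineticParameters) -> ReceptorState:
    """Advance the state exactly over ``dt`` minutes of constant ligand ``L``."""
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt}")
    if dt == 0:
        return state
    P = _segment_propagator(L, dt, params)
    return ReceptorState.from_array(P @ state.as_array())


def _stimulus_breakpoints(stimulus: PiecewiseConstantStimulus, horizon: float):
    """Constant segments (t0, t1, level) of a periodic stimulus on [0, horizon]."""
    segs: list[tuple[float, float, float]] = []
    t = 0.0
    while t < horizon - 1e-12:
        for dur, level in stimulus.segments_in_period():
            if t >= horizon - 1e-12:
                break
            t1 = min(t + dur, horizon)
            if level < 0:
                raise ValueError("stimulus values must be non-negative")
            segs.append((t, t1, level))
            t = t1
    return segs


def simulate(
    stimulus: PiecewiseConstantStimulus,
    params: KineticParameters,
    horizon: float,
    dt_out: float = 0.1,
    initial: ReceptorState | None = None,
) -> Trajectory:
    """Integrate the receptor ODE over ``[0, horizon]`` and sample every ``dt_out`` min.

    The solution is advanced segment by segment with matrix exponentials
    (exact for the piecewise-constant ligand); within a segment the sample
    values come from the spectral representation of the same flow.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    x = (initial or equilibrium_state(_tonic_level(stimulus), params)).as_array()
    t_grid = np.arange(0.0, horizon + 0.5 * dt_out, dt_out)
    t_grid = t_grid[t_grid <= horizon + 1e-12]
    out = np.empty((t_grid.size, 4))
    lig = np.empty(t_grid.size)
    idx = 0
    for t0, t1, level in _stimulus_breakpoints(stimulus, horizon):
        in_seg = (t_grid >= t0 - 1e-12) & (t_grid < t1 - 1e-12)
        if t1 >= horizon - 1e-12:  # close the final segment
            in_seg |= np.isclose(t_grid, horizon)
        ts = t_grid[in_seg]
        if ts.size:
            lam, modes = flow_modes(x, level, params)
            vals = (modes @ np.exp(np.outer(lam, ts - t0))).T.real
            out[idx : idx + ts.size] = vals
            lig[idx : idx + ts.size] = level
            idx += ts.size
        x = _segment_propagator(level, t1 - t0, params) @ x
    return Trajectory(time_min=t_grid, states=out[: t_grid.size], ligand=lig[: t_grid.size])


def _tonic_level(stimulus: PiecewiseConstantStimulus) -> float:
    """Off-phase (tonic) level of a stimulus; falls back to the minimum segment level."""
    return min(level for _, level in stimulus.segments_in_period())


def monodromy_matrix(stimulus: PiecewiseConstantStimulus, params: KineticParameters) -> np.ndarray:
    """One-period propagator ``M`` with ``x(T) = M x(0)``."""
    M = np.eye(4)
    for dur, level in stimulus.segments_in_period():
        if dur > 0:
            M = _segment_propagator(level, dur, params) @ M
    return M


def periodic_steady_state(
    stimulus: PiecewiseConstantStimulus, params: KineticParameters
) -> ReceptorState:
    """State at the start of a period once the response has become periodic.

    ``M`` inherits unit column sums from the zero column sums of ``K``, so 1 is
    always an eigenvalue of the monodromy map; the periodic orbit is its fixed
    point, found by a direct linear solve.  All other eigenvalues must lie
    strictly inside the unit circle for the orbit to attract.
    """
    if not stimulus.period > 0:
        raise ValueError("stimulus period must be positive")
    M = monodromy_matrix(stimulus, params)
    eigvals = np.sort(np.abs(np.linalg.eigvals(M)))
    if eigvals[-2] >= 1.0 - 1e-12:
        raise ConvergenceError(
            f"one-period map is not contracting (second-largest |eigenvalue| {eigvals[-2]:.3e})"
        )
    A = M - np.eye(4)
    A[3, :] = 1.0
    x = np.linalg.solve(A, np.array([0.0, 0.0, 0.0, 1.0]))
    resid = np.max(np.abs(M @ x - x))
    if resid > 1e-10:
        raise ConvergenceError(f"periodic fixed point residual {resid:g} exceeds 1e-10")
    return ReceptorState.from_array(x)
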