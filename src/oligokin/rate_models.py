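"""Closed-form kinetic predictors for short RNA duplexes.

Three families of rates are predicted from sequence composition alone:

* association, via a nucleation-zipper model in which the two strands form
  an initial base-pair contact at a bimolecular rate k_bi and then either
  zipper (unimolecular rate k_uni) or fall apart; k_on is the contact rate
  times the nucleation success probability, summed over the N possible
  initial contacts;
* dissociation, via an Eyring barrier that grows linearly with duplex
  length, with per-base-pair contributions depending on CG content;
* toehold-mediated strand displacement, as a fast toehold pre-equilibrium
  (association constant K_A) followed by branch migration at a unimolecular
  rate k_s, giving k_displ = k_s * K_A, saturating at high invader
  concentration where branch migration becomes rate-limiting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import (
    FOUR_WAY_EXCHANGE_UPPER_BOUND,
    K_B,
    PLANCK_H,
    R_KCAL,
    T_DEFAULT,
)
from .thermo import dissociation_constant

# --------------------------------------------------------------------------
# parameter sets (defaults are the fitted constants for RNA at high salt)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalyticKineticParams:
    """Fitted constants of the analytic nucleation-zipper k_on model."""

    k_bi: float = 1.6e7  # M^-1 s^-1, productive collision rate per contact
    k_uni: float = 2.1e5  # s^-1, zippering rate per base-pair step

    def __post_init__(self) -> None:
        if self.k_bi <= 0 or self.k_uni <= 0:
            raise ValueError("kinetic constants must be positive")


@dataclass(frozen=True)
class EyringParams:
    """Eyring activation parameters for duplex dissociation.

    The barrier is dG_act = L*(f_CG*dgact_CG + (1-f_CG)*dgact_AU) +
    dgact_init; k_off = kappa*(k_B*T/h)*exp(-dG_act/(R*T)).
    """

    dgact_CG: float = 3.06  # kcal/mol per CG pair
    dgact_AU: float = 1.32  # kcal/mol per AU pair
    dgact_init: float = 3.18  # kcal/mol
    kappa: float = 1.0
    k_B: float = K_B
    h: float = PLANCK_H

    def __post_init__(self) -> None:
        if min(self.dgact_CG, self.dgact_AU, self.dgact_init) < 0:
            raise ValueError("activation energies must be >= 0")
        if not 0 < self.kappa <= 1:
            raise ValueError("transmission coefficient must be in (0, 1]")

    @classmethod
    def dna_rejali(cls) -> "EyringParams":
        """Averaged DNA parameterization of Rejali et al., for comparison."""
        return cls(dgact_CG=2.24, dgact_AU=1.19, dgact_init=5.12)


@dataclass(frozen=True)
class DisplacementParams:
    """Branch-migration constants for toehold-mediated displacement."""

    k_s: float = 8.9  # s^-1, unimolecular branch-migration rate
    four_way_upper_bound: float = FOUR_WAY_EXCHANGE_UPPER_BOUND

    def __post_init__(self) -> None:
        if self.k_s <= 0:
            raise ValueError("k_s must be positive")


# --------------------------------------------------------------------------
# association
# --------------------------------------------------------------------------


def initial_contact_delta_g(f_cg: float) -> float:
    """Apparent binding free energy of an initial base-pair contact,
    kcal/mol, as an empirical function of strand CG content:
    dG(f_CG) = -2.27*f_CG / (0.24 + f_CG). Always <= 0 and decreasing."""
    if not 0.0 <= f_cg <= 1.0:
        raise ValueError("f_CG must be in [0, 1]")
    return -2.27 * f_cg / (0.24 + f_cg)


def kon_cg_model(
    N: int,
    f_cg: float,
    p: AnalyticKineticParams = AnalyticKineticParams(),
    T: float = T_DEFAULT,
    R: float = R_KCAL,
) -> float:
    """Length-and-CG k_on predictor, M^-1 s^-1.

    k_on = N * k_bi * 2*k_uni / (2*k_uni + k_bi*K_D), with K_D the contact
    dissociation constant from :func:`initial_contact_delta_g` and N the
    length of the shorter strand (the number of in-register contacts).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    kd = dissociation_constant(initial_contact_delta_g(f_cg), T, R)
    return N * p.k_bi * 2.0 * p.k_uni / (2.0 * p.k_uni + p.k_bi * kd)


def kon_full_sum(
    contact_kds: Sequence[float],
    p: AnalyticKineticParams = AnalyticKineticParams(),
) -> float:
    """k_on as a sum of per-contact nucleation terms, M^-1 s^-1.

    Each initial contact i with dissociation constant K_D^i contributes
    k_bi * 2*k_uni / (2*k_uni + k_bi*K_D^i). Reduces to
    :func:`kon_cg_model` when all contacts share the CG-model K_D.
    """
    if len(contact_kds) == 0:
        raise ValueError("contact K_D list must be non-empty")
    total = 0.0
    for kd in contact_kds:
        if kd < 0:
            raise ValueError("contact K_D must be >= 0")
        if math.isinf(kd):
            continue  # a contact that never nucleates contributes 0
        total += p.k_bi * 2.0 * p.k_uni / (2.0 * p.k_uni + p.k_bi * kd)
    return total


# --------------------------------------------------------------------------
# dissociation
# --------------------------------------------------------------------------


def eyring_barrier(L: int, f_cg: float, p: EyringParams = EyringParams()) -> float:
    """Activation free energy for dissociation of an L-bp duplex, kcal/mol."""
    if L < 1:
        raise ValueError("duplex length must be >= 1")
    if not 0.0 <= f_cg <= 1.0:
        raise ValueError("f_CG must be in [0, 1]")
    return L * (f_cg * p.dgact_CG + (1.0 - f_cg) * p.dgact_AU) + p.dgact_init


def koff_eyring(
    L: int,
    f_cg: float,
    p: EyringParams = EyringParams(),
    T: float = T_DEFAULT,
    R: float = R_KCAL,
) -> float:
    """Eyring k_off, s^-1, strictly decreasing in L and f_CG."""
    dg_act = eyring_barrier(L, f_cg, p)
    return p.kappa * (p.k_B * T / p.h) * math.exp(-dg_act / (R * T))


def koff_thermodynamic(k_on: float, kd: float) -> float:
    """k_off = k_on * K_D (the thermodynamic consistency route)."""
    if k_on < 0 or kd < 0:
        raise ValueError("rates and K_D must be >= 0")
    return k_on * kd


# --------------------------------------------------------------------------
# strand displacement
# --------------------------------------------------------------------------


def kdispl_model(
    dg_toehold: float,
    p: DisplacementParams = DisplacementParams(),
    T: float = T_DEFAULT,
    R: float = R_KCAL,
) -> float:
    """Second-order displacement rate k_displ = k_s * K_A, M^-1 s^-1.

    K_A = exp(dG_toehold/(R*T)) per molar, with dG_toehold >= 0 the toehold
    binding energy (unbound-minus-bound). No saturation is applied here;
    see :func:`apparent_bimolecular_limit` for the strong-toehold regime.
    """
    if dg_toehold < 0:
        raise ValueError("dG_toehold must be >= 0")
    return p.k_s * math.exp(dg_toehold / (R * T))


def displacement_trace(
    k_on: float,
    k_s: float,
    c0: float,
    ab0: float,
    t: Sequence[float],
) -> np.ndarray:
    """Released strand concentration [A](t) of the irreversible
    consecutive-reaction displacement model.

    Toehold binding of the invader C (pseudo-first-order at rate k_on*[C]0,
    valid for [C]0 >> [AB]0) is followed by branch migration at k_s:

        [A](t) = [AB]0 * {1 + (k_s*exp(-k1*t) - k1*exp(-k_s*t)) / (k1 - k_s)}

    with k1 = k_on*[C]0. The degenerate k1 == k_s limit is handled
    analytically.
    """
    if min(k_on, k_s, c0, ab0) < 0:
        raise ValueError("rates and concentrations must be >= 0")
    t = np.asarray(t, dtype=float)
    k1 = k_on * c0
    if math.isclose(k1, k_s, rel_tol=1e-12):
        return ab0 * (1.0 - (1.0 + k1 * t) * np.exp(-k1 * t))
    return ab0 * (
        1.0 + (k_s * np.exp(-k1 * t) - k1 * np.exp(-k_s * t)) / (k1 - k_s)
    )


def characteristic_timescale(t: Sequence[float], trace: Sequence[float]) -> float:
    """Time at which a monotone trace reaches 1 - 1/e of its plateau.

    The plateau is the final trace value; the crossing time is interpolated
    linearly between grid points.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(trace, dtype=float)
    plateau = y[-1]
    target = (1.0 - math.exp(-1.0)) * plateau
    idx = np.nonzero(y >= target)[0]
    if idx.size == 0:
        raise ValueError("trace does not reach 1 - 1/e of its plateau on the grid")
    i = idx[0]
    if i == 0:
        return float(t[0])
    # linear interpolation between bracketing points
    t0, t1 = t[i - 1], t[i]
    y0, y1 = y[i - 1], y[i]
    return float(t0 + (target - y0) * (t1 - t0) / (y1 - y0))


def apparent_bimolecular_limit(
    k_on: float,
    k_s: float,
    c0: float,
    n_grid: int = 500,
) -> float:
    """Apparent second-order displacement rate in the saturating regime,
    M^-1 s^-1.

    Generates the consecutive-reaction trace, fits the invader-in-excess
    irreversible second-order model [A](t) = [AB]0*(1 - exp(-k*[C]0*t)) to
    it over t in [0, 5 * characteristic timescale] (uniform grid), and
    returns the fitted k. Bounded above by both k_on (toehold binding
    limits) and k_s/[C]0 (branch migration limits).
    """
    if min(k_on, k_s, c0) <= 0:
        raise ValueError("inputs must be positive")
    # locate the timescale on a provisional grid spanning both processes
    slow = 1.0 / min(k_on * c0, k_s)
    t_probe = np.linspace(0.0, 20.0 * slow, 4000)
    tau = characteristic_timescale(t_probe, displacement_trace(k_on, k_s, c0, 1.0, t_probe))
    t = np.linspace(0.0, 5.0 * tau, n_grid)
    y = displacement_trace(k_on, k_s, c0, 1.0, t)

    def resid(log_k):
        k = math.exp(log_k[0])
        return 1.0 - np.exp(-k * c0 * t) - y

    x0 = math.log(min(k_on, k_s / c0))
    sol = least_squares(resid, [x0], method="lm")
    if not sol.success:
        raise RuntimeError("apparent-rate fit did not converge")
    return math.exp(sol.x[0])


def migration_step_rate(k_s: float, N: int) -> float:
    """Elementary branch-migration step rate k_mig = k_s * N^2, s^-1.

    An unbiased random walk over an N-step branch-migration domain
    completes in ~N^2 elementary steps (gambler's-ruin argument), so the
    observed unimolecular rate k_s corresponds to k_mig = k_s * N^2.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if k_s <= 0:
        raise ValueError("k_s must be positive")
    return k_s * N * N
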