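"""Kinetic parameter recovery from stopped-flow and displacement traces.

Association traces are fit globally across concentrations to the reversible
bimolecular scheme A + B <-> AB integrated numerically; displacement traces
to the irreversible second-order scheme AB + C -> products. Fits use
trust-region least squares with log-spaced multi-starts; covariances come
from the Jacobian at the optimum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares


@dataclass
class KineticTrace:
    """A time-resolved signal with concentration metadata.

    ``a0``/``b0`` are the post-mixing reactant concentrations (molar); for
    displacement traces ``a0`` is the initial duplex and ``b0`` the invader.
    Signals are either raw fluorescence (normalize first) or fraction of
    the tracked strand remaining unbound.
    """

    t: np.ndarray
    signal: np.ndarray
    a0: float
    b0: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if self.a0 <= 0 or self.b0 < 0:
            raise ValueError(
                "concentrations must be positive (b0 may be 0 for buffer controls)"
            )


def normalize_stopped_flow(trace: KineticTrace, control: KineticTrace) -> KineticTrace:
    """Map a raw fluorescence trace onto the fraction-unbound scale.

    The control experiment (fluorescent strand mixed with buffer only)
    defines the unquenched plateau; the normalized signal is
    trace / control-plateau, so a fully unbound sample reads 1 and a fully
    quenched plateau approaches the residual quench level.
    """
    span = control.t.min(), control.t.max()
    if trace.t.min() < span[0] - 1e-12 or trace.t.max() > span[1] + 1e-12:
        raise ValueError("control trace does not cover the sample's time span")
    plateau = float(np.median(control.signal))
    if plateau <= 0 or np.std(control.signal) > 0.2 * abs(plateau):
        raise ValueError("control plateau undetectable")
    return KineticTrace(
        t=trace.t,
        signal=trace.signal / plateau,
        a0=trace.a0,
        b0=trace.b0,
        meta={**trace.meta, "normalized": True},
    )


@dataclass(frozen=True)
class FitResult:
    k_on: float
    k_off: float
    covariance: np.ndarray  # in log-parameter space
    residual_norm: float
    n_starts_tried: int


def _bimolecular_fraction_unbound(
    t: np.ndarray, a0: float, b0: float, k_on: float, k_off: float
) -> np.ndarray:
    """Fraction of A unbound over time for A + B <-> AB, [AB](0) = 0."""

    def rhs(_t, y):
        ab = y[0]
        return [k_on * (a0 - ab) * (b0 - ab) - k_off * ab]

    sol = solve_ivp(
        rhs, (0.0, t[-1]), [0.0], t_eval=t, method="LSODA", rtol=1e-10, atol=a0 * 1e-12
    )
    if not sol.success:
        raise RuntimeError("trace model integration failed")
    return (a0 - sol.y[0]) / a0


def fit_bimolecular_global(
    traces: Sequence[KineticTrace],
    weak_binding: bool = False,
    n_starts: int = 5,
) -> FitResult:
    """Global (k_on[, k_off]) fit across association traces.

    ``weak_binding`` selects the joint (k_on, k_off) fit; otherwise k_off
    is fixed at zero (strong binders dissociate negligibly on the observed
    time scale). Signals must be on the fraction-unbound scale. Multi-start
    over log-spaced k_on initials; the best converged start wins.
    """
    if len(traces) < 1:
        raise ValueError("at least one trace required")
    if weak_binding and len(traces) < 2:
        warnings.warn(
            "joint (k_on, k_off) fit from a single trace is ill-conditioned; "
            "k_on/k_off are nearly degenerate",
            RuntimeWarning,
        )

    def resid(logp):
        k_on = math.exp(logp[0])
        k_off = math.exp(logp[1]) if weak_binding else 0.0
        parts = []
        for tr in traces:
            model = _bimolecular_fraction_unbound(tr.t, tr.a0, tr.b0, k_on, k_off)
            parts.append(model - tr.signal)
        return np.concatenate(parts)

    best: Optional[least_squares] = None
    tried = 0
    for k0 in np.logspace(4, 8, n_starts):
        x0 = [math.log(k0)] + ([math.log(0.1)] if weak_binding else [])
        tried += 1
        try:
            sol = least_squares(resid, x0, ftol=1e-10, xtol=1e-12)
        except RuntimeError:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("bimolecular fit failed to converge from any start")
    cov = _covariance(best)
    k_on = math.exp(best.x[0])
    k_off = math.exp(best.x[1]) if weak_binding else 0.0
    return FitResult(k_on, k_off, cov, float(np.linalg.norm(best.fun)), tried)


def _displacement_released_fraction(
    t: np.ndarray, ab0: float, c0: float, k: float
) -> np.ndarray:
    """Released fraction for the irreversible second-order AB + C -> products.

    Closed form via the standard unequal-concentration solution; the equal
    concentration case degenerates to 1/(1 + k*c*t) kinetics.
    """
    if math.isclose(ab0, c0, rel_tol=1e-9):
        ab = ab0 / (1.0 + k * ab0 * t)
    else:
        d = c0 - ab0
        e = np.exp(np.clip(-k * d * t, -700, 700))
        ab = ab0 * d * e / (c0 - ab0 * e)
    return (ab0 - ab) / ab0


def fit_displacement_global(traces: Sequence[KineticTrace], n_starts: int = 5) -> FitResult:
    """Global k_displ fit across displacement traces at >= 2 invader
    concentrations; the model is the irreversible second-order reaction
    AB + C -> AC + B. Signals are the released fraction of the duplex."""
    if len(traces) < 2:
        raise ValueError("displacement fitting requires traces at >= 2 concentrations")

    def resid(logk):
        k = math.exp(logk[0])
        parts = []
        for tr in traces:
            model = _displacement_released_fraction(tr.t, tr.a0, tr.b0, k)
            parts.append(model - tr.signal)
        return np.concatenate(parts)

    best = None
    tried = 0
    for k0 in np.logspace(1, 7, n_starts):
        tried += 1
        sol = least_squares(resid, [math.log(k0)], ftol=1e-10, xtol=1e-12)
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("displacement fit failed to converge from any start")
    return FitResult(
        k_on=math.exp(best.x[0]),
        k_off=0.0,
        covariance=_covariance(best),
        residual_norm=float(np.linalg.norm(best.fun)),
        n_starts_tried=tried,
    )


def _covariance(sol) -> np.ndarray:
    J = sol.jac
    dof = max(J.shape[0] - J.shape[1], 1)
    s2 = 2.0 * sol.cost / dof
    try:
        return s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return np.full((J.shape[1], J.shape[1]), np.nan)
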