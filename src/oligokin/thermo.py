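"""Two-state nearest-neighbor duplex thermodynamics and melting analysis.

A duplex between two fully complementary strands is treated as a two-state
system (bound/unbound, no ensemble of suboptimal configurations): its
formation free energy is the sum of nearest-neighbor stack terms, one
bimolecular initiation term, and a penalty per terminal A-U pair. The sign
convention is bound-minus-unbound throughout, so a stable duplex has
dG < 0 and K_D = exp(dG/(R*T)) << 1 M.

Toehold binding free energies use the opposite (unbound-minus-bound)
convention: dG_toehold >= 0 for any genuine toehold, and the toehold
association constant is K_A = exp(dG_toehold/(R*T)) per molar.

Melting analysis implements the fluorescence route (fraction unbound ->
K_D(T) -> Van't Hoff regression) and the UV route (ln(c_tot/4) vs 1/Tm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import R_KCAL, T_DEFAULT
from .params import NNParameterSet, DEFAULT_NN
from .strands import RnaStrand, is_full_duplex


class NotTwoStateDuplexError(ValueError):
    """Raised when two strands are not fully Watson-Crick complementary."""


class ToeholdGeometryError(ValueError):
    """Raised when a toehold context is geometrically inconsistent."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplexThermo:
    """Two-state duplex thermodynamics: dH (kcal/mol), dS (kcal/mol/K)."""

    dH: float
    dS: float

    def dg(self, T: float) -> float:
        """Binding free energy dG(T) = dH - T*dS, kcal/mol."""
        return self.dH - T * self.dS

    def kd(self, T: float, R: float = R_KCAL) -> float:
        """Dissociation constant at T, molar (1 M standard state)."""
        return dissociation_constant(self.dg(T), T, R)

    def tm(self, c_tot: float, R: float = R_KCAL) -> float:
        """Melting temperature (K) of an equimolar duplex at total strand
        concentration ``c_tot``; at Tm the dissociation constant equals
        c_tot/4."""
        return self.dH / (self.dS + R * math.log(c_tot / 4.0))


@dataclass
class MeltingObservation:
    """A normalized melting curve: fraction unbound f(T).

    ``a_tot`` is the total concentration of the tracked strand A and
    ``delta`` the excess of its partner B over A (both molar).
    """

    temperature: np.ndarray
    fraction_unbound: np.ndarray
    a_tot: float
    delta: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fraction_unbound = np.asarray(self.fraction_unbound, dtype=float)
        if self.a_tot <= 0:
            raise ValueError("a_tot must be positive")
        if self.delta < 0:
            raise ValueError("delta (excess of B over A) must be >= 0")


@dataclass(frozen=True)
class ToeholdContext:
    """Geometry of a toehold-mediated displacement reaction.

    ``template`` carries the toehold; ``incumbent`` occupies a contiguous
    register on the template; ``invader`` covers that register plus the
    toehold. ``side`` says on which end of the template the toehold sits.
    """

    template: RnaStrand
    incumbent: RnaStrand
    invader: RnaStrand
    side: str  # "5p" | "3p" | "none"
    toehold_length: int
    incumbent_register: tuple[int, int]  # [start, end) on template
    invader_register: tuple[int, int]

    @classmethod
    def infer(
        cls, template: RnaStrand, incumbent: RnaStrand, invader: RnaStrand
    ) -> "ToeholdContext":
        inc = _binding_register(template, incumbent)
        inv = _binding_register(template, invader)
        if not (inv[0] <= inc[0] and inc[1] <= inv[1]):
            raise ToeholdGeometryError(
                "invader register must cover the incumbent register"
            )
        left = inc[0] - inv[0]
        right = inv[1] - inc[1]
        if left and right:
            raise ToeholdGeometryError(
                "invader extends past the incumbent on both sides; "
                "a single contiguous toehold is required"
            )
        if left:
            side, n = "5p", left
        elif right:
            side, n = "3p", right
        else:
            side, n = "none", 0
        return cls(template, incumbent, invader, side, n, inc, inv)


def _binding_register(template: RnaStrand, strand: RnaStrand) -> tuple[int, int]:
    """[start, end) slice of the template to which ``strand`` is fully
    complementary (antiparallel)."""
    target = strand.reverse_complement().bases
    pos = template.bases.find(target)
    if pos < 0:
        raise ToeholdGeometryError(
            f"{strand.name!r} has no full complementary register on "
            f"{template.name!r}"
        )
    return pos, pos + len(target)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def duplex_delta_g(
    a: RnaStrand,
    b: RnaStrand,
    params: NNParameterSet = DEFAULT_NN,
    T: float = T_DEFAULT,
) -> DuplexThermo:
    """Two-state NN thermodynamics of the duplex a:b.

    Requires b to be the exact reverse complement of a. 2Ap positions are
    treated as A. Returns the DuplexThermo (dH, dS); evaluate ``.dg(T)`` /
    ``.kd(T)`` for the temperature-dependent quantities.
    """
    if not is_full_duplex(a, b):
        raise NotTwoStateDuplexError(
            f"{a.name!r} and {b.name!r} are not fully complementary; "
            "not a two-state duplex"
        )
    seq = a.bases
    dH = params.init_dH
    dS = params.init_dS
    for i in range(len(seq) - 1):
        top = seq[i : i + 2]
        dH += params.stack_dH[top]
        dS += params.stack_dS[top]
    for idx in {0, len(seq) - 1}:  # a 1-bp duplex has a single terminus
        if seq[idx] in "AU":
            dH += params.terminal_au_dH
            dS += params.terminal_au_dS
    return DuplexThermo(dH=dH, dS=dS)


_EXP_CLAMP = 500.0


def dissociation_constant(dg_binding: float, T: float, R: float = R_KCAL) -> float:
    """K_D = exp(dG_binding/(R*T)), molar. dG_binding is bound-minus-unbound."""
    if R <= 0 or T <= 0:
        raise ValueError("R and T must be positive")
    x = dg_binding / (R * T)
    if abs(x) > _EXP_CLAMP:
        warnings.warn("K_D exponent clamped to avoid overflow", RuntimeWarning)
        x = math.copysign(_EXP_CLAMP, x)
    return math.exp(x)


def toehold_delta_g(
    ctx: ToeholdContext,
    params: NNParameterSet = DEFAULT_NN,
    T: float = T_DEFAULT,
) -> float:
    """Binding free energy of the invader to the toehold, kcal/mol (>= 0).

    Computed as minus the NN stack sum over the toehold base pairs,
    including the junction stack that joins the toehold helix to the
    incumbent duplex. An n-nt toehold therefore contributes n stack terms.
    Zero-length toeholds are out of contract: use :func:`zero_toehold_delta_g`.
    """
    n = ctx.toehold_length
    if n < 1:
        raise ValueError(
            "toehold length must be >= 1; zero-toehold displacement is "
            "handled by zero_toehold_delta_g"
        )
    s, e = ctx.incumbent_register
    if ctx.side == "5p":
        window = ctx.template.bases[s - n : s + 1]
    else:
        window = ctx.template.bases[e - 1 : e + n]
    total = sum(
        params.stack_dg(window[i : i + 2], T) for i in range(len(window) - 1)
    )
    return -total


def zero_toehold_delta_g(
    dg5: Optional[float],
    dg3: Optional[float],
    T: float = T_DEFAULT,
    R: float = R_KCAL,
) -> float:
    """Apparent toehold energy of a blunt-ended (zero-toehold) invasion.

    Displacement without a toehold proceeds through transiently frayed
    terminal base pairs at either duplex end; with effective end energies
    dG5 and dG3 (>= 0, unbound-minus-bound), the apparent energy is
    RT*ln(exp(dG5/RT) + exp(dG3/RT)). Pass None for an absent end.
    """
    if dg5 is None and dg3 is None:
        raise ValueError("at least one duplex end must provide a frayed-end toehold")
    if dg5 is None:
        return float(dg3)
    if dg3 is None:
        return float(dg5)
    rt_ = R * T
    return rt_ * float(np.logaddexp(dg5 / rt_, dg3 / rt_))


def frayed_end_energies(
    a: RnaStrand,
    b: RnaStrand,
    params: NNParameterSet = DEFAULT_NN,
    T: float = T_DEFAULT,
) -> tuple[float, float]:
    """Default frayed-end toehold energies (dG5, dG3) of the duplex a:b.

    Each end's effective zero-length-toehold energy is the magnitude of the
    terminal NN stack at that end of the duplex (the energy an invader gains
    by capturing the transiently open terminal pair). Pluggable: any provider
    returning two non-negative energies can replace this.
    """
    if not is_full_duplex(a, b):
        raise NotTwoStateDuplexError("frayed-end model requires a full duplex")
    seq = a.bases
    dg5 = -params.stack_dg(seq[:2], T)
    dg3 = -params.stack_dg(seq[-2:], T)
    return dg5, dg3


def melt_kd_from_fraction(obs: MeltingObservation) -> np.ndarray:
    """Per-temperature K_D from the unbound fraction.

    K_D(T) = ((f*A_tot)^2 + f*A_tot*Delta) / (A_tot*(1-f)). Points with
    f >= 1 (fully melted) are reported as +inf rather than raised.
    """
    f = obs.fraction_unbound
    if np.any(f < 0):
        raise ValueError("fraction unbound must be >= 0")
    a = obs.a_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        kd = ((f * a) ** 2 + f * a * obs.delta) / (a * (1.0 - f))
    kd = np.where(f >= 1.0, np.inf, kd)
    return kd


@dataclass(frozen=True)
class VantHoffFit:
    dH: float
    dS: float
    residuals: np.ndarray
    covariance: np.ndarray  # 2x2 for (slope, intercept) of ln K_D vs 1/T

    def duplex(self) -> DuplexThermo:
        return DuplexThermo(self.dH, self.dS)


def vant_hoff_fit(
    temperature: Sequence[float],
    kd: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    R: float = R_KCAL,
) -> VantHoffFit:
    """Van't Hoff regression of ln K_D on 1/T.

    With the bound-minus-unbound convention, ln K_D = dH/(R*T) - dS/R, so
    the slope is dH/R and the intercept -dS/R. Requires >= 3 points with
    finite positive K_D.
    """
    T = np.asarray(temperature, dtype=float)
    kd = np.asarray(kd, dtype=float)
    ok = np.isfinite(kd) & (kd > 0)
    T, kd = T[ok], kd[ok]
    w = None if weights is None else np.asarray(weights, dtype=float)[ok]
    if T.size < 3:
        raise ValueError("Van't Hoff fit requires at least 3 usable points")
    x = 1.0 / T
    y = np.log(kd)
    coef, cov = np.polyfit(x, y, 1, w=w, cov="unscaled" if w is not None else True)
    slope, intercept = coef
    resid = y - (slope * x + intercept)
    return VantHoffFit(dH=slope * R, dS=-intercept * R, residuals=resid, covariance=cov)


def uv_melt_fit(
    c_tot: Sequence[float],
    tm: Sequence[float],
    R: float = R_KCAL,
) -> VantHoffFit:
    """Recover (dH, dS) from UV melting temperatures of equimolar duplexes.

    At the Tm of an equimolar duplex, K_D = c_tot/4, so the Van't Hoff plot
    of ln(c_tot/4) versus 1/Tm has slope dH/R and intercept -dS/R.
    Requires >= 2 distinct total concentrations.
    """
    c = np.asarray(c_tot, dtype=float)
    T = np.asarray(tm, dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("uv_melt_fit needs >= 2 distinct total concentrations")
    x = 1.0 / T
    y = np.log(c / 4.0)
    coef, cov = np.polyfit(x, y, 1, cov="unscaled")
    slope, intercept = coef
    resid = y - (slope * x + intercept)
    return VantHoffFit(dH=slope * R, dS=-intercept * R, residuals=resid, covariance=cov)


def normalize_melting_curve(
    temperature: Sequence[float],
    signal: Sequence[float],
    low_window: tuple[float, float],
    high_window: tuple[float, float],
    a_tot: float,
    delta: float = 0.0,
) -> MeltingObservation:
    """Baseline-correct and normalize a raw melting signal to f in [0, 1].

    Linear baselines are fitted in the low- and high-temperature windows
    (temperature ranges in the same units as ``temperature``); the unbound
    fraction is f = (S - S_low(T)) / (S_high(T) - S_low(T)), clipped to
    [0, 1]. Descending (quench-type) signals are handled automatically by
    the same formula and flagged in the diagnostics. A warning (not an
    error) is emitted when a baseline window appears to overlap the
    transition.
    """
    T = np.asarray(temperature, dtype=float)
    S = np.asarray(signal, dtype=float)
    base_low = _fit_baseline(T, S, low_window)
    base_high = _fit_baseline(T, S, high_window)
    span = np.polyval(base_high, T) - np.polyval(base_low, T)
    if np.any(span == 0):
        raise ValueError("degenerate baselines: zero dynamic range")
    f = (S - np.polyval(base_low, T)) / span
    inverted = float(np.median(span)) < 0
    # slope heterogeneity check: a baseline window that caught part of the
    # transition has a slope comparable to the transition's own slope
    steepest = float(np.max(np.abs(np.gradient(S, T))))
    for name, base in (("low", base_low), ("high", base_high)):
        if steepest > 0 and abs(base[0]) > 0.3 * steepest:
            warnings.warn(
                f"{name}-temperature baseline window may overlap the melting "
                "transition",
                RuntimeWarning,
            )
    return MeltingObservation(
        temperature=T,
        fraction_unbound=np.clip(f, 0.0, 1.0),
        a_tot=a_tot,
        delta=delta,
        diagnostics={
            "baseline_low": tuple(base_low),
            "baseline_high": tuple(base_high),
            "inverted_signal": inverted,
        },
    )


def _fit_baseline(T: np.ndarray, S: np.ndarray, window: tuple[float, float]):
    lo, hi = window
    m = (T >= lo) & (T <= hi)
    if m.sum() < 2:
        raise ValueError(f"baseline window {window} contains < 2 points")
    return np.polyfit(T[m], S[m], 1)
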