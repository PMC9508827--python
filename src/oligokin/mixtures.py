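"""Mass-action reaction networks for competing four-strand RNA mixtures.

The canonical experiment mixes four strands: a long complementary pair
(A_L, B_L) and truncated versions of each (A_S, B_S), so every A strand can
pair with every B strand. On mixing, all four duplexes (A_S:B_S, A_L:B_L,
A_L:B_S, A_S:B_L) form within seconds in proportion to their hybridization
rates; the mixture then relaxes toward its free-energy minimum (only
A_S:B_S and A_L:B_L) through two competing pathways: direct hybridization
of transiently free long strands, and toehold-mediated strand displacement
through the overhangs the short duplexes expose. Four-way strand exchange
between two duplexes is excluded (experimentally bounded below
~1e2 M^-1 s^-1 and negligible here).

Rate constants are supplied by the closed-form predictors: k_on from the
CG-content nucleation model, k_off from the Eyring barrier, k_displ from
the toehold pre-equilibrium model. Displacement channels are reversible:
each reverse (zero-toehold) rate is assigned by detailed balance against
the network's own duplex dissociation constants k_off/k_on, so the
stationary state of the full network coincides with the hybridization
equilibrium.

The experimental observable is the fluorescence of a 2-aminopurine
reporter placed in B_L where only A_L quenches it: signal tracks
([B_L free] + [A_S:B_L]) / [B_L total].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .constants import R_KCAL, T_DEFAULT
from .rate_models import (
    AnalyticKineticParams,
    DisplacementParams,
    EyringParams,
    apparent_bimolecular_limit,
    kdispl_model,
    koff_eyring,
    kon_cg_model,
)
from .strands import RnaStrand
from .thermo import ToeholdContext, toehold_delta_g

SPECIES = ("A_S", "A_L", "B_S", "B_L", "A_S:B_S", "A_L:B_L", "A_L:B_S", "A_S:B_L")


@dataclass(frozen=True)
class KineticBundle:
    """Predictor parameter sets used to derive the network rate constants."""

    analytic: AnalyticKineticParams = AnalyticKineticParams()
    eyring: EyringParams = EyringParams()
    displacement: DisplacementParams = DisplacementParams()
    T: float = T_DEFAULT
    R: float = R_KCAL
    # multiplicative adjustments, used by the uncertainty resampling
    kon_factor: float = 1.0
    koff_factor: float = 1.0
    kdispl_factor: float = 1.0


@dataclass(frozen=True)
class MixtureSpec:
    """Four-strand mixture: strands, initial molar concentrations, flags."""

    a_s: RnaStrand
    a_l: RnaStrand
    b_s: RnaStrand
    b_l: RnaStrand
    concentrations: dict[str, float]  # keys A_S, A_L, B_S, B_L, molar
    temperature: float = T_DEFAULT
    enable_zero_toehold: bool = True
    clamp_kdispl: bool = True

    def __post_init__(self) -> None:
        for k in ("A_S", "A_L", "B_S", "B_L"):
            if self.concentrations.get(k, -1.0) < 0:
                raise ValueError(f"missing or negative concentration for {k}")


@dataclass(frozen=True)
class Reaction:
    name: str
    kind: str  # "hybridization" | "dissociation" | "displacement"
    reactants: tuple[int, ...]  # species indices
    products: tuple[int, ...]
    rate: float
    source: str  # which predictor produced the rate
    partner: Optional[str] = None  # name of the reverse reaction, if any


@dataclass
class ReactionNetwork:
    species: tuple[str, ...]
    reactions: list[Reaction]
    spec: MixtureSpec
    notes: dict = field(default_factory=dict)

    def stoichiometry(self) -> np.ndarray:
        S = np.zeros((len(self.species), len(self.reactions)))
        for r, rxn in enumerate(self.reactions):
            for i in rxn.reactants:
                S[i, r] -= 1
            for i in rxn.products:
                S[i, r] += 1
        return S

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(len(self.species))
        for k, v in self.spec.concentrations.items():
            y0[self.species.index(k)] = v
        return y0

    def rates(self, y: np.ndarray) -> np.ndarray:
        v = np.empty(len(self.reactions))
        for r, rxn in enumerate(self.reactions):
            val = rxn.rate
            for i in rxn.reactants:
                val *= y[i]
            v[r] = val
        return v


@dataclass
class TimeCourse:
    """Integrated concentrations, reaction extents and the 2Ap observable."""

    t: np.ndarray
    conc: np.ndarray  # (n_species, n_t)
    extents: np.ndarray  # (n_reactions, n_t), time-integrated reaction fluxes
    network: ReactionNetwork

    def species_index(self, name: str) -> int:
        return self.network.species.index(name)

    def totals(self) -> dict[str, np.ndarray]:
        """Per-strand totals along the trajectory (conserved quantities)."""
        c = {s: self.conc[i] for i, s in enumerate(self.network.species)}
        return {
            "A_S": c["A_S"] + c["A_S:B_S"] + c["A_S:B_L"],
            "A_L": c["A_L"] + c["A_L:B_L"] + c["A_L:B_S"],
            "B_S": c["B_S"] + c["A_S:B_S"] + c["A_L:B_S"],
            "B_L": c["B_L"] + c["A_L:B_L"] + c["A_S:B_L"],
        }


@dataclass(frozen=True)
class EnvelopeSpec:
    """Parameter-resampling specification for uncertainty envelopes.

    ``ci`` maps a rate class ("k_on", "k_off", "k_displ") to multiplicative
    (low, high) confidence bounds; resampled factors are drawn log-uniformly
    within each interval.
    """

    ci: dict[str, tuple[float, float]]
    n_resamples: int = 100
    quantiles: tuple[float, ...] = (95.0, 90.0, 60.0, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if any(not 0 < q < 100 for q in self.quantiles):
            raise ValueError("quantiles must be in (0, 100)")


# --------------------------------------------------------------------------
# network construction
# --------------------------------------------------------------------------

_DUPLEXES = (
    ("A_S:B_S", "A_S", "B_S"),
    ("A_L:B_L", "A_L", "B_L"),
    ("A_L:B_S", "A_L", "B_S"),
    ("A_S:B_L", "A_S", "B_L"),
)


def _paired_register(a: RnaStrand, b: RnaStrand) -> tuple[int, float]:
    """(length, f_CG) of the paired register of duplex a:b (the shorter
    strand defines the register; its composition sets the CG fraction)."""
    short = a if len(a) <= len(b) else b
    return len(short), short.gc_fraction


def build_network(spec: MixtureSpec, params: KineticBundle = KineticBundle()) -> ReactionNetwork:
    """Assemble the mass-action network of the four-strand mixture.

    Four reversible hybridizations (k_on from the CG model over the paired
    register, k_off from the Eyring barrier); two toehold displacements
    (long strand invades the short-strand duplex through the exposed
    overhang), optionally clamped at the apparent bimolecular limit
    evaluated at the invader's initial concentration; and, behind
    ``spec.enable_zero_toehold`` (default on), the two reverse
    displacements with rates set by detailed balance against the duplex
    K_Ds so the stationary state is thermodynamically consistent. Four-way
    exchange between duplexes is never included.
    """
    strands = {"A_S": spec.a_s, "A_L": spec.a_l, "B_S": spec.b_s, "B_L": spec.b_l}
    idx = {s: i for i, s in enumerate(SPECIES)}
    T = spec.temperature
    rxns: list[Reaction] = []
    kon: dict[str, float] = {}
    koff: dict[str, float] = {}
    for duplex, xa, xb in _DUPLEXES:
        L, fcg = _paired_register(strands[xa], strands[xb])
        k_on = kon_cg_model(L, fcg, params.analytic, T, params.R) * params.kon_factor
        k_off = koff_eyring(L, fcg, params.eyring, T, params.R) * params.koff_factor
        kon[duplex], koff[duplex] = k_on, k_off
        rxns.append(
            Reaction(
                name=f"hyb:{duplex}",
                kind="hybridization",
                reactants=(idx[xa], idx[xb]),
                products=(idx[duplex],),
                rate=k_on,
                source="kon_cg_model",
                partner=f"diss:{duplex}",
            )
        )
        rxns.append(
            Reaction(
                name=f"diss:{duplex}",
                kind="dissociation",
                reactants=(idx[duplex],),
                products=(idx[xa], idx[xb]),
                rate=k_off,
                source="koff_eyring",
                partner=f"hyb:{duplex}",
            )
        )

    notes: dict = {"kon": kon, "koff": koff, "omitted_displacements": []}
    displacements = (
        # invader, template duplex, incumbent -> product duplex + released
        ("A_L", "A_S:B_L", "B_L", "A_S", "A_L:B_L"),
        ("B_L", "A_L:B_S", "A_L", "B_S", "A_L:B_L"),
    )
    for invader, dup, template, released, product in displacements:
        try:
            ctx = ToeholdContext.infer(
                strands[template], strands[released], strands[invader]
            )
            dg_toe = toehold_delta_g(ctx, T=T)
        except Exception as exc:  # no valid toehold geometry
            notes["omitted_displacements"].append((invader, dup, str(exc)))
            continue
        k_d = kdispl_model(dg_toe, params.displacement, T, params.R) * params.kdispl_factor
        if spec.clamp_kdispl:
            c_inv = spec.concentrations[invader]
            if c_inv > 0:
                limit = apparent_bimolecular_limit(
                    kon[product], params.displacement.k_s, c_inv
                )
                k_d = min(k_d, limit)
        fwd_name = f"displ:{invader}+{dup}"
        rxns.append(
            Reaction(
                name=fwd_name,
                kind="displacement",
                reactants=(idx[invader], idx[dup]),
                products=(idx[product], idx[released]),
                rate=k_d,
                source="kdispl_model(toehold)",
                partner=f"displ0:{released}+{product}" if spec.enable_zero_toehold else None,
            )
        )
        notes[f"dg_toehold:{fwd_name}"] = dg_toe
        if spec.enable_zero_toehold:
            # reverse (zero-toehold) displacement; detailed balance against
            # the network's duplex K_Ds: K_eq = K_D(dup) / K_D(product)
            keq = (koff[dup] / kon[dup]) / (koff[product] / kon[product])
            rxns.append(
                Reaction(
                    name=f"displ0:{released}+{product}",
                    kind="displacement",
                    reactants=(idx[released], idx[product]),
                    products=(idx[dup], idx[invader]),
                    rate=k_d / keq,
                    source="detailed_balance(zero_toehold)",
                    partner=fwd_name,
                )
            )
    return ReactionNetwork(species=SPECIES, reactions=rxns, spec=spec, notes=notes)


# --------------------------------------------------------------------------
# integration and observables
# --------------------------------------------------------------------------


def integrate(
    net: ReactionNetwork,
    t_end: float,
    grid: Optional[Sequence[float]] = None,
    rtol: float = 1e-10,
    atol: float = 1e-18,
    y0: Optional[Sequence[float]] = None,
) -> TimeCourse:
    """Integrate the network ODEs to ``t_end`` with a stiff solver.

    The state is augmented with per-reaction extents (time-integrated
    fluxes) used for pathway decomposition. Per-strand totals are conserved
    to integrator tolerance. ``y0`` overrides the initial species state
    (e.g. a pre-annealed mixture); the default is the spec's all-single-
    stranded mix.
    """
    n_s, n_r = len(net.species), len(net.reactions)
    S = net.stoichiometry()
    start = net.initial_state() if y0 is None else np.asarray(y0, dtype=float)
    y0 = np.concatenate([start, np.zeros(n_r)])

    def rhs(t, y):
        v = net.rates(np.maximum(y[:n_s], 0.0))
        return np.concatenate([S @ v, v])

    t_eval = None if grid is None else np.asarray(grid, dtype=float)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return TimeCourse(
        t=sol.t, conc=sol.y[:n_s], extents=sol.y[n_s:], network=net
    )


def fluorescence_observable(tc: TimeCourse) -> np.ndarray:
    """Normalized 2Ap signal: ([B_L] + [A_S:B_L]) / [B_L total].

    The reporter sits in B_L where only A_L quenches it; in the A_S:B_L
    duplex it lies in the overhang, unpaired and unquenched.
    """
    bl = tc.conc[tc.species_index("B_L")]
    asbl = tc.conc[tc.species_index("A_S:B_L")]
    total = tc.totals()["B_L"]
    if np.all(total == 0):
        raise ValueError("mixture contains no B_L")
    return (bl + asbl) / total


def fast_phase_end(tc: TimeCourse, threshold: float = 0.01) -> float:
    """End of the initial rapid-hybridization phase.

    Defined as the first time the free single-strand pool of the limiting
    side (the smaller of free A_S+A_L and free B_S+B_L) falls below
    ``threshold`` (default 1%) of its initial value. Using the limiting
    side keeps the definition meaningful for unbalanced mixtures, where an
    excess strand stays single-stranded forever. If the threshold is never
    reached, the first grid time is returned.
    """
    a_side = tc.conc[0] + tc.conc[1]
    b_side = tc.conc[2] + tc.conc[3]
    free = np.minimum(a_side, b_side)
    init = free[0]
    if init == 0:
        return float(tc.t[0])
    below = np.nonzero(free < threshold * init)[0]
    return float(tc.t[below[0]]) if below.size else float(tc.t[0])


def pathway_contributions(tc: TimeCourse, t_from: Optional[float] = None) -> dict[str, float]:
    """Percentage of A_L:B_L production per pathway after the fast phase.

    Net time-integrated flux into A_L:B_L from the end of the rapid
    hybridization phase (or ``t_from``) to the end of the trajectory,
    attributed to direct hybridization versus each displacement channel and
    normalized to 100%.
    """
    if t_from is None:
        t_from = fast_phase_end(tc)
    net = tc.network
    i0 = int(np.searchsorted(tc.t, t_from))
    i0 = min(i0, len(tc.t) - 1)
    by_name = {r.name: k for k, r in enumerate(net.reactions)}
    windows = tc.extents[:, -1] - tc.extents[:, i0]

    def net_flux(fwd: str) -> float:
        r = net.reactions[by_name[fwd]]
        flux = windows[by_name[fwd]]
        if r.partner and r.partner in by_name:
            flux -= windows[by_name[r.partner]]
        return float(flux)

    contrib: dict[str, float] = {}
    if "hyb:A_L:B_L" in by_name:
        contrib["direct_hybridization"] = net_flux("hyb:A_L:B_L")
    for r in net.reactions:
        if r.kind == "displacement" and "A_L:B_L" in [net.species[i] for i in r.products]:
            contrib[r.name] = net_flux(r.name)
    total = sum(contrib.values())
    if total <= 0:
        warnings.warn("no net flux into A_L:B_L; contributions undefined", RuntimeWarning)
        return {k: float("nan") for k in contrib}
    return {k: 100.0 * v / total for k, v in contrib.items()}


def instantaneous_rates(
    net: ReactionNetwork, state: np.ndarray
) -> dict[str, float]:
    """Per-reaction mass-action rates at ``state``, in nM/min."""
    v = net.rates(np.asarray(state, dtype=float))
    return {r.name: float(vi * 1e9 * 60.0) for r, vi in zip(net.reactions, v)}


def equilibrium_state(net: ReactionNetwork) -> np.ndarray:
    """Mass-action equilibrium of the mixture by algebraic root-finding.

    Solves the four hybridization equilibria [AxBy] = [Ax][By]/K_D together
    with the four per-strand conservation laws (independent of the kinetic
    path, hence of the displacement channels, which are detailed-balanced).
    """
    kon = net.notes["kon"]
    koff = net.notes["koff"]
    y0 = net.initial_state()
    tot = {
        "A_S": y0[0] + y0[4] + y0[7],
        "A_L": y0[1] + y0[5] + y0[6],
        "B_S": y0[2] + y0[4] + y0[6],
        "B_L": y0[3] + y0[5] + y0[7],
    }
    scale = max(tot.values())

    def resid(x):
        a_s, a_l, b_s, b_l = np.exp(x)
        c = {
            "A_S:B_S": a_s * b_s * kon["A_S:B_S"] / koff["A_S:B_S"],
            "A_L:B_L": a_l * b_l * kon["A_L:B_L"] / koff["A_L:B_L"],
            "A_L:B_S": a_l * b_s * kon["A_L:B_S"] / koff["A_L:B_S"],
            "A_S:B_L": a_s * b_l * kon["A_S:B_L"] / koff["A_S:B_L"],
        }
        return [
            (a_s + c["A_S:B_S"] + c["A_S:B_L"] - tot["A_S"]) / scale,
            (a_l + c["A_L:B_L"] + c["A_L:B_S"] - tot["A_L"]) / scale,
            (b_s + c["A_S:B_S"] + c["A_L:B_S"] - tot["B_S"]) / scale,
            (b_l + c["A_L:B_L"] + c["A_S:B_L"] - tot["B_L"]) / scale,
        ]

    x0 = np.log(np.maximum([tot["A_S"], tot["A_L"], tot["B_S"], tot["B_L"]], 1e-30)) - 2.0
    sol = least_squares(resid, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not sol.success:
        raise RuntimeError("equilibrium root-finding failed")
    a_s, a_l, b_s, b_l = np.exp(sol.x)
    out = np.array(
        [
            a_s,
            a_l,
            b_s,
            b_l,
            a_s * b_s * kon["A_S:B_S"] / koff["A_S:B_S"],
            a_l * b_l * kon["A_L:B_L"] / koff["A_L:B_L"],
            a_l * b_s * kon["A_L:B_S"] / koff["A_L:B_S"],
            a_s * b_l * kon["A_S:B_L"] / koff["A_S:B_L"],
        ]
    )
    return out


def observable_half_time(tc: TimeCourse) -> float:
    """Time at which the 2Ap observable crosses the midpoint between its
    value at the end of the fast phase and its final value."""
    sig = fluorescence_observable(tc)
    t0 = fast_phase_end(tc)
    i0 = min(int(np.searchsorted(tc.t, t0)), len(tc.t) - 1)
    target = 0.5 * (sig[i0] + sig[-1])
    seg = sig[i0:]
    if sig[-1] <= sig[i0]:
        idx = np.nonzero(seg <= target)[0]
    else:
        idx = np.nonzero(seg >= target)[0]
    if idx.size == 0:
        raise ValueError("observable does not reach its half-way point")
    return float(tc.t[i0 + idx[0]])


def uncertainty_envelope(
    spec: MixtureSpec,
    env: EnvelopeSpec,
    t_end: float,
    grid: Sequence[float],
    params: KineticBundle = KineticBundle(),
) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Pointwise quantile bands of the observable under parameter resampling.

    Rate-class multipliers are drawn log-uniformly within their confidence
    intervals, the network is rebuilt and re-integrated, and for each
    configured level q the (50-q/2, 50+q/2) percentiles of the observable
    are returned. Failed resamples are dropped (error if more than 10%).
    """
    rng = np.random.default_rng(env.seed)
    grid = np.asarray(grid, dtype=float)
    sims = []
    failed = 0
    for _ in range(env.n_resamples):
        factors = {}
        for key in ("k_on", "k_off", "k_displ"):
            lo, hi = env.ci.get(key, (1.0, 1.0))
            factors[key] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        p = KineticBundle(
            analytic=params.analytic,
            eyring=params.eyring,
            displacement=params.displacement,
            T=params.T,
            R=params.R,
            kon_factor=factors["k_on"],
            koff_factor=factors["k_off"],
            kdispl_factor=factors["k_displ"],
        )
        try:
            tc = integrate(build_network(spec, p), t_end, grid)
            sims.append(fluorescence_observable(tc))
        except RuntimeError:
            failed += 1
    if failed > 0.1 * env.n_resamples:
        raise RuntimeError(f"{failed}/{env.n_resamples} resamples failed to integrate")
    arr = np.vstack(sims)
    bands: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for q in env.quantiles:
        lo = np.percentile(arr, 50.0 - q / 2.0, axis=0)
        hi = np.percentile(arr, 50.0 + q / 2.0, axis=0)
        bands[q] = (lo, hi)
    return bands
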