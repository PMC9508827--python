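"""Seeded synthetic data generation: sequences, traces, melting curves and
mixture fixtures.

Everything the package analyzes can be generated here, so all tests run
without external data. Generators emulate the study conditions: short
strands (5-12 nt) with CG content up to 0.8, designed against secondary
structure; stopped-flow association traces at micromolar concentrations;
fluorescence melting curves with linear instrument baselines; and the
standard 8/12-mer four-strand competition mixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import R_KCAL
from .mixtures import KineticBundle, MixtureSpec, ReactionNetwork, TimeCourse, build_network, integrate
from .strands import RnaStrand, complement_base
from .thermo import DuplexThermo
from .trace_fitting import KineticTrace, _bimolecular_fraction_unbound


@dataclass(frozen=True)
class FixtureConfig:
    lengths: tuple[int, ...] = (5, 6, 8, 10, 12)
    f_cg_targets: tuple[float, ...] = (0.0, 0.2, 0.5, 0.8)
    noise: float = 0.01
    seed: int = 0
    concentrations: tuple[float, ...] = (0.5e-6, 1e-6, 2e-6, 5e-6)

    def __post_init__(self) -> None:
        if any(not 5 <= L <= 12 for L in self.lengths):
            raise ValueError("fixture lengths must lie in [5, 12]")


# --------------------------------------------------------------------------
# sequence design
# --------------------------------------------------------------------------

_MAX_REJECTS = 10_000


def _revcomp(seq: str) -> str:
    return "".join(complement_base(b) for b in reversed(seq))


def _has_self_structure(seq: str, k: int = 4) -> bool:
    """True if any k-mer's reverse complement also occurs in the sequence
    (a proxy for hairpin/self-dimer potential at these lengths)."""
    if len(seq) < k:
        return False
    kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
    return any(_revcomp(m) in kmers for m in kmers)


def design_sequences(
    length: int,
    f_cg: float,
    seed: int,
    name: str = "S",
) -> tuple[RnaStrand, RnaStrand]:
    """Design a strand (and its complement) with a target CG fraction and
    no predicted self-structure.

    Candidates with round(f_cg*length) C/G bases are drawn uniformly and
    rejected if they contain a self-complementary stretch >= 4 nt or three
    consecutive guanines (G-quadruplex guard). Deterministic per seed.
    """
    if not 0.0 <= f_cg <= 0.8:
        raise ValueError("f_CG must be in [0, 0.8]; higher CG content is not supported")
    rng = np.random.default_rng(seed)
    n_cg = round(f_cg * length)
    for _ in range(_MAX_REJECTS):
        picks = list(rng.choice(list("CG"), n_cg)) + list(
            rng.choice(list("AU"), length - n_cg)
        )
        rng.shuffle(picks)
        seq = "".join(picks)
        if "GGG" in seq or "GGG" in _revcomp(seq):
            continue
        if _has_self_structure(seq):
            continue
        a = RnaStrand(name, seq)
        return a, a.reverse_complement(f"{name}_comp")
    raise RuntimeError(
        "sequence design rejection budget exhausted; relax length or f_CG"
    )


# --------------------------------------------------------------------------
# stopped-flow association traces
# --------------------------------------------------------------------------


def simulate_stopped_flow(
    k_on: float,
    k_off: float,
    concentrations: Sequence[float],
    a0: float = 0.5e-6,
    t_end: float = 5.0,
    n_points: int = 200,
    noise: float = 0.01,
    seed: int = 0,
) -> list[KineticTrace]:
    """Synthetic association traces (fraction unbound of A) at several
    concentrations of the partner strand B, with seeded Gaussian noise."""
    if k_on <= 0 or k_off < 0:
        raise ValueError("rates must be positive (k_off >= 0)")
    rng = np.random.default_rng(seed)
    t = np.linspace(1e-4, t_end, n_points)
    out = []
    for b0 in concentrations:
        f = _bimolecular_fraction_unbound(t, a0, b0, k_on, k_off)
        sig = f + rng.normal(0.0, noise, size=f.shape) if noise > 0 else f
        out.append(KineticTrace(t=t, signal=sig, a0=a0, b0=b0, meta={"true_k_on": k_on}))
    return out


# --------------------------------------------------------------------------
# melting curves
# --------------------------------------------------------------------------


def exact_unbound_fraction(
    thermo: DuplexThermo,
    T: np.ndarray,
    a_tot: float,
    delta: float = 0.0,
    R: float = R_KCAL,
) -> np.ndarray:
    """Exact f(T) for A + B <-> AB with [B] = [A] + delta.

    Solves the binding quadratic (f*a)^2 + f*a*(delta + K_D) - K_D*a = 0
    for the unbound concentration of A at each temperature.
    """
    T = np.asarray(T, dtype=float)
    kd = np.array([thermo.kd(Ti, R) for Ti in T])
    # a_free^2 + a_free*(delta + kd) - kd*a_tot = 0
    p = delta + kd
    a_free = 0.5 * (-p + np.sqrt(p * p + 4.0 * kd * a_tot))
    return a_free / a_tot


def simulate_melting_curve(
    thermo: DuplexThermo,
    a_tot: float,
    delta: float,
    T: Sequence[float],
    baseline_low: tuple[float, float] = (0.1, 1e-4),
    baseline_high: tuple[float, float] = (1.0, 2e-4),
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw melting signal with linear baselines and optional noise.

    Baselines are (intercept, slope) pairs: the bound-state signal is
    ``baseline_low`` and the unbound-state signal ``baseline_high``;
    the raw signal interpolates between them with the exact unbound
    fraction. Returns (T, signal, true_fraction).
    """
    if thermo.dH >= 0 or thermo.dS >= 0:
        raise ValueError("melting simulation expects dH < 0 and dS < 0 (binding sense)")
    T = np.asarray(T, dtype=float)
    f = exact_unbound_fraction(thermo, T, a_tot, delta)
    s_low = baseline_low[0] + baseline_low[1] * T
    s_high = baseline_high[0] + baseline_high[1] * T
    sig = s_low + f * (s_high - s_low)
    if noise > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise * float(np.ptp(sig)), size=sig.shape)
    return T, sig, f


# --------------------------------------------------------------------------
# mixtures
# --------------------------------------------------------------------------


def standard_mixture(
    seed: int = 11,
    concentrations: Optional[dict[str, float]] = None,
    f_cg: float = 0.5,
    long_length: int = 12,
    short_length: int = 8,
    **spec_kwargs,
) -> MixtureSpec:
    """The standard 8/12-mer four-strand competition fixture.

    B_L is a designed 12-mer; A_L its full complement; B_S the 5' 8-mer of
    B_L and A_S its complement, so that A_S:B_L and A_L:B_S each expose a
    4-nt toehold for invasion by the matching long strand. Default
    concentrations are 1 uM each (balanced mixture).
    """
    for _ in range(50):
        b_l, a_l = design_sequences(long_length, f_cg, seed, name="B_L")
        a_l = RnaStrand("A_L", a_l.bases)
        b_s = RnaStrand("B_S", b_l.bases[:short_length])
        a_s = b_s.reverse_complement("A_S")
        # registers must be unique for the toehold geometry to be inferable
        if b_l.bases.count(_revcomp(a_s.bases)) == 1 and a_l.bases.count(
            _revcomp(b_s.bases)
        ) == 1:
            break
        seed += 1000
    # place the 2Ap reporter on an adenine of B_L's overhang region, which
    # only A_L can pair (and hence quench)
    for i in range(short_length, long_length):
        if b_l.bases[i] == "A":
            b_l = RnaStrand(b_l.name, b_l.bases, two_ap_index=i)
            break
    conc = concentrations or {k: 1e-6 for k in ("A_S", "A_L", "B_S", "B_L")}
    return MixtureSpec(a_s=a_s, a_l=a_l, b_s=b_s, b_l=b_l, concentrations=conc, **spec_kwargs)


def simulate_mixture_experiment(
    spec: Optional[MixtureSpec] = None,
    t_end: float = 1e4,
    n_points: int = 300,
    noise: float = 0.0,
    seed: int = 0,
    params: KineticBundle = KineticBundle(),
) -> tuple[MixtureSpec, ReactionNetwork, TimeCourse, np.ndarray]:
    """End-to-end synthetic mixture experiment.

    Builds the network, integrates it on a log-spaced grid, and returns the
    observable with optional seeded Gaussian noise. With ``noise=0`` the
    observable equals the deterministic integration exactly.
    """
    from .mixtures import fluorescence_observable

    spec = spec or standard_mixture()
    grid = np.concatenate([[0.0], np.geomspace(1e-3, t_end, n_points - 1)])
    net = build_network(spec, params)
    tc = integrate(net, t_end, grid)
    obs = fluorescence_observable(tc)
    if noise > 0:
        rng = np.random.default_rng(seed)
        obs = obs + rng.normal(0.0, noise, size=obs.shape)
    return spec, net, tc, obs
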