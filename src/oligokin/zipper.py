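"""First-step Gillespie simulation of duplex nucleation and zippering.

The hybridization of two strands A and B is modeled as a continuous-time
Markov chain over inter-strand pairing states: sets of Watson-Crick base
pairs (i on A, j on B) that are mutually non-crossing in antiparallel
coordinates. Intramolecular structure is excluded (the sequences this
package targets are designed to have none). Single base pairs are added or
removed one at a time with Metropolis rates: a move with dG <= 0 proceeds
at k_uni, an unfavorable move at k_uni * exp(-dG/RT). Removing the last
base pair detaches the strands and is the one bimolecular-scale move: its
rate is k_bi * exp(dG_state/RT), the detailed-balance partner of attachment
at k_bi (1 M standard state).

The first-step method estimates k_on: a trajectory starts from one initial
contact (any single complementary pair, in-register or off-register) and is
run until it either reaches the minimum-free-energy duplex (success) or
detaches (failure); k_on = k_bi * sum of per-site success probabilities.

For short duplexes the full chain is small enough to solve exactly;
:func:`exact_success_probabilities` computes absorption probabilities by a
linear solve over the reachable state space, which serves as the
simulator's reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Hashable, Optional, Sequence

import numpy as np

from .constants import R_KCAL, T_DEFAULT
from .params import DEFAULT_LOOPS, DEFAULT_NN, LoopPenalties, NNParameterSet
from .strands import RnaStrand, is_full_duplex, is_wc_pair

Pair = tuple[int, int]
State = tuple[Pair, ...]  # pairs sorted by position on A

DETACHED: State = ()


@dataclass(frozen=True)
class StochasticParams:
    """Rate constants of the stochastic zipper (RNA defaults)."""

    k_bi: float = 3.5e6  # M^-1 s^-1
    k_uni: float = 4.25e5  # s^-1
    T: float = T_DEFAULT
    R: float = R_KCAL

    def __post_init__(self) -> None:
        if self.k_bi <= 0 or self.k_uni <= 0:
            raise ValueError("rate constants must be positive")


@dataclass
class Trajectory:
    """One first-step trajectory: visited states with absolute times."""

    states: list[tuple[State, float]]
    outcome: str  # "success" | "detached" | "censored"

    @property
    def duration(self) -> float:
        return self.states[-1][1]


@dataclass
class FirstStepEstimate:
    """Aggregated first-step k_on estimate."""

    sites: list[Pair]
    in_register: list[bool]
    p_success: np.ndarray  # mean success probability per site
    p_se: np.ndarray  # Monte-Carlo standard error per site
    k_on: float  # k_bi * sum(p_success), M^-1 s^-1
    k_on_replicates: list[float]
    samples_per_site: int
    replicates: int
    n_censored: int = 0


def validate_state(state: State, a: RnaStrand, b: RnaStrand) -> None:
    """Raise if a pairing state violates complementarity or planarity."""
    seen_i, seen_j = set(), set()
    for i, j in state:
        if not (0 <= i < len(a) and 0 <= j < len(b)):
            raise ValueError(f"pair {(i, j)} out of range")
        if not is_wc_pair(a.bases[i], b.bases[j]):
            raise ValueError(f"pair {(i, j)} is not Watson-Crick")
        if i in seen_i or j in seen_j:
            raise ValueError("a base cannot participate in two pairs")
        seen_i.add(i)
        seen_j.add(j)
    for (i1, j1), (i2, j2) in zip(state, state[1:]):
        if not (i1 < i2 and j1 > j2):
            raise ValueError("pairs must be non-crossing (antiparallel order)")


def _au_close(a: RnaStrand, first: Pair, last: Pair, au_dg: float) -> float:
    """Terminal-AU penalty of a closed helix (counted once for 1-bp helices)."""
    pen = 0.0
    if a.bases[first[0]] in "AU":
        pen += au_dg
    if last != first and a.bases[last[0]] in "AU":
        pen += au_dg
    return pen


def state_free_energy(
    state: State,
    a: RnaStrand,
    b: RnaStrand,
    nn: NNParameterSet = DEFAULT_NN,
    loops: LoopPenalties = DEFAULT_LOOPS,
    T: float = T_DEFAULT,
) -> float:
    """Free energy of a pairing state relative to the unbound strands,
    kcal/mol.

    NN stacks over contiguous helices + tabulated bulge/internal-loop
    penalties between helices + one bimolecular initiation term + terminal
    A-U penalties per helix end. The full in-register state of a
    complementary pair equals ``thermo.duplex_delta_g(...).dg(T)`` exactly.
    """
    if state == DETACHED:
        return 0.0
    g = nn.init_dg(T)
    au = nn.terminal_au_dg(T)
    helix_first = state[0]
    prev = state[0]
    for cur in state[1:]:
        di = cur[0] - prev[0]
        dj = prev[1] - cur[1]
        if di == 1 and dj == 1:  # stacked: same helix
            g += nn.stack_dg(a.bases[prev[0]] + a.bases[cur[0]], T)
        else:
            g += _au_close(a, helix_first, prev, au)
            na, nb = di - 1, dj - 1
            if na == 0 or nb == 0:
                g += loops.bulge_dg(max(na, nb))
            else:
                g += loops.internal_dg(na + nb)
            helix_first = cur
        prev = cur
    g += _au_close(a, helix_first, prev, au)
    return g


def enumerate_initial_contacts(
    a: RnaStrand, b: RnaStrand
) -> tuple[list[Pair], list[bool]]:
    """All single-pair initial contacts (i, j) and their in-register flags.

    A contact is in-register when it belongs to the minimum-free-energy
    duplex (for fully complementary strands: j = len(b) - 1 - i).
    """
    contacts = [
        (i, j)
        for i in range(len(a))
        for j in range(len(b))
        if is_wc_pair(a.bases[i], b.bases[j])
    ]
    target = set(mfe_state(a, b)) if contacts else set()
    flags = [c in target for c in contacts]
    return contacts, flags


def mfe_state(a: RnaStrand, b: RnaStrand) -> State:
    """The absorbing minimum-free-energy pairing state.

    For fully complementary strands this is the in-register full duplex.
    Arbitrary pairs up to length 12 are handled by exact minimization over
    the non-crossing state space (dynamic program); longer non-complementary
    pairs are unsupported.
    """
    if is_full_duplex(a, b):
        L = len(a)
        return tuple((i, L - 1 - i) for i in range(L))
    if min(len(a), len(b)) > 12:
        raise NotImplementedError(
            "MFE search for non-complementary pairs is supported up to 12 nt"
        )
    state, _ = _mfe_dp(a, b)
    return state


def _mfe_dp(
    a: RnaStrand,
    b: RnaStrand,
    nn: NNParameterSet = DEFAULT_NN,
    loops: LoopPenalties = DEFAULT_LOOPS,
    T: float = T_DEFAULT,
) -> tuple[State, float]:
    """Exact MFE over non-crossing pairing states, O(P^2) in pair count.

    DP key is (last pair, first pair of the current helix); the value holds
    every energy term except the terminal-AU closure of the current helix.
    """
    pairs = [
        (i, j)
        for i in range(len(a))
        for j in range(len(b))
        if is_wc_pair(a.bases[i], b.bases[j])
    ]
    if not pairs:
        raise ValueError("strands share no complementary base pair")
    au = nn.terminal_au_dg(T)
    # best[(p, f)] = (energy, parent_key) for a state ending at pair p whose
    # current helix started at pair f; energy excludes the closure of that
    # helix. Transitions only increase p[0], so buckets by p[0] give a
    # topological order.
    best: dict[tuple[Pair, Pair], tuple[float, Optional[tuple[Pair, Pair]]]] = {
        (p, p): (nn.init_dg(T), None) for p in pairs
    }
    for i_last in range(len(a)):
        keys = [k for k in best if k[0][0] == i_last]
        for key in keys:
            p, f = key
            g = best[key][0]
            for q in pairs:
                if not (q[0] > p[0] and q[1] < p[1]):
                    continue
                di, dj = q[0] - p[0], p[1] - q[1]
                if di == 1 and dj == 1:
                    cand = g + nn.stack_dg(a.bases[p[0]] + a.bases[q[0]], T)
                    newkey = (q, f)
                else:
                    na, nb = di - 1, dj - 1
                    pen = (
                        loops.bulge_dg(max(na, nb))
                        if (na == 0 or nb == 0)
                        else loops.internal_dg(na + nb)
                    )
                    cand = g + _au_close(a, f, p, au) + pen
                    newkey = (q, q)
                if newkey not in best or cand < best[newkey][0]:
                    best[newkey] = (cand, key)
    final_key, final_g = None, math.inf
    for (p, f), (g, _) in best.items():
        tot = g + _au_close(a, f, p, au)
        if tot < final_g:
            final_g, final_key = tot, (p, f)
    chain: list[Pair] = []
    key = final_key
    while key is not None:
        chain.append(key[0])
        key = best[key][1]
    return tuple(sorted(chain)), final_g


# --------------------------------------------------------------------------
# transition rates
# --------------------------------------------------------------------------


def _addable_pairs(state: State, a: RnaStrand, b: RnaStrand) -> list[Pair]:
    used_i = {i for i, _ in state}
    used_j = {j for _, j in state}
    out = []
    for i in range(len(a)):
        if i in used_i:
            continue
        for j in range(len(b)):
            if j in used_j or not is_wc_pair(a.bases[i], b.bases[j]):
                continue
            if all((i < i2) == (j > j2) for i2, j2 in state):
                out.append((i, j))
    return out


def transition_rates(
    state: State,
    a: RnaStrand,
    b: RnaStrand,
    params: StochasticParams = StochasticParams(),
    nn: NNParameterSet = DEFAULT_NN,
    loops: LoopPenalties = DEFAULT_LOOPS,
) -> list[tuple[State, float]]:
    """All single-base-pair moves from ``state`` with their rates, s^-1.

    Metropolis rule with dG = G_new - G_old: favorable or isoenergetic
    moves (dG <= 0) proceed at k_uni, unfavorable ones at
    k_uni*exp(-dG/RT). Removing the last pair (detachment) instead uses
    k_bi*exp(-dG/RT) = k_bi*K_D, the detailed-balance partner of
    attachment at k_bi. Detailed balance holds pairwise for every move.
    """
    if state == DETACHED:
        raise ValueError("transition rates are defined for attached states only")
    rt_ = params.R * params.T
    g_old = state_free_energy(state, a, b, nn, loops, params.T)
    moves: list[tuple[State, float]] = []
    for pair in _addable_pairs(state, a, b):
        new = tuple(sorted(state + (pair,)))
        dg = state_free_energy(new, a, b, nn, loops, params.T) - g_old
        rate = params.k_uni if dg <= 0 else params.k_uni * math.exp(-dg / rt_)
        moves.append((new, rate))
    for pair in state:
        new = tuple(p for p in state if p != pair)
        dg = state_free_energy(new, a, b, nn, loops, params.T) - g_old
        if new == DETACHED:
            rate = params.k_bi * math.exp(-dg / rt_)
        else:
            rate = params.k_uni if dg <= 0 else params.k_uni * math.exp(-dg / rt_)
        moves.append((new, rate))
    return moves


# --------------------------------------------------------------------------
# generic Gillespie absorption engine
# --------------------------------------------------------------------------


def gillespie_absorb(
    rates_of: Callable[[Hashable], list[tuple[Hashable, float]]],
    start: Hashable,
    is_success: Callable[[Hashable], bool],
    is_fail: Callable[[Hashable], bool],
    rng: np.random.Generator,
    step_cap: int = 1_000_000,
) -> tuple[list[tuple[Hashable, float]], str]:
    """Exact stochastic simulation until absorption.

    Exponential waiting times, rate-proportional move choice. Returns the
    visited (state, absolute time) list and the outcome string.
    """
    t = 0.0
    state = start
    path = [(state, t)]
    for _ in range(step_cap):
        if is_success(state):
            return path, "success"
        if is_fail(state):
            return path, "detached"
        moves = rates_of(state)
        rates = np.array([r for _, r in moves])
        total = rates.sum()
        t += rng.exponential(1.0 / total)
        state = moves[rng.choice(len(moves), p=rates / total)][0]
        path.append((state, t))
    return path, "censored"


class ZipperSimulator:
    """Caches energies and transition tables for one strand pair."""

    def __init__(
        self,
        a: RnaStrand,
        b: RnaStrand,
        params: StochasticParams = StochasticParams(),
        nn: NNParameterSet = DEFAULT_NN,
        loops: LoopPenalties = DEFAULT_LOOPS,
    ) -> None:
        self.a, self.b = a, b
        self.params = params
        self.nn, self.loops = nn, loops
        self.mfe = mfe_state(a, b)
        self._moves: dict[State, tuple[list[State], np.ndarray, float]] = {}
        self._energy: dict[State, float] = {}

    def energy(self, state: State) -> float:
        if state not in self._energy:
            self._energy[state] = state_free_energy(
                state, self.a, self.b, self.nn, self.loops, self.params.T
            )
        return self._energy[state]

    def moves(self, state: State) -> tuple[list[State], np.ndarray, float]:
        cached = self._moves.get(state)
        if cached is None:
            mv = transition_rates(state, self.a, self.b, self.params, self.nn, self.loops)
            succ = [s for s, _ in mv]
            rates = np.array([r for _, r in mv])
            total = rates.sum()
            cached = (succ, np.cumsum(rates) / total, total)
            self._moves[state] = cached
        return cached

    def run(self, site: Pair, rng: np.random.Generator, step_cap: int = 1_000_000) -> Trajectory:
        state: State = (site,)
        t = 0.0
        path = [(state, t)]
        for _ in range(step_cap):
            if state == self.mfe:
                return Trajectory(path, "success")
            if state == DETACHED:
                return Trajectory(path, "detached")
            succ, cum, total = self.moves(state)
            t += rng.exponential(1.0 / total)
            state = succ[int(np.searchsorted(cum, rng.random() * cum[-1]))]
            path.append((state, t))
        return Trajectory(path, "censored")


def simulate_first_step(
    a: RnaStrand,
    b: RnaStrand,
    site: Pair,
    params: StochasticParams = StochasticParams(),
    rng: Optional[np.random.Generator] = None,
    step_cap: int = 1_000_000,
    simulator: Optional[ZipperSimulator] = None,
) -> Trajectory:
    """One first-step trajectory from a single initial contact.

    The trajectory starts at the single-pair state ``site`` and evolves by
    the Gillespie algorithm until the minimum-free-energy duplex is reached
    (success) or the strands detach (failure). ``rng`` must be provided and
    seeded for reproducibility.
    """
    if rng is None:
        raise ValueError("a seeded numpy Generator is required")
    sim = simulator or ZipperSimulator(a, b, params)
    contacts, _ = enumerate_initial_contacts(a, b)
    if site not in contacts:
        raise ValueError(f"{site} is not a valid initial contact")
    return sim.run(site, rng, step_cap)


def estimate_kon(
    a: RnaStrand,
    b: RnaStrand,
    samples_per_site: int = 10,
    replicates: int = 3,
    params: StochasticParams = StochasticParams(),
    seed: int = 0,
    step_cap: int = 1_000_000,
) -> FirstStepEstimate:
    """First-step k_on estimate: k_bi times the summed per-site success
    probabilities, sampled ``samples_per_site`` times per initial contact
    and averaged over ``replicates`` independent replicates.
    """
    if samples_per_site < 1:
        raise ValueError("samples_per_site must be >= 1")
    rng = np.random.default_rng(seed)
    sim = ZipperSimulator(a, b, params)
    contacts, flags = enumerate_initial_contacts(a, b)
    n_sites = len(contacts)
    succ = np.zeros((replicates, n_sites))
    tried = np.zeros((replicates, n_sites))
    n_censored = 0
    for r in range(replicates):
        for s, site in enumerate(contacts):
            for _ in range(samples_per_site):
                traj = sim.run(site, rng, step_cap)
                if traj.outcome == "censored":
                    n_censored += 1
                    continue
                tried[r, s] += 1
                succ[r, s] += traj.outcome == "success"
    if n_censored:
        warnings.warn(
            f"{n_censored} trajectories hit the step cap and were excluded",
            RuntimeWarning,
        )
    with np.errstate(invalid="ignore"):
        p_rep = np.where(tried > 0, succ / np.maximum(tried, 1), 0.0)
    p_hat = p_rep.mean(axis=0)
    n_tot = tried.sum(axis=0)
    p_pool = succ.sum(axis=0) / np.maximum(n_tot, 1)
    se = np.sqrt(p_pool * (1 - p_pool) / np.maximum(n_tot, 1))
    k_on_reps = [params.k_bi * p_rep[r].sum() for r in range(replicates)]
    return FirstStepEstimate(
        sites=contacts,
        in_register=flags,
        p_success=p_hat,
        p_se=se,
        k_on=params.k_bi * float(p_hat.sum()),
        k_on_replicates=k_on_reps,
        samples_per_site=samples_per_site,
        replicates=replicates,
        n_censored=n_censored,
    )


def annealing_pathway(
    traj: Trajectory,
    a: RnaStrand,
    b: RnaStrand,
    nn: NNParameterSet = DEFAULT_NN,
    loops: LoopPenalties = DEFAULT_LOOPS,
    T: float = T_DEFAULT,
) -> list[tuple[State, float, float]]:
    """Unique states of a trajectory as (state, dG, minimal formation time).

    The minimal formation time of a state is the first time it is reached;
    the series is ordered by that time (strictly increasing).
    """
    if not traj.states:
        raise ValueError("empty trajectory")
    first_seen: dict[State, float] = {}
    for state, t in traj.states:
        if state not in first_seen:
            first_seen[state] = t
    return [
        (s, state_free_energy(s, a, b, nn, loops, T), t)
        for s, t in sorted(first_seen.items(), key=lambda kv: kv[1])
    ]


def off_register_share(est: FirstStepEstimate) -> float:
    """Fraction of the first-step k_on carried by off-register contacts."""
    total = float(est.p_success.sum())
    if total == 0:
        return 0.0
    off = sum(
        p for p, flag in zip(est.p_success, est.in_register) if not flag
    )
    return float(off) / total


# --------------------------------------------------------------------------
# exact absorption probabilities (reference for the Monte-Carlo estimate)
# --------------------------------------------------------------------------


def exact_success_probabilities(
    a: RnaStrand,
    b: RnaStrand,
    params: StochasticParams = StochasticParams(),
    nn: NNParameterSet = DEFAULT_NN,
    loops: LoopPenalties = DEFAULT_LOOPS,
) -> dict[Pair, float]:
    """Absorption probabilities of reaching the MFE duplex before
    detaching, for every initial contact, by a linear solve over the full
    reachable state space. Feasible for short duplexes; this is the exact
    reference the Monte-Carlo first-step estimate is checked against.
    """
    sim = ZipperSimulator(a, b, params, nn, loops)
    contacts, _ = enumerate_initial_contacts(a, b)
    # BFS over reachable transient states
    transient: list[State] = []
    index: dict[State, int] = {}
    stack: list[State] = [(c,) for c in contacts]
    seen = set(stack)
    while stack:
        s = stack.pop()
        if s == DETACHED or s == sim.mfe:
            continue
        index[s] = len(transient)
        transient.append(s)
        for nxt in sim.moves(s)[0]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    n = len(transient)
    A = np.eye(n)
    rhs = np.zeros(n)
    for s in transient:
        i = index[s]
        succ, cum, _ = sim.moves(s)
        probs = np.diff(cum, prepend=0.0)
        for nxt, p in zip(succ, probs):
            if nxt == sim.mfe:
                rhs[i] += p
            elif nxt == DETACHED:
                continue
            else:
                A[i, index[nxt]] -= p
    sol = np.linalg.solve(A, rhs)
    out: dict[Pair, float] = {}
    for c in contacts:
        s = (c,)
        out[c] = 1.0 if s == sim.mfe else float(sol[index[s]])
    return out


def exact_kon(
    a: RnaStrand,
    b: RnaStrand,
    params: StochasticParams = StochasticParams(),
) -> float:
    """k_bi * sum of exact per-site success probabilities, M^-1 s^-1."""
    probs = exact_success_probabilities(a, b, params)
    return params.k_bi * sum(probs.values())


# --------------------------------------------------------------------------
# nucleation ladder (the analytic model's own Markov chain)
# --------------------------------------------------------------------------


def simulate_nucleation_ladder(
    contact_kds: Sequence[float],
    params: StochasticParams = StochasticParams(),
    samples_per_site: int = 100,
    seed: int = 0,
) -> float:
    """Monte-Carlo k_on over the analytic nucleation ladder, M^-1 s^-1.

    Each initial contact i competes between extension (rate 2*k_uni; the
    contact can zipper in either direction) and detachment (rate
    k_bi*K_D^i); reaching two base pairs commits the trajectory to full
    zippering (nucleation-limited assumption). This is exactly the chain
    under which the analytic per-contact success probability
    2*k_uni/(2*k_uni + k_bi*K_D^i) holds, so the estimate converges to the
    closed-form k_on; it exercises the same Gillespie engine as the full
    zipper simulation.
    """
    rng = np.random.default_rng(seed)
    total_p = 0.0
    for kd in contact_kds:
        detach = params.k_bi * kd

        def rates_of(state):
            return [(2, 2.0 * params.k_uni), (0, detach)]

        wins = 0
        for _ in range(samples_per_site):
            _, outcome = gillespie_absorb(
                rates_of, 1, lambda s: s == 2, lambda s: s == 0, rng
            )
            wins += outcome == "success"
        total_p += wins / samples_per_site
    return params.k_bi * total_p
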