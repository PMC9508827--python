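import math

import numpy as np
import pytest

from oligokin.constants import R_KCAL, T_DEFAULT
from oligokin.params import DEFAULT_LOOPS, DEFAULT_NN
from oligokin.rate_models import AnalyticKineticParams, kon_full_sum
from oligokin.strands import RnaStrand
from oligokin.synth import design_sequences
from oligokin.thermo import dissociation_constant, duplex_delta_g
from oligokin.zipper import (
    DETACHED,
    StochasticParams,
    ZipperSimulator,
    annealing_pathway,
    enumerate_initial_contacts,
    estimate_kon,
    exact_success_probabilities,
    gillespie_absorb,
    mfe_state,
    off_register_share,
    simulate_first_step,
    simulate_nucleation_ladder,
    state_free_energy,
    transition_rates,
    validate_state,
)

RT = R_KCAL * T_DEFAULT


class TestContacts:
    def test_homopolymer_counts(self):
        a, b = RnaStrand("a", "AAAA"), RnaStrand("b", "UUUU")
        contacts, flags = enumerate_initial_contacts(a, b)
        assert len(contacts) == 16
        assert sum(flags) == 4

    def test_non_interacting_pair_empty(self):
        contacts, _ = enumerate_initial_contacts(
            RnaStrand("a", "AAAA"), RnaStrand("b", "AAAA")
        )
        assert contacts == []

    def test_count_matches_exhaustive_scan(self):
        a, b = design_sequences(8, 0.5, seed=2)
        contacts, _ = enumerate_initial_contacts(a, b)
        comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
        brute = sum(
            1
            for i in range(8)
            for j in range(8)
            if comp[a.bases[i]] == b.bases[j]
        )
        assert len(contacts) == brute


class TestStateEnergy:
    def test_single_pair_is_initiation_only(self):
        a, b = RnaStrand("a", "CCCC"), RnaStrand("b", "GGGG")
        g = state_free_energy(((1, 2),), a, b)
        assert g == pytest.approx(DEFAULT_NN.init_dg(T_DEFAULT))

    def test_mfe_equals_two_state_duplex(self):
        a, b = design_sequences(8, 0.4, seed=9)
        g = state_free_energy(mfe_state(a, b), a, b)
        assert g == pytest.approx(duplex_delta_g(a, b).dg(T_DEFAULT), abs=1e-12)

    def test_two_helix_state_with_bulge_matches_hand_sum(self):
        # A = GC-A-GC against B = GCGC: the middle A of strand A is bulged
        # out, leaving two 2-bp helices separated by a 1-nt bulge
        a = RnaStrand("a", "GCAGC")
        b = RnaStrand("b", "GCGC")
        pairs = ((0, 3), (1, 2), (3, 1), (4, 0))
        validate_state(pairs, a, b)
        T = T_DEFAULT
        expected = (
            DEFAULT_NN.init_dg(T)
            + 2 * DEFAULT_NN.stack_dg("GC", T)
            + DEFAULT_LOOPS.bulge_dg(1)
        )  # no AU helix ends anywhere
        assert state_free_energy(pairs, a, b) == pytest.approx(expected, abs=1e-12)

    def test_internal_loop_state_matches_hand_sum(self):
        # full in-register frame with one pair removed from the middle:
        # both strands keep an unpaired base -> 2-nt internal loop
        a = RnaStrand("a", "ACGCUACG")
        b = a.reverse_complement()
        L = len(a)
        pairs = tuple((i, L - 1 - i) for i in range(L) if i != 2)
        validate_state(pairs, a, b)
        T = T_DEFAULT
        expected = DEFAULT_NN.init_dg(T)
        expected += DEFAULT_NN.stack_dg("AC", T)  # helix 1: pairs 0-1
        for top in ("CU", "UA", "AC", "CG"):  # helix 2: pairs 3..7
            expected += DEFAULT_NN.stack_dg(top, T)
        expected += DEFAULT_LOOPS.internal_dg(2)
        # AU helix-end penalties: helix-1 ends at a[0]=A and a[1]=C;
        # helix-2 ends at a[3]=C and a[7]=G -> only one penalty
        expected += DEFAULT_NN.terminal_au_dg(T)
        assert state_free_energy(pairs, a, b) == pytest.approx(expected, abs=1e-12)

    def test_invalid_geometry_rejected(self):
        a, b = RnaStrand("a", "AAAA"), RnaStrand("b", "UUUU")
        with pytest.raises(ValueError):
            validate_state(((0, 0), (1, 1)), a, b)  # crossing in antiparallel
        with pytest.raises(ValueError):
            validate_state(((0, 0),), RnaStrand("a", "AAAA"), RnaStrand("b", "AAAA"))


class TestTransitionRates:
    def test_favorable_addition_runs_at_kuni(self):
        a, b = RnaStrand("a", "GGCC"), RnaStrand("b", "GGCC")
        p = StochasticParams()
        state = ((0, 3), (1, 2))
        for new, rate in transition_rates(state, a, b, p):
            if len(new) == 3:
                dg = state_free_energy(new, a, b) - state_free_energy(state, a, b)
                if dg <= 0:
                    assert rate == p.k_uni

    def test_detailed_balance_over_random_states(self, rng):
        a, b = design_sequences(6, 0.5, seed=4)
        p = StochasticParams()
        sim = ZipperSimulator(a, b, p)
        contacts, _ = enumerate_initial_contacts(a, b)
        checked = 0
        for _ in range(200):
            # random reachable state: random walk a few moves from a contact
            state = (contacts[rng.integers(len(contacts))],)
            for _ in range(rng.integers(1, 5)):
                moves = transition_rates(state, a, b, p)
                nxt = moves[rng.integers(len(moves))][0]
                if nxt == DETACHED:
                    break
                state = nxt
            if state == DETACHED:
                continue
            for nxt, fwd in transition_rates(state, a, b, p):
                if nxt == DETACHED:
                    continue
                back = dict(transition_rates(nxt, a, b, p))[state]
                ddg = sim.energy(nxt) - sim.energy(state)
                assert fwd / back == pytest.approx(math.exp(-ddg / RT), rel=1e-9)
                checked += 1
        assert checked > 100

    def test_detachment_is_detailed_balance_partner_of_kbi(self):
        a, b = RnaStrand("a", "ACGU"), RnaStrand("b", "ACGU")
        p = StochasticParams()
        state = ((0, 3),)
        rates = dict(transition_rates(state, a, b, p))
        g1 = state_free_energy(state, a, b)
        assert rates[DETACHED] == pytest.approx(p.k_bi * math.exp(g1 / RT), rel=1e-12)


class TestGillespieEngine:
    def test_two_state_competition_matches_bernoulli(self):
        r_f, r_d = 3.0, 7.0
        rng = np.random.default_rng(77)
        n = 10_000
        wins = 0
        for _ in range(n):
            _, outcome = gillespie_absorb(
                lambda s: [(2, r_f), (0, r_d)], 1, lambda s: s == 2, lambda s: s == 0, rng
            )
            wins += outcome == "success"
        p = r_f / (r_f + r_d)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(wins / n - p) < 3 * se

    def test_birth_death_chain_matches_gamblers_ruin(self):
        f_rate, b_rate, L = 2.0, 3.0, 5
        rng = np.random.default_rng(5)

        def rates_of(s):
            return [(s + 1, f_rate), (s - 1, b_rate)]

        n = 10_000
        wins = sum(
            gillespie_absorb(rates_of, 1, lambda s: s == L, lambda s: s == 0, rng)[1]
            == "success"
            for _ in range(n)
        )
        q = b_rate / f_rate
        p = (1 - q) / (1 - q**L)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(wins / n - p) < 3 * se


class TestFirstStep:
    def test_trajectory_contract(self):
        a, b = design_sequences(6, 0.5, seed=4)
        rng = np.random.default_rng(3)
        contacts, _ = enumerate_initial_contacts(a, b)
        traj = simulate_first_step(a, b, contacts[0], rng=rng)
        assert len(traj.states[0][0]) == 1
        times = [t for _, t in traj.states]
        assert all(t2 > t1 for t1, t2 in zip(times, times[1:]))
        assert traj.outcome in ("success", "detached")
        final = traj.states[-1][0]
        assert final == DETACHED or final == mfe_state(a, b)

    def test_invalid_site_rejected(self):
        a, b = RnaStrand("a", "AAAA"), RnaStrand("b", "UUUU")
        with pytest.raises(ValueError):
            simulate_first_step(a, b, (0, 9), rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            simulate_first_step(a, b, (0, 0), rng=None)

    def test_monte_carlo_matches_linear_solve(self):
        """Primary oracle: MC success probabilities vs exact absorption
        probabilities of the full Markov chain, within 3 SE."""
        a, b = design_sequences(6, 0.5, seed=5)
        exact = exact_success_probabilities(a, b)
        est = estimate_kon(a, b, samples_per_site=3000, replicates=1, seed=21)
        n = 3000
        for site, p_hat in zip(est.sites, est.p_success):
            p = exact[site]
            se = math.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(p_hat - p) < max(3 * se, 1e-4), (site, p_hat, p)

    def test_same_seed_is_bit_identical(self):
        a, b = design_sequences(5, 0.4, seed=8)
        e1 = estimate_kon(a, b, samples_per_site=50, replicates=2, seed=99)
        e2 = estimate_kon(a, b, samples_per_site=50, replicates=2, seed=99)
        assert e1.k_on == e2.k_on
        assert np.array_equal(e1.p_success, e2.p_success)

    def test_kon_bounded_by_collision_rate(self):
        a, b = design_sequences(5, 0.4, seed=8)
        p = StochasticParams()
        est = estimate_kon(a, b, samples_per_site=20, replicates=1, seed=1)
        assert 0 <= est.k_on <= p.k_bi * len(est.sites)


class TestNucleationLadder:
    def test_converges_to_analytic_kon(self):
        """The Gillespie engine run on the analytic nucleation ladder must
        reproduce the closed-form per-contact summation within 3 SE."""
        p = StochasticParams()
        kd = dissociation_constant(-1.0, p.T)
        contact_kds = [kd] * 8
        n = 4000
        est = simulate_nucleation_ladder(contact_kds, p, samples_per_site=n, seed=13)
        analytic = kon_full_sum(
            contact_kds, AnalyticKineticParams(k_bi=p.k_bi, k_uni=p.k_uni)
        )
        p_site = analytic / (8 * p.k_bi)
        se_kon = p.k_bi * math.sqrt(8 * p_site * (1 - p_site) / n)
        assert abs(est - analytic) < 3 * se_kon


class TestPathways:
    def test_pathway_keeps_first_passage_times(self):
        a, b = design_sequences(6, 0.5, seed=5)
        rng = np.random.default_rng(11)
        contacts, flags = enumerate_initial_contacts(a, b)
        site = contacts[[i for i, f in enumerate(flags) if f][0]]
        sim = ZipperSimulator(a, b)
        traj = None
        for _ in range(200_000):
            t = sim.run(site, rng)
            if t.outcome == "success":
                traj = t
                break
        assert traj is not None, "no successful trajectory sampled"
        path = annealing_pathway(traj, a, b)
        times = [t for _, _, t in path]
        assert all(t2 > t1 for t1, t2 in zip(times, times[1:]))
        assert len(path) <= len(traj.states)
        # every trajectory state appears with its first-passage time
        firsts = {}
        for s, t in traj.states:
            firsts.setdefault(s, t)
        assert {s: t for s, _, t in path} == firsts

    def test_smooth_in_register_pathway_for_strong_duplex(self):
        """An in-register nucleation pathway of a CG-rich duplex descends to
        the global minimum without realignment kinetic traps: any uphill
        excursion stays bounded by a single loop penalty."""
        a = RnaStrand("a", "GCGGCUGC")
        b = a.reverse_complement()
        rng = np.random.default_rng(6)
        sim = ZipperSimulator(a, b)
        site = (0, 7)
        checked = 0
        for _ in range(500_000):
            t = sim.run(site, rng)
            if t.outcome != "success":
                continue
            path = annealing_pathway(t, a, b)
            energies = [g for _, g, _ in path]
            assert energies[-1] == min(energies)  # terminal MFE is the floor
            assert energies[-1] < energies[0] - 10.0  # deep overall descent
            assert all(
                g2 - g1 < 4.0 for g1, g2 in zip(energies, energies[1:])
            )  # bumps bounded by loop penalties, no strand-realignment traps
            checked += 1
            if checked >= 5:
                break
        assert checked >= 5, "too few successful trajectories sampled"


class TestOffRegisterShare:
    def test_share_of_homopolymer_matches_linear_solve(self):
        a, b = RnaStrand("a", "AAAA"), RnaStrand("b", "UUUU")
        exact = exact_success_probabilities(a, b)
        contacts, flags = enumerate_initial_contacts(a, b)
        total = sum(exact.values())
        share_exact = (
            sum(exact[c] for c, f in zip(contacts, flags) if not f) / total
        )
        est = estimate_kon(a, b, samples_per_site=30_000, replicates=1, seed=17)
        share_mc = off_register_share(est)
        assert abs(share_mc - share_exact) < 0.05 + 3 * 0.01

    def test_low_cg_short_duplex_share_is_small(self):
        a, b = design_sequences(6, 0.2, seed=30)
        est = estimate_kon(a, b, samples_per_site=2000, replicates=1, seed=31)
        if est.p_success.sum() > 0:
            assert off_register_share(est) < 0.2

    def test_all_failures_give_zero_share(self):
        a, b = design_sequences(5, 0.0, seed=1)
        est = estimate_kon(a, b, samples_per_site=1, replicates=1, seed=1)
        if est.p_success.sum() == 0:
            assert off_register_share(est) == 0.0
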