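# Methods

`oligokin` predicts and simulates the binding kinetics of short RNA
oligonucleotides (5–12 nt, CG content up to 0.8) that are designed to have
no secondary structure, and the out-of-equilibrium evolution of mixtures of
such strands. This note records the models, the parameters and their
defaults, the numerical choices, and the limits of what the synthetic-data
tests demonstrate.

## Duplex thermodynamics

Duplex stability is computed with the two-state nearest-neighbor (NN)
model: the binding free energy of a fully complementary pair is the sum of
dinucleotide stack terms, one bimolecular initiation term, and a penalty
per terminal A·U pair, each with tabulated (ΔH, ΔS) so that
ΔG(T) = ΔH − T·ΔS. The packaged table is the Watson–Crick RNA set of
Xia et al. (1998), stored as versioned JSON and pluggable. Signs follow the
bound-minus-unbound convention: a stable duplex has ΔG < 0 and
K_D = e^{ΔG/(RT)} ≪ 1 M (1 M standard state). Toehold binding energies use
the opposite sign (ΔG_toehold ≥ 0, K_A = e^{ΔG_toehold/(RT)}).

Two points deserve emphasis:

* **Two-state only.** No partition-function ensemble, dangles, terminal
  mismatches or coaxial stacking. For duplexes designed without secondary
  structure the two-state NN sum is a good approximation of the full
  ensemble free energy, but it is systematically less favorable for
  partially paired states (see the zipper discussion below).
* **Gas constant.** R defaults to the rounded 1.99×10⁻³ kcal/mol/K used in
  the parameterization this package packages, so that derived K_D and rate
  values match the printed constants digit-for-digit; the CODATA value
  1.987×10⁻³ is available as `constants.R_PRECISE`. Default temperature is
  298.15 K.
* **2-aminopurine.** A strand may mark one adenine as the fluorescent
  analogue 2-aminopurine (2Ap). Its destabilization (~0.2 kcal/mol) is
  negligible at room temperature, so 2Ap is thermodynamically treated as A;
  the marker only drives observable modeling.

Melting analysis implements both experimental routes. For fluorescence
melts of a tracked strand A with partner excess Δ, the unbound fraction f
gives K_D(T) = ((f·A_tot)² + f·A_tot·Δ)/(A_tot·(1−f)); a Van't Hoff
regression of ln K_D on 1/T returns (ΔH, ΔS) with slope ΔH/R and intercept
−ΔS/R (binding sign convention). For UV melts of equimolar duplexes,
K_D(T_m) = c_tot/4, so regression of ln(c_tot/4) on 1/T_m returns the same
pair; equivalently T_m = ΔH/(ΔS + R·ln(c_tot/4)). Raw curves are
baseline-corrected with linear fits in user-chosen low/high-temperature
windows; descending (quench-type) signals normalize correctly without
special-casing because the bound-state baseline is fitted at low
temperature, and a window whose slope approaches the transition slope
triggers a warning rather than an error.

## Association: the nucleation–zipper rate model

Hybridization is treated as nucleation-limited: strands collide and form
one initial base pair at a bimolecular rate k_bi; the contact either
zippers (per-step rate k_uni, two available directions) or detaches (rate
k_bi·K_D^i with K_D^i the contact's dissociation constant). Summing over
the N possible in-register contacts (N = length of the shorter strand):

    k_on = Σ_i k_bi · 2·k_uni / (2·k_uni + k_bi·K_D^i)

With a single composition-averaged contact energy
ΔG(f_CG) = −2.27·f_CG/(0.24 + f_CG) kcal/mol this becomes the two-parameter
(length, CG fraction) predictor `kon_cg_model`; k_on is exactly linear in N
and increasing in f_CG. Defaults: k_bi = 1.6×10⁷ M⁻¹s⁻¹,
k_uni = 2.1×10⁵ s⁻¹ (the analytic parameterization). The per-contact
provider for the full summation defaults to the uniform composition value;
a sequence-specific provider can be substituted, but how contact energies
should incorporate unpaired-neighbor contributions is genuinely open, so it
is pluggable rather than fixed.

## Dissociation: Eyring barrier

k_off = κ·(k_B·T/h)·e^{−ΔG‡/RT} with a three-parameter barrier

    ΔG‡ = L·[f_CG·ΔG‡_CG + (1−f_CG)·ΔG‡_AU] + ΔG‡_init

Defaults (RNA): ΔG‡_CG = 3.06, ΔG‡_AU = 1.32 kcal/mol per pair,
ΔG‡_init = 3.18 kcal/mol, κ = 1. A DNA preset (2.24, 1.19, 5.12) is
included for comparison; RNA duplexes of equal composition dissociate
orders of magnitude more slowly. Across L ∈ [5,12] and f_CG ∈ [0,0.8] the
model spans more than eight decades of k_off.

The consistency route k_off = k_on·K_D (NN thermodynamics) and the Eyring
route agree within about three decades across that regime — the measured
spread on designed test sequences is a ratio between 0.4 and ~110, worst
for short, low-CG duplexes, because three composition parameters cannot
carry sequence-level detail. The tests assert this documented envelope, not
a tighter one.

## Toehold-mediated strand displacement

With the toehold pre-equilibrium fast relative to branch migration, the
displacement of an incumbent by an invader is second-order with

    k_displ = k_s · K_A,   K_A = e^{ΔG_toehold/(RT)}

Default k_s = 8.9 s⁻¹. ΔG_toehold is minus the NN stack sum over the
toehold base pairs including the junction stack against the incumbent
duplex, so an n-nt toehold contributes n stack terms and lengthening the
toehold by one pair adds exactly that stack's |ΔG|. Blunt-ended (zero
toehold) invasion proceeds through transiently frayed duplex termini with
apparent energy RT·ln(e^{ΔG5/RT} + e^{ΔG3/RT}); the default frayed-end
energies are the terminal stack magnitudes at each end (pluggable).

`kdispl_model` applies no saturation: at high invader concentration the
measured reaction is only apparently bimolecular, limited by k_s.
`apparent_bimolecular_limit` quantifies this by generating the
irreversible consecutive-reaction trace

    [A](t) = [AB]·{1 + (k_s·e^{−k₁t} − k₁·e^{−k_s t})/(k₁ − k_s)},  k₁ = k_on[C]₀

and least-squares fitting a pseudo-first-order (invader-in-excess
second-order) model over t ∈ [0, 5·τ] on a uniform 500-point grid, where τ
is the 1−1/e completion time of the trace (the package-wide definition of a
characteristic timescale; the degenerate k₁ = k_s limit is evaluated
analytically). With k_on = 10⁷ M⁻¹s⁻¹, k_s = 8.9 s⁻¹ and [C]₀ = 1 μM this
gives τ ≈ 0.23 s and an apparent limit ≈ 4.6×10⁶ M⁻¹s⁻¹. Decomposing
branch migration as an unbiased random walk (gambler's ruin) over an N-step
domain gives the elementary step rate k_mig = k_s·N²; N = 8 yields
≈ 570 s⁻¹.

Four-way strand exchange between two duplexes is never modeled; its rate is
bounded above by ~10² M⁻¹s⁻¹ for 4-nt overhangs
(`constants.FOUR_WAY_EXCHANGE_UPPER_BOUND`) and is negligible against the
other pathways for short strands.

## Stochastic zipper simulation

The full hybridization process is simulated as a continuous-time Markov
chain over pairing states: sets of inter-strand Watson–Crick pairs,
mutually non-crossing in antiparallel coordinates, with intramolecular
pairs excluded. State free energies are NN stacks over contiguous helices,
tabulated bulge/internal-loop penalties between helices (Turner-2004-style
initiation values with a Jacobson–Stockmayer log extrapolation,
temperature-independent), one initiation term, and terminal-A·U penalties
per helix end (counted once for a 1-bp helix, which keeps the full
in-register state identical to the two-state duplex energy). Moves add or
remove one pair with Metropolis rates: k_uni for ΔG ≤ 0 (ties included, for
continuity with the favorable branch), k_uni·e^{−ΔG/RT} otherwise.
Removing the last pair is the one bimolecular-scale move, at
k_bi·e^{ΔG_state/RT} — the detailed-balance partner of attachment at k_bi
and the one place the 1 M standard state enters. Detailed balance holds
pairwise for every move by construction and is property-tested.

k_on is estimated by the first-step method: trajectories start from each
single-pair contact (all complementary (i,j) are admitted, in- and
off-register; no minimum-helix rule is imposed) and run under the Gillespie
algorithm until the minimum-free-energy duplex is reached or the strands
detach; k_on = k_bi·Σ p̂_i. Defaults: k_bi = 3.5×10⁶ M⁻¹s⁻¹,
k_uni = 4.25×10⁵ s⁻¹ (the stochastic parameterization), 10 samples per
site, 3 replicates, mandatory seed (NumPy PCG64: same seed and call order
give the same stream on every platform). Trajectories are capped at 10⁶
moves; censored runs are excluded from p̂ with a warning. The MFE target is
the full in-register duplex for complementary pairs; for arbitrary pairs up
to 12 nt it is found exactly by a dynamic program over non-crossing states
keyed on (last pair, first pair of the current helix).

Two oracles anchor the simulator. For short duplexes the chain is small
enough to solve exactly: absorption probabilities from a linear solve over
the reachable state space must match Monte-Carlo estimates within 3
standard errors (the comparison uses the binomial SE of the exact
probability, since the empirical SE vanishes for rare sites). And the same
Gillespie engine run on the nucleation ladder — forward 2·k_uni from the
initial contact, detachment k_bi·K_D, success at two pairs — converges to
the closed-form summation above, tying the simulator to the analytic model
under exactly the assumptions that make the closed form exact.

**Known gap.** With bare two-state NN energies a single-pair state costs
about +4 kcal/mol (initiation), so detachment outpaces zippering and the
absolute first-step success probabilities (~10⁻⁴–10⁻³) imply k_on values
far below the 10⁶–10⁷ M⁻¹s⁻¹ regime the stochastic k_bi/k_uni constants
were fitted against, which presumed ensemble state energies where
neighboring unpaired bases stabilize early contacts. The simulator's
correctness is established by the exact-solve oracle; its absolute k_on
scale inherits the contact-energy model and should be interpreted
accordingly. Relative quantities (site profiles, off-register shares,
pathway shapes) are meaningful as computed.

## Mixture networks

The four-strand design mixes a long complementary pair (A_L, B_L) with
truncations of each (A_S = complement of B_L's first 8 nt, B_S = B_L's
first 8 nt in the standard 8/12-mer fixture), so each short duplex
(A_S:B_L, A_L:B_S) exposes a 4-nt toehold. The mass-action network holds 8
species and, by default, 12 reactions:

* 4 reversible hybridizations — k_on from the CG model over the paired
  register (length and composition of the shorter strand), k_off from the
  Eyring barrier;
* 2 toehold displacements (A_L invades A_S:B_L; B_L invades A_L:B_S) with
  k_displ from the toehold model, optionally clamped at the apparent
  bimolecular limit evaluated at the invader's initial concentration (the
  clamp is not refreshed along the trajectory — a second-order effect);
* 2 reverse (zero-toehold) displacements, enabled by default. Their rates
  are set by detailed balance against the network's own duplex dissociation
  constants (k_off/k_on), k_rev = k_fwd·K_D(product)/K_D(reactant duplex),
  rather than independently from the frayed-end model: a displacement cycle
  whose forward and reverse rates come from two different models would
  violate the cycle condition and shift the stationary state away from the
  hybridization equilibrium. With this choice the long-time state is
  exactly the algebraic mass-action equilibrium of the four duplex K_Ds,
  which an independent root-finding solver verifies to ≤10⁻⁴ relative.

Integration uses LSODA with rtol = 10⁻¹⁰ and atol = 10⁻¹⁸ (concentrations
are molar, typically 10⁻⁶); per-strand totals are conserved to ≲10⁻¹⁴
relative. The state vector is augmented with per-reaction extents
(time-integrated fluxes) so equilibration pathways can be decomposed
afterwards without re-integration.

Observable: the 2Ap reporter sits in B_L where only A_L quenches it, so
signal = ([B_L] + [A_S:B_L])/[B_L]_total ∈ [0, 1]. The "fast phase" of
initial duplex formation ends when the limiting side's free single-strand
pool (min of free A-type and free B-type totals) first falls below 1% of
its initial value — the limiting-side form keeps the definition meaningful
for unbalanced mixtures, where the excess strand never binds completely.
Pathway contributions are net time-integrated fluxes into A_L:B_L (forward
minus reverse per channel) from the fast-phase end to the trajectory end,
normalized to 100%; instantaneous rates are reported in nM/min at the
fast-phase-end state.

Equilibration phenomenology reproduced by the engine: a balanced 1 μM
mixture relaxes on the dissociation clock of the short-strand duplexes —
the observable's half-time is ln2/(2·k_off) to ln2/k_off of A_S:B_L
(both short duplexes dissociate at the same rate and each dissociation
event productively converts one metastable duplex, directly or through
displacement by the freed long strand), i.e. hours when k_off ~ 10⁻⁴ s⁻¹ —
while a tenfold excess of A_L strictly shortens it, since free invader
no longer waits for a dissociation event.

Uncertainty envelopes resample multiplicative factors for the three rate
classes (k_on, k_off, k_displ) log-uniformly within user-supplied
confidence intervals (rates are positive with multiplicative uncertainty),
rebuild the network — reverse displacement rates are re-derived so each
resample stays thermodynamically consistent — re-integrate, and report
pointwise percentile bands of the observable at the configured levels
(default 95/90/60/20%). Failed resamples are dropped, with an error if more
than 10% fail.

## Trace fitting

Stopped-flow association traces are normalized against a buffer-only
control (plateau division; a linear two-point mapping from fluorescence to
fraction unbound is assumed) and fit globally across concentrations to the
numerically integrated reversible bimolecular ODE. Strong binders fix
k_off = 0; "weak binding" mode fits (k_on, k_off) jointly and warns on the
single-trace degeneracy. Displacement traces fit the closed-form
irreversible second-order solution globally across invader concentrations.
Optimization is trust-region least squares in log-parameters with five
log-spaced multi-starts (k_on initials 10⁴–10⁸ M⁻¹s⁻¹), ftol 10⁻¹⁰;
covariance comes from the Jacobian at the optimum. At 1% Gaussian noise and
four concentrations, recovery over a seeded (k_on, k_off) grid spanning
10⁶–2×10⁷ M⁻¹s⁻¹ and 0.02–1 s⁻¹ has median relative error below 5%.

## Synthetic data: what it does and does not emulate

The generator module creates all test inputs: designed sequences (uniform
draws at the target CG count, rejecting self-complementary stretches ≥ 4 nt
and G-runs ≥ 3 — a scan, not a folding computation, adequate at these
lengths), stopped-flow traces (exact ODE + seeded Gaussian noise), melting
curves (exact binding quadratic + linear instrument baselines + noise), and
the standard mixture fixture (defaults: 12/8-mers at f_CG = 0.5, all four
strands at 1 μM — the micromolar, high-salt, room-temperature regime).
Everything is deterministic per seed.

Passing tests on these inputs demonstrate internal consistency — the
estimators invert the exact models that generated the data, at the stated
noise — not instrument realism: no dead time, photobleaching, lamp drift,
pipetting error, or model misspecification (e.g. real traces contaminated
by secondary structure or aggregation). Absolute rate predictions carry the
parameterization's own fitting uncertainty, which the envelope machinery
exists to propagate.

## Numerical conventions and degenerate inputs

* Energies kcal/mol; concentrations molar internally (nM/μM accepted in
  configs); rates M⁻¹s⁻¹ / s⁻¹; indices 0-based internally, 1-based
  5'→3' in CLI output.
* K_D exponents are clamped at |x| = 500 with a warning rather than
  overflowing.
* Fully melted points (f = 1) report K_D = ∞ instead of raising; Van't
  Hoff fits drop non-finite points and require ≥ 3 usable ones.
* `displacement_trace` switches to the analytic L'Hôpital limit when
  k_on[C]₀ and k_s agree to 10⁻¹²; `characteristic_timescale` interpolates
  the 1−1/e crossing linearly between grid points.
* A fully degenerate mixture (A_S = A_L, B_S = B_L) collapses to the single
  long-duplex hybridization; strands whose overhang admits no valid toehold
  simply omit that displacement channel, with the reason logged in the
  network notes.

## Problem sizes

Default test and reproduction sizes are chosen to resolve each claim
comfortably on a single core: 10⁴ Monte-Carlo samples per initial contact
for 6-bp oracle comparisons (binomial SE ≈ 10⁻²·√p), 400-point
logarithmic time grids over 10⁶ s for mixture equilibration, 500-point
uniform grids for apparent-rate fits, and 3×3 parameter grids at four
concentrations for recovery studies.

## Known limitations

* Two-state NN thermodynamics only; no salt correction (the packaged
  constants correspond to the high-salt regime where ~1 M NaCl and
  ~100 mM MgCl₂ behave equivalently), no temperature dependence of k_bi,
  k_uni or k_s.
* Mismatched, bulged or remote-toehold invaders are out of scope; the
  network builder is written over generic strand pairings but only the
  four-strand design is supported and tested.
* The zipper's absolute k_on scale inherits the two-state contact-energy
  approximation (see above).
* Thermal-annealing protocols (temperature ramps) are not simulated.
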