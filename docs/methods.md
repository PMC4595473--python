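# Methods

## The model

The IP3 receptor (IP3R) is modeled as an aggregated continuous-time Markov
chain with twelve states, nine closed (C00L, C20L, C30L, C32L, C34L, C04L,
C04I, C24I, C24H) and three open (O14I, O24I, O24H).  A state name `XmnM`
encodes conductance class (`C`/`O`), the number of bound Ca²⁺ ions `m`, the
number of bound IP3 molecules `n`, and the gating mode `M ∈ {L, I, H}`
(low-activity, intermediate, high-activity/bursting).  Mode membership:
L = {C00L, C20L, C30L, C32L, C34L, C04L}, I = {C04I, C24I, O14I, O24I},
H = {C24H, O24H}.

The chain is thermodynamically parameterized.  Each state carries an
*occupancy parameter* K (units µM^−(m+n); K = 1 for the unliganded reference
state C00L), the product of equilibrium association constants along any path
from C00L.  At Ca²⁺ concentration C and IP3 concentration I (both µM) the
unnormalized equilibrium weight of a state is Z_s = K_s·C^m·I^n, and

- open probability: Po = Z_O / Z with Z_O the summed open weights;
- modal prevalence: π^M = Z^M / Z.

Kinetics are parameterized by symmetric *flux parameters* j: a transition
S → U has rate j/K_S, its reverse j/K_U (times the appropriate ligand
powers), so equilibrium probability fluxes balance by construction.
Multi-step composite transitions combine step rates harmonically,
`rsr(x, y) = 1/(1/x + 1/y)` (reciprocal of sum of reciprocals).  Two
parameter sets ship with the package: `WT` (channel gating in the presence
of wild-type presenilin-1) and `M146L` (the familial-Alzheimer's PS1-M146L
mutant), differing in exactly four occupancy parameters (KC32L, KO14I,
KO24H, KO24I) and two flux parameters (j0414II, j2424HH).

Channel-model computations use µM and ms throughout; the cluster simulation
converts to µm/s/µM at its boundary.

### Conventions the rate table forces

- Backward rates whose printed form divides by a ligand power are evaluated
  in algebraically equivalent forms that stay finite at zero ligand, e.g.
  `rsr(a·C, b·C²)/(K·C²) = a·b/(K·(a + b·C))`.
- Two transition pairs (C04I⇌C24I and C00L⇌C20L) reuse the C04I⇌C24H rates
  verbatim.  This preserves detailed balance only because KC24I ≈ KC24H and
  KC24H/KC20L ≈ KC04I *to printed precision* (relative differences ~1e-4 and
  ~4e-5).  Consequences, measured by the test suite:
  - the stationary distribution of the assembled generator agrees with the
    normalized occupancy vector only to ≈2×10⁻⁵ relative (not machine
    precision) over the physiological ligand grid;
  - the closed-dwell mean −π_C·Q_CC⁻¹·1 agrees with Z_C/J only to ≈3×10⁻⁶
    (the identity requires exactly stationary weights); the open side is
    exact to 1e-12 because the open⇌closed flux balances by construction.
  Parameter values are stored at full printed precision and not re-derived;
  re-rounding or re-balancing them would silently change the published
  model.

### Equilibrium flux, mean times, modal lifetimes

J denotes the total unnormalized open→closed equilibrium flux,
J = Σ_open Z_s·Σ_closed r(s→u).  Mean open/closed times are τ_o = Z_O/J and
τ_c = Z_C/J, which makes Po = τ_o/(τ_o+τ_c) an identity.  (Defining τ from
*unnormalized* weights over the *unnormalized* flux is the only reading that
is dimensionally consistent; dividing the normalized Po by an unnormalized
flux would carry units of occupancy.)  A mode or arbitrary aggregate X has
lifetime τ^X = Z^X/J_X with J_X the total flux out of X.

## Dwell-time distributions

For a partition of a chain into aggregates X and Y, a sojourn in X started
at equilibrium has density f_X(t) = π_X·exp(Q_XX·t)·Q_XY·1, where the entry
distribution π_X = W_Y·Q_YX/J is the probability of entering X through each
X state (W_Y = diag of Y weights, J the X⇌Y flux).  The entry distribution
is always the one *into* the aggregate whose dwell is being measured — the
reading consistent with using f_X as the density of complete X sojourns.

Within-mode dwell distributions use the mode-restricted sub-chain: only
transitions among states of the mode populate the sub-generator, so leaving
the mode is not an exit event for a within-mode open/closed dwell.  For the
I mode this makes each open state's only exit its own closing transition
(O24I closes to C24I; a printed variant naming C24H in one matrix entry is
inconsistent with the sub-chain's own off-diagonal block and is resolved in
favor of C24I, which keeps the sub-generator rows conservative).

Densities and survival functions are evaluated through a cached
eigen-expansion of the sub-generator when its eigenvector basis is well
conditioned (cond < 1e8), and by scaling-and-squaring `expm` otherwise —
sub-generators need not be diagonalizable.  The two routes are
cross-checked in the tests to 1e-9.  Means use the closed form
−π_X·Q_XX⁻¹·1; an independent quadrature check integrates the survival
function (smooth and monotone, so adaptive quadrature resolves all
exponential components).

## Likelihood of idealized records

A gating record is an alternating dwell sequence (t_c1, t_o1, …, t_cn,
t_on), closed-leading and open-trailing.  Its log-likelihood is

    log L = log( π_C·e^{Q_CC t_c1}·Q_CO·e^{Q_OO t_o1}·Q_OC·…·e^{Q_OO t_on}·1_O )

with π_C = W_O·Q_OC/J (records are assumed to start at stationarity) and
the final open dwell contributing only its survival factor — the record ends
because recording stopped, not because the channel closed.  The state
row-vector is renormalized after every dwell factor with the log-norms
accumulated, so arbitrarily long records cannot underflow.  Per ligand
condition the Q blocks are eigendecomposed once and dwell factors applied
spectrally (complex-safe, with an `expm` fallback when the eigenvector
condition number exceeds 1e10); a compiled kernel makes the per-dwell cost
sub-microsecond.  No missed-event (dead-time) correction is applied: the
synthetic records are perfectly idealized, matching how the original
records entered the likelihood.

## Two-stage fitting

1. **Occupancy stage** — unweighted least squares of model (Po, π_L, π_I,
   π_H) against measured summaries over all supplied ligand conditions,
   optimizing log10 of the free parameters (trust-region reflective within
   ±8 decades of the start, so summaries carrying no information about a
   parameter leave it finite instead of running it to zero).  For the
   mutant fit only {KC32L, KO14I, KO24H, KO24I} are free; everything else
   stays pinned to wild-type values.

2. **Flux stage** — Nelder–Mead minimization of −log L over log10 of the
   free flux parameters ({j0414II, j2424HH} for the mutant) with the
   occupancies held fixed; objective tolerance 1e-6, ≤5000 iterations, with
   optional seeded restarts from perturbed starting points.

Identifiability caveat: at a *single* Ca²⁺ concentration the three
open-state weights enter every equilibrium observable only through
I⁴-scaled sums; KO14I (stoichiometry C¹I⁴) separates from KO24I/KO24H
(C²I⁴) only when conditions vary Ca²⁺.  Recovery tests therefore use a
Ca-varying condition grid; fits restricted to the 1 µM-Ca study conditions
inherit a one-dimensional degeneracy between KO14I and KO24I.

## Synthetic gating records

The generator replaces the nuclear-patch-clamp records, which were never
deposited.  It simulates the chain exactly (exponential sojourns, embedded
jump chain, stationary initial state, fully seeded), merges sojourns into
conductance dwells, and trims to the likelihood convention: a record starts
at the first closed dwell that *follows* a closing (so the first closed
dwell is entry-distributed) and ends with the censored final open dwell.
Ensemble defaults mirror the study: 30 records (WT) or 15 (M146L), 30 s
each, per condition.

What the generator emulates: stationary alternating dwell statistics of the
twelve-state chain at fixed ligands, including modal structure and the
serial correlation between neighbouring dwells that modal gating induces.
What it does not: recording noise, baseline drift, idealization (SKM)
errors, missed brief events, ligand nonstationarity.  Tests passing on
synthetic records therefore validate the estimation machinery, not the
idealization step of a real experiment.

Two censoring regimes matter for analysis:

- `empirical_summary` works on likelihood-convention traces;
- `trajectory_summary` works on untrimmed trajectories and keeps records
  with no openings at all.  This matters because L-mode quiescence is
  heavy-tailed here: C32L sojourns average ~700 s at 100 nM IP3 (~6700 s at
  33 nM), so trimmed, opening-containing records are a biased sample of
  stationary time, and π_L estimates converge slowly no matter how the
  records are cut (tens of thousands of seconds per condition still leave
  SE(π_L) ≈ 0.05).

### Modal segmentation

Following the experimental procedure: closings shorter than `t_short`
(default 10 ms; the published analysis removed "short closings" without
stating the threshold — 10 ms sits an order of magnitude below the modal
criticals and is configurable) are merged into bursts; a *gap* is a closed
dwell ≥ T_g = 200 ms and is assigned L mode; a *burst* is a maximal
interval between gaps, assigned H if it lasts ≥ T_b = 100 ms and I
otherwise.  Ties go to the longer-duration class.

Known property (demonstrated in the test suite): for these parameter sets
the duration-only rule recovers π_L well but folds essentially all I-mode
time into H — I-mode episodes last ~350 ms on average yet contain no
≥200 ms gaps, so nothing ends a burst inside them.  Measured π_I ≈ 0 and
π_H ≈ π_H + π_I.  The published modal analysis evidently used more than
the two critical durations; only the two criticals are documented, so only
they are implemented.  This bias is why the full
generate→segment→fit pipeline does not return the generating open-state
weights at the 5% level, while the same fit from unbiased summaries does.

## Cluster simulation of Ca²⁺ puffs and blips

Ten channels in a 2×5 planar array, 120 nm spacing.  Each channel owns a
spherically symmetric radial field of free Ca²⁺ and free dye on a
hemispherical domain of radius 5 µm; fields are solved independently and
superposed.  The local Ca²⁺ at channel i is C_i = c_rest + Σ_j
[c_j(r_ij) − c_rest], with the self term evaluated at the source-shell
radius Δr — the resting level is counted once (summing ten absolute
resting fields would give ten times rest, which is bookkeeping, not
chemistry).  Inter-channel buffer competition is linearized by the
per-channel-field construction; that approximation is inherited from the
source scheme, not corrected.

Numerics per field step (default dt = 50 µs):

- backward-Euler diffusion on the conservative finite-volume tridiagonal
  system (zero-flux at r = 0, Dirichlet rest at the far boundary), with the
  open-channel source folded into the implicit right-hand side so the
  near-source profile is the discrete Poisson solution rather than a
  dt-dependent spike (a Richardson test verifies ~first-order dt
  convergence and a few-percent step error at dt = 5 µs);
- pointwise semi-implicit dye binding (implicit in free dye, then in free
  Ca²⁺), which is positivity-preserving and leaves the resting buffer
  equilibrium an exact fixed point.

The source is J = I/(2FδV) within r ≤ Δr, with I = 0.05 pA, Δr = r_pore =
2.5 nm and δV the hemisphere of radius r_pore; with no buffer the
steady-state excess matches (I/2F)/(2πD_c r) to <5% for Δr ≪ r ≪ 5 µm, and
the finite-domain form (1/r − 1/r_max) to <0.1% over the whole interior.

Gating advances by *exact* jump sampling within each field step at frozen
local Ca²⁺ (rates interpolated from a log-Ca table built once per IP3), so
no transition-probability step-size restriction applies; a simple
first-order stepper (`step_channels`) is kept for clamped-Ca²⁺ reference
checks and refuses steps with r·dt > 0.1.  Channels whose field has
relaxed to rest are skipped until they reopen.  The default production grid
is geometrically stretched (160 nodes, 1.25 nm → 5 µm), resolving the
source shell with ~14 nodes and the 120 nm neighbour distance with ~6 nm
local spacing; a uniform 5 nm grid is available for convergence studies.

Buffer and geometry constants (B_d = 40 µM dye, k_on = 150 µM⁻¹s⁻¹,
k_off = 90 s⁻¹, D_c = 220 µm²/s, D_d = 32 µm²/s, c_rest = 0.07 µM) are
standard Ca²⁺-microdomain modeling values chosen a priori; the study's own
constants live in supplementary material that is not in the main text, so
these are explicit placeholders and every cluster-level statistic depends
on them.  With these defaults and physically correct near-source coupling
(self-Ca²⁺ ≈ 70 µM at the pore while open), the mutant cluster latches
into long sustained multi-channel release events — its H-mode lifetime at
elevated Ca²⁺ is seconds — so the mutant's event *frequency* is lower than
wild-type's while its puff amplitude and life-time distributions dominate.
Reproducing the published ordering of event frequencies (frequent short
mutant puffs) evidently requires the supplementary buffer/coupling regime;
the acceptance checks encoding that ordering fail under these defaults and
are left failing rather than tuned.

## Event detection and sensitization sweeps

A release event is a maximal interval with ≥1 channel open, bridging
all-closed gaps shorter than t_sep = 20 ms (well above intraburst closings,
well below observed inter-event intervals; configurable and reported with
all statistics).  Events are blips when exactly one channel opened at peak,
puffs otherwise.  Life time runs from event start to last closing;
termination time from the peak-open moment to last closing.  Amplitude is
reported in two metrics — peak open-channel count and peak summed excess
free Ca²⁺ at the cluster centre (with peak excess bound dye at a 1 µm
observation shell as a fluorescence proxy) — because the published
amplitude unit is unstated.

The deterministic sensitization sweep evaluates both variants' observables
over (Ca, IP3) grids and locates, by bisection on log-IP3 to ~1%
resolution: the IP3 at which the mutant's Po at 1 µM Ca²⁺ reaches the
wild-type's Po at 100 nM IP3 (≈7 nM), and the IP3 where the mutant's π_L
and π_H cross (≈10 nM).

## Problem sizes used by the test suite and acceptance checks

Chosen as the package's own balance of statistical power against
desk-scale runtime: Monte-Carlo dwell checks use a 4000 s trajectory
(~1.4×10⁵ dwells, thinned 64× for distributional tests to suppress serial
correlation) plus 4×10⁴ independently sampled dwells; the pipeline-closure
check uses 20 records × 500 s per IP3 condition for summaries and 30
records × 30 s for the flux likelihood; cluster checks use 100 s recordings
per variant at fixed seeds.  All randomness is seeded; identical seeds give
byte-identical traces.

## Known limitations

- Printed-precision detailed-balance breakage caps several consistency
  identities at ~1e-5 (see above); this is a property of the published
  tables, not of the implementation.
- The duration-only modal segmentation conflates I into H for these
  parameters; prevalence-based refits inherit that bias.
- No missed-event correction; no Bayesian uncertainty quantification
  (point estimates only, as published).
- The cluster model is per-channel radially symmetric with superposition —
  no full 3-D solve, no ER luminal depletion, no pumps/leaks (slow on the
  simulated timescales), and its quantitative event statistics depend on
  placeholder buffer constants.
- The untransfected-cell channel variant is not modeled; only the two
  presenilin-expressing parameter sets ship.
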