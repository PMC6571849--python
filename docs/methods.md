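# Methods

`lassocap` predicts the relative capture efficiency of gene-capture probes
(molecular inversion probes and their long-adapter variants, LASSO probes)
from equilibrium statistical mechanics, and provides the sequencing-side
statistics used to compare such predictions with capture experiments.  This
note records the model, the algorithms, the tunable parameters, and the
boundaries of what the desk-scale tests demonstrate.

## The reduced coarse-grained model

A probe (`extension arm + adapter + ligation arm`) and its single-stranded
DNA target are represented one bead per nucleotide in a periodic cubic box.
All distances are in nm and all energies in units of kT at the configured
temperature (default 338.15 K, the 65 °C capture temperature).  The energy
function has five terms:

* **Bonds** — harmonic, `E = k_b (r - r0)^2 / 2`, with `r0 = 0.65` nm (the
  single-stranded rise per base) and `k_b = 100` kT/nm².
* **Bending** — Kratky–Porod, `E = k_bend (1 - cos θ)` per interior bead.
  This is harmonic in the angle for small bends, and its transfer matrix is
  exactly solvable: `⟨cos θ⟩ = coth(k) − 1/k`, so the persistence length is
  `l_p = −r0 / ln⟨cos θ⟩`.  The default `k_bend = 2.8` kT gives
  `l_p ≈ 1.5` nm, the single-stranded DNA value at high salt.  The closed
  form is what the worm-like-chain validation tests assert against.
* **Excluded volume** — purely repulsive truncated-and-shifted
  Lennard-Jones (WCA) between all non-bonded bead pairs, `σ = 0.55` nm,
  `ε = 1` kT; pair repulsion is capped at `cap_energy = 100` kT so
  coincident beads remain finite.
* **Electrostatics** — screened Yukawa repulsion
  `A (e^{−r/λ}/r − e^{−r_c/λ}/r_c)` for `r < r_c = 2λ`, with the Debye
  length `λ = 0.304/√(M)` nm from the Na⁺ molarity.  The default 300 mM
  Na⁺ (the standard monovalent surrogate for a Mg²⁺-containing capture
  buffer) gives `λ = 0.55` nm: screening is nearly complete beyond the
  excluded-volume core, so this term is a small perturbation at capture
  ionic strength.
* **Hybridization** — Gō-like square wells of depth `hyb_epsilon` and range
  0.85 nm, acting *only* between each arm base and its designed
  complementary target base (found by exact antiparallel reverse-complement
  matching).  There is no nearest-neighbor thermodynamics, no stacking and
  no off-target pairing; the model's resolution is the polymer physics of
  capture, not base-resolution energetics.

The default well depth is `hyb_epsilon = 3` kT per pair.  The *sweep
studies* (below) instead use 1.2 kT per pair: capture is performed near the
arms' melting temperature, where the net per-base stability is of order
1 kT, and deep wells freeze arm unzipping out of the reachable Monte Carlo
timescale (the states with a partially unzipped arm are invisible to the
distance order parameter, so no umbrella can assist them).

## Order parameters

The capture state is summarized by `d_ex` and `d_lig`: for each arm, the
minimum minimum-image distance between its beads and their designed
complementary target beads.  Each distance is discretized on an 11-interval
table of half-open bins `[e_i, e_{i+1})` into `Q ∈ [0, 10]`; `(0,0)` is the
interaction state and `(10,10)` the fully dissociated state.  The default
table keeps every printed edge of the reference discretization
(0, 1.7, 3.4, 5.1, 8.5, 12.8, 17.0, 34.1, 68.1, 102.2 nm) and inserts one
edge at 85.2 nm so that the table has the stated 11 intervals (the
reference list enumerates only ten; the inserted edge continues the
doubling pattern of the far-field intervals).  Desk-scale studies use the
same table scaled by 0.6 so that the dissociated corner fits inside the
desk-scale box.

## Monte Carlo engines

A single-bead Metropolis sampler is the reference engine.  Production work
uses Virtual Move Monte Carlo in the symmetrized Whitelam–Geissler form:
a seed bead and a trial rigid map (translation, or rotation about the
seed) recruit neighbours into a cluster through pairwise link
probabilities `p1 = max(0, 1 − e^{−ΔE_fwd})`, with the reverse-map test
`min(1, p2/p1)` and outright rejection of frustrated links.  Two
implementation details matter for correctness:

* pairs that were tested, stayed unlinked, and later ended *inside* the
  cluster contribute a non-cancelling ratio of no-link probabilities; the
  acceptance is corrected by `min(1, Π e^{min(0,−ΔE_rev)−min(0,−ΔE_fwd)})`
  over such pairs;
* the bending term is three-body and cannot enter pairwise link formation;
  bend triplets straddling the cluster boundary are handled by an explicit
  Metropolis factor `e^{−ΔE_bend}`.

Both corrections preserve detailed balance exactly; the test suite checks
the stationary distribution against exact enumeration (two-particle
system) and against the Metropolis engine (4-bead system).

Move sizes default to 0.25 nm translations and 0.2 rad rotations (30–50 %
acceptance on reference systems).  Two optional mixtures address large
systems: occasional large translations (default off; sweep studies use
4 nm at 25 % probability) recruit whole chains through their bonds and act
as rigid diffusion moves; and the rotation fraction is configurable
because rotations displace far beads proportionally to their lever arm and
always recruit whole chains, which costs O(N²) per move once excluded
volume is on.

An umbrella weight table `w(Q_ex, Q_lig)` multiplies every move's
acceptance by `w_new/w_old`, so the sampler targets `w(Q) e^{−E}`.

## Umbrella adaptation (stage 1)

The weight table must span ~25–35 kT between the bound corner and the
dissociated corner.  Adaptation proceeds in three parts:

1. **Analytic prior.**  The dominant structure of `−ln P(Q_ex, Q_lig)` is
   known in advance: the minimum-image shell volume of each distance bin
   (computed exactly on a grid over the periodic cell) plus the expected
   well energy of a (mostly) zipped arm for bins inside the well range.
   Starting from this prior leaves only few-kT residuals — loop-closure
   entropy, partial zipping, arm–arm coupling — for the sampled stage.
2. **Wang–Landau anneal with a 1/t tail.**  Per-move updates lower the
   occupied cell's log-weight by `f`, halving `f` each block from 0.1 down
   to 0.005 and then decaying it as 1/t.  Per-move (rather than per-block)
   updating is what makes adaptation robust: a walker trapped in a cell
   the table over-weights continuously sinks that cell until it escapes.
   After each block the table is renormalized and cells not visited in
   that block are clamped to the visited maximum plus a small frontier
   margin — without the clamp, renormalization slowly inflates unvisited
   cells into absorbing traps.
3. **Pooled estimate.**  At the tiny `f` of the tail the per-block bias is
   essentially frozen, so each block yields an unbiased estimate
   `counts_b / w_b` through its weight snapshot.  These are pooled in log
   space across all tail blocks and the final table is rebuilt from the
   pooled estimate (cells without pooled data keep the deposit-stage
   value, spliced on a median-aligned scale).  Pooling keeps the
   information from every corner excursion instead of trusting whatever
   state the deposits happen to end in.

If the first block reveals a tiny reachable grid (at most four cells, an
enumeration-scale toy), there is no landscape to carve and Wang-Landau
deposits would only churn: the anneal stops, the table resets to the
analytic prior, and the tail runs as pure frozen measurement, re-splicing
the running pooled estimate after every block (an inaccurate prior
throttles the exchange rate, and each block's contribution stays unbiased
through its snapshot).

A final block under frozen weights provides the convergence diagnostic:
flatness (min/mean of visited-cell counts) is judged on the *diagonal*
cells, the reaction channel between the corners — off-diagonal extremes
such as `(0, 10)` are thin transit slivers whose block occupancy never
stabilizes, so a global flatness criterion would never fire.  A
non-converged table remains usable: re-weighting in the unbiasing step
corrects any bias imperfection at the price of variance.

The block-multiplicative rule `w ← w / counts` applied per block, with or
without damping, was implemented first and abandoned: block samples are
strongly correlated, so the update overshoots regionally and the table
ping-pongs without converging whenever the walker cannot cross the full
grid within one block.

## Production and estimation (stages 2–3)

Production runs under a *channel-shaped* copy of the adapted table: cells
outside the union of the diagonal band `|Q_ex − Q_lig| ≤ 2` and the two
bound-edge strips `min(Q_ex, Q_lig) = 0` are suppressed by 2 kT per cell of
excess.  Binding proceeds either with both arms closing together (the
diagonal) or sequentially (the edges); confining sampling to this channel
multiplies the corner-to-corner round-trip rate several-fold.  Because the
unbiasing step divides by the exact weights used, any weight table gives
an unbiased estimate; shaping only reduces variance.

After discarding the equilibration steps, the biased histogram is
accumulated and transformed to `P(Q_ex, Q_lig) ∝ counts/w` (in log space),
and the interaction free energy is

    dG_int / RT = −ln[ P(0,0) / P(max,max) ].

The statistical error is a block bootstrap over the recorded OP trajectory
(20 contiguous blocks, 200 resamples).  The diagonal free-energy profile
is `−ln P(q,q)`, shifted to zero at the dissociated corner; unvisited
cells are reported as gaps (NaN), and a never-visited corner raises an
explicit unbounded-estimate error rather than returning a number.

The full pipeline retries adaptation (and production) up to four times
with a deterministic seed schedule and a fresh initial configuration when
the pooled tail failed to measure both corner weights or production never
visited a corner; roughly one attempt in five lands in a table with an
absorbing artifact, and the retry schedule keeps the pipeline reproducible
for a given configuration seed.

## Desk-scale studies

Simulating 54–788-nt adapters against 400–1500-bp targets is beyond a
desk-scale test budget, so the packaged studies are explicit scale-downs:

* **Loop-closure sweep** — 4-nt arms, 8-bead target (sites adjacent),
  adapters of 16/32/64/128 beads, box fixed at 90 nm across the sweep.
  Bending, excluded volume and electrostatics are off, making the study an
  exactly Gaussian-chain limit: the closure cost between corner states
  grows as ≈ 1.5 ln N.  The measured slope is slightly depressed (≈ 1.4)
  by the constant part of the loop (arms plus target span) — the fit is
  over `ln N`, not `ln(N + const)`.
* **Capture sweep** — 8-nt arms, 40-bead target with sites at its two
  ends, adapters of 10/30/60/120 beads, box fixed at 90 nm.  This
  reproduces the study design of varying adapter length against a fixed
  gene target.  The 10-bead adapter can barely bridge the two target
  sites, the intermediate adapters close their loops cheaply, and the
  120-bead adapter pays the full ring-closure entropy — recovering the
  non-monotonic efficiency (intermediate adapters best, the longest
  worst) seen in capture experiments.

Both studies use the freely-jointed reduced chain (bending, excluded
volume, electrostatics off) with 1.2 kT wells.  At desk scale every
adapter spans several Kuhn lengths, so the adapter-length dependence is
dominated by loop-closure entropy; the sparse interaction set also keeps
bound-state kinetics (zipping/unzipping of 8-pair arms, arm threading)
fast enough for production round trips.  With excluded volume on, the
corner entry times exceed the affordable production length at this scale —
those runs neither converge nor fail loudly in a useful time, which is why
the studies do not use the full interaction set.  The box is fixed across
each sweep because a box growing with probe length would add a ~3 ln N
translational-entropy term to `dG_int` and mask the adapter physics; both
boxes satisfy the containment rule (side ≥ the longest strand's contour
length).

Production lengths are 6×10⁶ moves per member scaled up 2–4× with
adapter length (round-trip rates drop as adapters grow); weight
adaptation uses 30 blocks of 2×10⁵ moves.  These sizes give bootstrap
errors of 0.2–0.9 RT per member, sufficient for the slope and ordering
checks the studies support.

## What the synthetic data does and does not emulate

`gen_capture_system` guarantees exactly complementary arms (reverse
complements of the target ends) and shared arms across an adapter sweep —
mirroring the real study design, but with random sequences and no
off-target homology.  `gen_read_table` draws negative-binomial counts
(gamma–Poisson, dispersion 0.3) with mean `depth × enrichment ×
length/1000` and lengths uniform on 400–1500 nt; it emulates library
overdispersion and length scaling but not PCR bias, duplicate reads or
sequencing error.  Passing the parameter-recovery tests therefore shows
the *estimators* are correct and unbiased under the stated noise model,
not that real libraries satisfy that model.

`gen_wlc_chain` draws exact equilibrium samples of the bonded model (bond
lengths by rejection from their 1-D Boltzmann density, successive
directions by inverse-CDF of the Kratky–Porod kernel); it validates the
force-field calibration independently of the Monte Carlo engine.

## Enrichment statistics

RPKM is implemented with the standard `10⁹/(library reads × length)`
scaling — the bare ratio sometimes quoted omits the constant, and every
downstream quantity (median ratios, log ratios) is invariant to it.
Enrichment is the ratio of median target RPKM to median off-target RPKM
(median of an even stratum = mean of the central pair).  Probe free-energy
differences are `dG(A−B)/RT = −ln(RPKM_A/RPKM_B)`, implemented as a log
difference so antisymmetry is exact in floating point; the per-probe
relative scale sets zero at the largest RPKM (ties all map to zero).
Zero counts are handled by an optional +0.5 pseudocount, off by default.

## Known limitations

* The Gō wells are blind to off-target hybridization and mis-registered
  binding; capture specificity is outside the model.
* The order parameter is a minimum distance: states with one contact and
  states with a fully zipped arm land in the same cell, so the umbrella
  cannot assist partial-unzipping kinetics; this bounds the usable well
  depth (see above).
* dG_int depends on the box volume through the dissociated corner
  (dimerization free energies always carry a standard-state volume);
  comparisons are meaningful only at fixed box and bin table, which the
  studies enforce.
* The full interaction set (excluded volume on) is implemented and tested
  for correctness, but at desk scale its bound-corner kinetics are too
  slow for converged free-energy sweeps within a test budget.
* Weight-table adaptation is stochastic; roughly one attempt in five needs
  a retry (handled automatically, deterministically, inside the pipeline).
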