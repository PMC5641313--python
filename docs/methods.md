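# Methods

`sbskit` implements the strings-and-binders (SBS) picture of chromatin
folding as a self-contained, testable pipeline: a chromatin fibre is a
self-avoiding bead chain, one bead per genomic bin, decorated with
binding-site types; diffusing binder particles bridge cognate sites and
thereby fold the chain. The package covers four layers: (i) Langevin
dynamics of the bead–binder system, (ii) observables and phase
classification, (iii) decomposition of contact-decay curves into pure-state
mixtures, and (iv) inference of binding-site arrangements from a contact
matrix, with synthetic-locus generators that make every stage testable
without external data.

## Polymer model and integrator

Units are reduced throughout: bead diameter σ = 1, thermal energy kT = 1,
time τ = 1, mass 1. The force field is the standard bead-spring
(Kremer–Grest-style) choice for this class of models:

* **Bonds** between consecutive beads: FENE with K = 30 kT/σ², R₀ = 1.5 σ,
  plus the repulsive excluded-volume term below. The force-free bond length
  is ≈ 0.97 σ (`equilibrium_bond_length`).
* **Excluded volume** between all particle pairs: purely repulsive
  shifted-truncated 12-6 potential (WCA), ε = 1 kT, cutoff 2^(1/6) σ.
* **Binding**: a binder of type *t* and a bead carrying that type interact
  through a truncated 12-6 well of depth E_X × (site copy number), cutoff
  1.5 σ (the binder's interaction range). Binders of different types, and
  binders with non-cognate beads, interact only through excluded volume.
  Binder valence is not capped: one binder may bridge every bead within its
  interaction range.

Dynamics are underdamped Langevin integrated with the BAOAB splitting
(default dt = 0.01 τ, friction γ = 0.5 τ⁻¹), in a periodic cube with
minimum-image convention; coordinates are stored unwrapped. Defaults were
chosen so that a dt/stability check (`SimulationBlowupError`: non-finite
coordinate or bond beyond R₀, reported with the step index) never triggers
at well depths up to ~8 kT; deeper wells need a smaller timestep (the
reference protocols use dt = 0.005 τ at E_X = 12). Identical seeds give
bitwise-identical trajectories on one platform; across platforms identity
is statistical only.

Initial states: `build_initial_saw` grows an off-lattice self-avoiding
chain (unit bonds, no two beads closer than 0.8 σ, bounded backtracking)
and scatters binders uniformly without overlaps; `build_initial_compact`
threads the chain along a boustrophedon path on a cubic lattice;
`build_initial_ordered` builds a layered bead/binder crystal (serpentine
bead layers with rows at 2^(1/6) σ where excluded volume vanishes, binder
layers in the gaps with every contact at the 12-6 minimum, chain crossings
routed outside the slab face so no bond exceeds ~1.13 σ). The collapsed
reference states start compact or ordered because the spontaneous
coil–globule collapse — and far more so crystallisation — is slower than
any desk-scale run; starting near the expected equilibrium probes the
stability of a structure rather than the kinetics of reaching it.

## Observables and phase classification

* **Rg(t)** — gyration radius of the chain beads (binders excluded).
* **Equilibration** — a run counts as equilibrated when the linear trend
  fitted to Rg(t) over its last two thirds predicts a net change smaller
  than max(10 % of mean Rg, 2.5 fluctuation standard deviations). The
  fluctuation-scaled bound matters: an equilibrium coil's Rg wanders by
  15–25 % on long correlation times, so autocorrelated noise alone fits to
  1–2 σ of apparent drift, while a genuine coil→globule transit moves Rg by
  over 50 % and dominates its window variance (a pure linear transit has
  drift = √12 σ ≈ 3.5 σ). A fixed small percentage bound would reject every
  equilibrium coil; a slow drift hiding inside the fluctuation band is the
  accepted failure mode.
* **Contact maps** — entry (i, j) is the fraction of retained frames
  (pooled over replicas, first half discarded as burn-in) with beads i, j
  within a capture radius. Two radii are used deliberately: 3.5 σ for
  Hi-C-like maps (a generous capture volume, matching the diffuse nature of
  crosslinking), and 2.5 σ for P(s) *decay* analyses. The decay radius was
  calibrated once against a known standard: at 3.5 σ the short-separation
  curve saturates at 1 (any s ≲ 8 is always in contact), at 1.5 σ the s ≤ 4
  points are dominated by discrete-bond geometry and steepen the fit to
  ≈ −2.5; at 2.5 σ the coil reproduces the established self-avoiding-walk
  contact exponent ≈ −2.1 over 2 ≤ s ≤ N/4.
* **Size exponent ν** — across a chain-length sweep, from log Rg vs log N
  (`fit_scaling_exponent`); at a single length, from internal subchain
  scaling ⟨R²(s)⟩ ~ s^(2ν) fitted over s ∈ [4, N/2]
  (`internal_distance_exponent`). The internal estimate needs no calibrated
  prefactor, which matters because bound binders swell a globule's Rg
  prefactor without changing its scaling.
* **Bond-orientational order** — the neighbour-averaged Steinhardt
  order parameter q̄6 (Lechner–Dellago) over *bound* binders, neighbours
  within 1.4 σ among all particles. Raw per-particle q6 is useless here:
  with the 6–10 neighbours typical of these packings it is dominated by
  sampling noise (≈ 1/√n_neighbours ≈ 0.4 even for random bonds).
  Neighbour averaging suppresses that noise; on reference states the
  disordered (glassy/liquid) band is 0.18–0.29 across binder counts,
  affinities and temperatures, and crystalline packings score 0.44–0.55.

`classify_phase` labels an equilibrated trajectory **coil** if ν ≥ 0.50,
**globule** if ν ≤ 0.45 (values between go to the nearer band and are
flagged in the diagnostics), and splits globules into **ordered** vs
**disordered** at q̄6 = 0.35, the midpoint of the calibrated gap.

### The three reference corners

`sbskit.phases` pins one reproducible protocol per phase (N = 64 unless
noted):

| phase | affinity E_X | binders | start | T |
|---|---|---|---|---|
| coil | 0 | none | self-avoiding walk | 1 |
| disordered globule | 8 kT | lattice capacity (≈ 0.4/bead) | ordered slab | 1 |
| ordered globule | 12 kT | same, snug box (higher c) | ordered slab | 0 |

The disordered corner starts from the ordered slab because the bare compact
chain melts faster than shell-scattered binders can adsorb, which leaves
seed-dependent, arrested half-collapsed states; with binders pre-bound the
slab amorphises *in place* within ~20 τ into a reproducible compact glass
(q̄6 ≈ 0.21, ν_internal ≈ 0.2–0.3).

The ordered corner is the athermal strong-coupling limit: T = 0 overdamped
dynamics (γ = 2, dt = 0.005) from the layered crystal, i.e. the
E_X/kT → ∞ extreme of the "higher concentration and especially higher
affinity" corner of the phase diagram. This is a deliberate, documented
compromise: at these system sizes the crystalline packing is only
marginally metastable at any finite temperature — its surface remodels
within hundreds of τ, seed-dependently — and no finite-temperature
desk-scale run crystallises spontaneously (measured: q̄6 stays ≈ 0.21 from
every disordered start over 1600 τ, under annealing as well as quenching).
At T = 0 the relaxed crystal is indefinitely mechanically stable
(q̄6 ≈ 0.47). The classifier itself is temperature-agnostic; what the
corner protocols demonstrate is that each phase's structure is stable under
its own conditions, not that the dynamics can cross between them at this
scale.

## Pure-state mixture decomposition

A chromosome is modelled as a mixture of regions folded in the three pure
states, so its average contact decay is a convex combination of the
pure-state curves: P(s) = A·[f_c P_c(s) + f_d P_d(s) + f_o P_o(s)], with
the fractions on the simplex and A a free positive amplitude (raw Hi-C is
count-valued). Pure curves are simulated once per configuration by the
corner protocols (four replicas each), verified by `classify_phase`, pooled
into P(s) at the 2.5 σ decay radius, and cached on disk keyed by all
parameters.

The fit (`PureStateMixture`) minimises weighted least squares **on log P**
with weights 1/s (every decade of separation counts equally), seeded by
weighted non-negative linear least squares and normalised to the simplex.
Fitting in log space is deliberate: Hi-C-like noise is multiplicative, so
log residuals are the homoskedastic ones, and the two globule curves —
nearly collinear in linear space — separate cleanly. Under the package's
own noise model (5 % multiplicative), log-space fitting recovers planted
fractions to ≤ 0.04 where the linear-space fit errs by up to 0.30.
Frozen-crystal basis curves contain exact zeros at separations beyond the
slab diameter; separations where any basis curve is non-positive are
dropped from the fit. Observed curves from other chain lengths are mapped
onto the basis through fractional separations s/N with log-log
interpolation. The goodness statistic is χ² = Σ (obs − model)²/model over
the fitted range.

## Binding-domain inference

The arrangement of binding-site types is inferred from a contact matrix by
simulated annealing over binary occupancies a_{t,i} ∈ {0, 1} (inference is
binary; integer copy numbers are a synthesis-side generalisation). The
**forward model** is mean-field: contact(i, j) = min(saturation,
s^(−α) · (1 + β Σ_t a_{t,i} a_{t,j})), s = |i − j|, diagonal 1 — a
power-law backbone boosted wherever beads share binding types, which is the
structural signal binders create. Running molecular dynamics inside the
Monte-Carlo loop would cost ~10⁶ simulations per anneal and is unnecessary
for locating the sites; the inferred profile can afterwards be handed to
the simulator for 3D reconstruction, which is exactly what the pipeline
does.

The **cost** is the mean absolute difference between model and data maps
after each is scaled to unit off-diagonal mean (only relative structure is
comparable for unnormalised counts; L1 for robustness to heavy-tailed
noise), plus a sparsity penalty λ · (total sites)/n_beads (default
λ = 0.002) that suppresses the sites-everywhere degenerate fit. A
consequence of the scale-free cost is that a *uniform* enrichment is nearly
invisible except through the saturation cap — one reason the annealing must
be able to cross cost plateaus.

**Annealing**: moves flip one (type, bead) occupancy; Metropolis acceptance
(ΔE = 0 accepted, keeping plateau moves ergodic); geometric cooling
T_{k+1} = 0.95 T_k; one sweep = n_types × n_beads moves; best state over
`n_restarts` independent restarts returned, with the best-so-far cost per
sweep recorded (non-increasing by construction). Each restart starts from
an independent random occupancy (density 0.3). Random initialisation is
load-bearing twice over: restarts explore different basins, and the
automatic start-temperature calibration — T_start set from the mean uphill
ΔE of 200 probe moves so that initial acceptance ≈ 50 % — only sees
representative, data-scale cost changes from a non-trivial state. From an
empty profile every probe move costs just the sparsity penalty, T_start
collapses, and the annealer cannot cross the cooperative barrier out of the
empty state (single added sites change nothing until a second shared-type
site exists).

The number of types is user-supplied, as in the published locus models
(11 types for a 2.34 Mb locus at 30 kb, 15 for an 8 Mb locus at 50 kb);
inferred profiles are identified only up to a permutation of type labels,
so recovery is scored after Hungarian matching on site overlap
(`match_types`), with per-type Jaccard indices. Model-vs-data agreement is
the Pearson correlation over strict upper-triangle entries
(`map_pearson`).

## Synthetic loci and tracks

`make_block_profile` builds deterministic block architectures (the
two-colour alternating toy layout used throughout the tests);
`make_random_profile` draws geometric-length runs (default mean 8 bins)
assigned uniform random types, resampling until every type appears. The
default fixture scales mirror the published configurations: 160 bins × 15
types (8 Mb at 50 kb) and 78 bins × 11 types (2.34 Mb at 30 kb).
`synth_contact_map` applies unit-mean log-normal multiplicative noise to
the forward model (Hi-C counts are overdispersed; ratio noise is
scale-free), mirrored across the diagonal so maps are exactly symmetric;
the default coefficient of variation is 0.05, a fixture choice rather than
a claim about any particular dataset. `synth_track` plants a
chromatin-feature-like signal on one binding type (abundance row plus
Gaussian noise, floored at zero).

What the generators deliberately do **not** emulate: Hi-C technical biases
(matrix balancing artifacts, mappability, coverage), and any mismatch
between the mean-field forward model and real folding. Passing the planted
recovery tests therefore shows the inference machinery is correct and
well-conditioned under the stated noise model — not that the forward model
captures everything in experimental maps.

## Track binning and correlation

Tracks are interval signals in 0-based half-open (bedGraph) coordinates.
Binned values are coverage-weighted means over covered bases; bins with no
coverage are missing (NaN), not zero — no-data is distinct from no-signal.
Correlations between per-type abundance and binned tracks are raw Pearson r
with pairwise deletion of missing bins; cells with fewer than 4 shared bins
or zero variance are reported missing. Signals are used raw (no
binarisation or quantile normalisation) and no multiple-testing correction
is applied: the output mirrors the raw correlation heatmaps used to
annotate binding domains with chromatin features.

## Pipeline and reproducibility

`run_pipeline` chains the stages (read and symmetrise the matrix →
mixture-decompose its P(s) → infer the profile → simulate an ensemble of
the inferred model, one self-avoiding start per replica seed → contact map,
P(s), phase, XYZ conformations → track correlations), writes every artifact
with provenance header lines (package version, SHA-256 configuration hash,
master seed), and aborts with the stage name on failure, preserving partial
outputs. For fixed configuration and seed, all non-simulation outputs are
bitwise reproducible; simulation outputs are reproducible on one platform
and statistically equivalent across platforms. Binder species for the
reconstruction default to 0.5 binders per inferred site at E_X = 8 kT — the
disordered-globule regime, matching the compact-but-liquid organisation the
model attributes to real loci.

## Reference problem sizes

The validation suite runs chain lengths N ∈ {16, 32, 64, 128} with 10
replicas per length for scaling sweeps (400 τ each), 64-bead corners for
phase classification, four 600 τ replicas per pure-state curve, and the
160-bin × 15-type locus fixture for end-to-end recovery. These sizes were
chosen as the smallest at which the scaling fits stabilise (the bands
[0.54, 0.64] and [0.28, 0.38] are comfortably resolved) while a full
validation pass stays in the minutes range on a single CPU.

## Known limitations

* The ordered globule is demonstrated as a stable branch at the athermal
  corner, not reached kinetically at finite temperature (see above).
* The mean-field forward model ignores polymer connectivity beyond the
  backbone power law; its decay exponent, enrichment and saturation are
  fixed inputs to the inference, not fitted.
* No confinement, hydrodynamics, crowding or entanglement; binder valence
  is unlimited within the interaction range.
* The equilibration test cannot detect drifts hiding below the fluctuation
  amplitude.
* `n_types` selection is left to the user (a cost-vs-n_types sweep is easy
  to script with `BindingDomainAnnealer`); the published locus models fixed
  these counts externally.
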