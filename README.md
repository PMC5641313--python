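# sbskit — strings-and-binders chromatin polymer modelling

Chromosomes fold in 3D: Hi-C maps show megabase topological domains (TADs),
their higher-order groupings, and a contact probability P(s) that decays
over orders of magnitude in genomic separation. The **strings-and-binders
(SBS)** model explains this with minimal ingredients — a chromatin fibre is
a self-avoiding chain of beads carrying binding-site types, and diffusing
binder molecules (concentration *c*, affinity *E_X*) bridge cognate sites,
spontaneously creating loops, domains and compartments.

`sbskit` is a self-contained implementation of that modelling programme for
people who want to simulate SBS polymers, classify their thermodynamic
state, decompose contact decays, or infer binding-site arrangements from
contact matrices:

* **Simulation** — Langevin (BAOAB) dynamics of the bead–binder system with
  FENE bonds, excluded volume and type-specific binding wells
  (numba-accelerated, seeded, reproducible).
* **Observables** — gyration radius, contact maps and P(s) from replica
  ensembles, and classification of the three stable phases (open **coil**,
  compact **disordered globule**, crystalline-like **ordered globule**) via
  internal-distance scaling exponents and a neighbour-averaged Steinhardt
  q̄6 order parameter.
* **Mixture decomposition** (`PureStateMixture`) — fit an observed P(s) as
  a convex combination of the three simulated pure-state decays, the
  polymer-physics reading of eu-/heterochromatin composition.
* **Binding-domain inference** (`BindingDomainAnnealer`) — recover the
  multi-type binding-site profile from a contact matrix by simulated
  annealing against a mean-field forward model; hand the inferred profile
  back to the simulator for 3D ensemble reconstruction.
* **Epigenomic annotation** — bin bedGraph/BED tracks to model resolution
  and correlate them with inferred binding-domain abundance.
* **Pipeline & CLI** — `sbskit pipeline --config run.toml` chains matrix →
  mixture fit → inference → 3D ensemble → correlations, with provenance
  stamps on every artifact.

The two estimators follow scikit-learn conventions (`fit`, `get_params`,
fitted attributes with trailing underscores). Everything is validated on
synthetic loci with planted architectures at the scales of published SBS
locus models (e.g. 160 bins × 15 binding-site types for an 8 Mb region at
50 kb resolution).

## Worked example: recover a planted architecture

```python
import numpy as np
from sbskit import (
    make_block_profile, synth_contact_map,
    BindingDomainAnnealer, jaccard_per_type,
)

# a 40-bead toy locus: two binding-site types in alternating blocks of 10
planted = make_block_profile(40, [(0, 10, 0), (10, 20, 1), (20, 30, 0), (30, 40, 1)])

# its contact map under the forward model, with 5% multiplicative noise
cmap = synth_contact_map(planted, decay_exponent=1.0, enrichment=1.0,
                         noise_cv=0.05, seed=7)

# infer the binding-domain profile back from the map alone
est = BindingDomainAnnealer(n_types=2, n_sweeps=300, n_restarts=3,
                            random_state=0).fit(cmap)
print(f"map correlation r = {est.pearson_r_:.3f}")
print(f"per-type Jaccard  = {jaccard_per_type(est.profile_, planted)}")
```

Output:

```
map correlation r = 0.998
per-type Jaccard  = [1. 1.]
```

The inferred model's contact map correlates with the input at r = 0.998,
and after optimal type matching every planted binding site is recovered
exactly (Jaccard 1.0 for both types). On the 160-bin, 15-type locus-scale
fixture the same estimator reaches r ≈ 0.99.

Simulating the three phases directly:

```python
from sbskit import run_phase_corner, classify_phase

traj, binders = run_phase_corner("disordered_globule", n_beads=64, seed=1)
print(classify_phase(traj, binders))
# PhaseLabel(label='disordered_globule', nu_estimate=0.207,
#            binder_order_parameter=0.215, ...)
```

## Data formats

Dense or sparse-triplet contact matrices (TSV), bedGraph/4-column BED
tracks, profile TSVs (`chrom  bin_start  bin_end  type_0 … type_{k-1}`),
XYZ trajectories, TOML pipeline configs, JSON reports. Coordinates are
0-based half-open everywhere.
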