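# engramap

Micro-topographic mapping of activated neurons in the lateral amygdala (LA),
with the behavioral statistics of fear-memory reconsolidation experiments.

## What problem this solves

Pharmacological reconsolidation studies ask whether a drug given at memory
reactivation erases an auditory fear memory. Two readouts are standard:

* **Behavior** — percent freezing to the conditioned tone across three days
  (post-training, reactivation, test), analyzed with a two-way mixed ANOVA
  (drug group between subjects, day within subjects) and Tukey post-hoc
  comparisons, after excluding animals that froze ≤ 37% at reactivation
  (failed acquisition).
* **Histology** — the (x, y) positions of pERK-immunopositive (activated)
  neurons counted inside a traced LA contour. Rather than comparing only the
  whole-ROI totals, the contour's bounding box is tiled with a fixed grid
  (default 7 × 9 = 63 bins), each animal's point pattern becomes a count
  matrix, and every bin is tested with a one-way ANOVA across groups. The
  resulting p values are corrected with the Benjamini–Hochberg false
  discovery rate (tolerable limit q = 0.1) and mapped back onto the grid as
  a q-value matrix, revealing *hotspots* — localized bins where treatment
  changed the number of activated neurons. Planned pairwise comparisons
  inside significant bins classify each hotspot (all treatments lower than
  vehicle, or specific to a single drug).

`engramap` implements this pipeline end to end for analysts of such
experiments, together with a synthetic-data module that generates neuron
point patterns (inhomogeneous Poisson: uniform baseline plus truncated
Gaussian hotspots) and freezing cohorts with known ground truth, so the
whole analysis can be exercised, calibrated and power-checked without animal
data.

## The statistics

Per bin *b* with group counts `x_gb` (animals as replicates), the
mass-univariate test is the classical fixed-effects one-way ANOVA
`F_b = MS_between / MS_within`. Across the bin family (bins whose center is
inside the contour and that are not structurally empty), q values follow the
Benjamini–Hochberg step-up: with sorted p values `p_(1) ≤ … ≤ p_(m)`,

    q_(i) = min_{j ≥ i} p_(j) · m / j   (capped at 1),

and bins with `q < 0.1` are reported as hotspots.

Behavioral data use the standard mixed partition: the group effect is tested
against subjects-within-groups (df = N − k), day and group × day against the
within-subject error (df = (N − k)(m − 1)). The a priori sample-size
computation uses the noncentral F distribution with

    λ = f² · N · m · ε / (1 + (m − 1)ρ),  df₁ = k − 1,  df₂ = N − k,

the repeated-measures between-factors convention; with Cohen's f = 0.58,
α = 0.05, target power 0.8, k = 6 groups, m = 3 measures and ρ = 0.5 it
returns a total N = 36 (n = 6 per group).

## Worked example

A three-arm histology experiment (vehicle, high-dose mirdametinib, SL327) on
the bundled LA-like contour, with two planted hotspots that both drugs erase:

```python
import numpy as np
import engramap as em

roi = em.default_la_contour()
arms = [("vehicle", 1.0), ("mird-25", 0.15), ("sl327", 0.2)]  # hotspot multipliers
cfg = em.SimConfig(
    roi=roi,
    hotspots=[em.Hotspot(center=(650, 550), radius=60, amplitude=40),
              em.Hotspot(center=(350, 200), radius=60, amplitude=25)],
    spatial_specs=[em.GroupSpatialSpec(lab, 180.0, m) for lab, m in arms],
    freezing_specs=[em.GroupFreezingSpec(lab, phases={
        "training-post": (35, 8), "reactivation": (65, 10),
        "test": (65 if lab == "vehicle" else 38, 10)}) for lab, _ in arms],
    n_per_group=6, seed=7,
)
maps = em.simulate_neuron_maps(cfg)
grid = em.build_bin_grid(roi, rows=7, cols=9)
counts = [em.assign_counts(m, grid, roi) for m in maps]
res = em.mass_univariate(counts, grid, q_threshold=0.1)
em.classify_bins(res, counts, reference_group="vehicle")
```

Output of the summary loop (`res.n_family`, significant bins, totals):

```
family: 50 bins, significant at q < 0.1: 8
  bin (0,6): q = 0.0961, code = mird-25-specific
  bin (1,3): q = 0.0007, code = all-drugs-lower
  bin (2,2): q = 0.0824, code = all-drugs-lower
  bin (2,3): q = 0.0132, code = all-drugs-lower
  bin (4,5): q = 0.0244, code = all-drugs-lower
  bin (4,6): q = 0.0003, code = all-drugs-lower
  bin (5,5): q = 0.0019, code = all-drugs-lower
  bin (5,6): q = 0.0016, code = all-drugs-lower
total-count ANOVA: F(2,15) = 42.73, p = 6.398e-07
```

Reading: 50 of the 63 bins lie inside the contour; 8 of them are significant
at q < 0.1. Seven cluster around the two planted hotspots and are classified
"all-drugs-lower" (both drugs below vehicle, not different from each other —
the *red bins* of a q-matrix figure); one borderline bin comes out
drug-specific. The whole-ROI totals confirm a strong overall reduction. The
matching behavioral run (exclusion filter, mixed ANOVA, Tukey) prints:

```
retained 18/18 animals (> 37% reactivation freezing)
  group: F(2,15) = 0.98, p = 0.3988
  phase: F(2,30) = 49.90, p = 2.867e-10
  interaction: F(4,30) = 5.06, p = 0.003083
```

— the drug effect appears as a group × day interaction (groups differ only
on test day), exactly the signature a reconsolidation block produces.

The same analysis is available from the shell:

```bash
engramap run --config config.yaml --seed 7 --out-dir results/
engramap power --f 0.58 --alpha 0.05 --power 0.8 --groups 6 --measures 3 --rho 0.5
# total N = 36 (n = 6 per group), achieved power = 0.870
```

`engramap run` writes count matrices, density/CV maps (CSV + PNG), the
F/p/q matrices, the classified q-matrix plot, ANOVA tables and a manifest
with SHA-256 digests of every output; reruns with the same config and seed
are byte-identical.

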