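# Methods

This note documents the models, conventions and design choices behind
`engramap`, in the spirit of a statistical methods appendix.

## Spatial model and binning

**Input.** Per animal, the (x, y) positions (µm) of activated neurons inside
a traced ROI contour, assumed pre-registered to a common section frame
(registration, stitching and cell detection are upstream of this package).
Coordinates use the stored orientation directly — y increases with its
value; anatomical orientation (e.g. dorsolateral vs ventrolateral) is
metadata, not geometry.

**Grid.** The ROI's axis-aligned bounding box is tiled with a rows × cols
grid (default 7 × 9 = 63 bins, the family size used for LA sections). Bins
are half-open rectangles, with the far row/column closed, so every
bounding-box point maps to exactly one bin — there is no double counting and
no gap. A bin belongs to the analysis family iff its **center** lies inside
the contour (boundary inclusive). Center-in-polygon was chosen over
area-overlap weighting because it is deterministic, cheap, and matches the
presentation of a rectangular matrix superimposed on a contour; the cost is
that boundary bins with small overlap may be kept or dropped "unfairly",
which is irrelevant for interior hotspots. A helper (`suggest_grid`)
proposes grid dimensions targeting at least one expected neuron per bin.

**Counts.** Coordinates outside the contour are excluded (and reported).
Every in-ROI coordinate increments exactly one bin — including the rare bin
whose center is outside the contour while part of its area is inside; such
counts are reported separately (`n_in_masked_bins`) rather than silently
dropped, so the per-animal total over *all* bins always equals the in-ROI
neuron count. Counts are raw, not area-normalized: all bins share the same
area, so normalization would only rescale every statistic; the ROI area is
recorded for reporting.

**Group maps.** The density map is the per-bin mean count across a group's
animals; the CV map is the per-bin sample SD (n − 1 denominator, because
groups are small samples of typically 6 animals) divided by the mean,
flagged undefined where the mean is zero.

## Per-bin statistics and FDR

Each family bin is tested with the classical fixed-effects one-way ANOVA
across conditions, animals as replicates. The implementation is by explicit
sums of squares rather than a library call because count data at n = 6 hit
degenerate cases that need defined answers:

* all values equal in every group → F = 0, p = 1;
* zero within-group variance with unequal means → p = 0;
* bins with zero counts for every animal are structurally empty and are
  excluded from the family — testing them cannot reject and only inflates
  the family size m.

The family's p values enter the Benjamini–Hochberg step-up procedure;
q values are reported for every family bin (the full q matrix, not only the
significant entries), and the rejection set is `q < q_threshold` with the
threshold defaulting to the tolerable FDR limit 0.1. Masked (outside-
contour) bins never enter m.

**Classification.** Inside each FDR-significant bin, planned pairwise
comparisons run as *uncorrected* two-sided two-sample t-tests at α = 0.05
(pooled variance by default; Welch available by flag). Codes:
`all-drugs-lower` if every treatment is significantly below the reference
and no two treatments differ; `<label>-specific` if that treatment is below
both the reference and every other treatment; `other` otherwise. Planned
comparisons are gated by the q mask — a non-significant bin is `none`
regardless of its means. Leaving the planned tests uncorrected is a
deliberate reading of "planned comparisons"; the gate by the FDR mask
already controls the family-level error of *selecting* bins.

The whole-ROI analysis applies the same one-way ANOVA to per-animal totals
over family bins.

## Behavioral statistics

**Inclusion rule.** An animal counts as conditioned iff its reactivation
freezing is strictly greater than 37% — an animal at exactly 37.0 is
excluded. The threshold is configurable.

**Mixed ANOVA.** The two-way repeated-measures ANOVA uses the textbook
mixed partition: between-subject SS splits into group and
subjects-within-groups (error for the group test, df = N − k);
within-subject SS splits into phase, group × phase, and
phase × subjects-within-groups (error for both within tests,
df = (N − k)(m − 1)). Group sizes may be unequal (exclusions make them so);
the within-subject layout must be complete per animal. Published denominator
degrees of freedom in this literature sometimes follow other conventions
(e.g. pooling errors); this package implements the standard partition and
reports all dfs explicitly rather than reverse-engineering any particular
printed table.

**Tukey HSD.** Pairwise comparisons use the studentized-range distribution
with the Tukey–Kramer standard error for unequal n, and take the error term
as an *argument* so the caller controls it. For group comparisons in the
mixed design the error is the between-subject mean square on the
subject-mean scale (the convenience wrapper computes exactly that), because
group is a between-subject factor.

**Power analysis.** `rm_anova_power` follows the G*Power repeated-measures
*between-factors* formulation: λ = f² N m ε / (1 + (m − 1)ρ), df₁ = k − 1,
df₂ = N − k, power = P(F′(df₁, df₂, λ) > F₀.₉₅). Among the standard
repeated-measures power conventions (between, within, interaction — which
differ in how ρ enters λ and in their dfs), this is the one that reproduces
the canonical worked result N = 36 from f = 0.58, α = 0.05, power 0.8,
k = 6, m = 3, ρ = 0.5; the within/interaction formulations give materially
different N (about 12–42) from the same inputs. ε defaults to 1 (sphericity
assumed; no correction applied). `rm_anova_sample_size` searches the
multiples of k upward and returns the smallest N with power ≥ target.

**Degenerate conventions** mirror the bin statistics throughout: zero error
variance yields p = 1 for a zero effect and p = 0 for a nonzero one.

## Synthetic data generator

Each animal's point pattern is an inhomogeneous Poisson process:

* a uniform baseline over the contour with expectation `baseline_count`
  (rejection sampling from the bounding box, hard cap of 10⁶ proposals so a
  pathological sliver polygon fails loudly instead of spinning);
* per hotspot, an isotropic Gaussian at the hotspot center with scale
  `radius`, truncated to the contour, with expectation
  `hotspot_multiplier × amplitude`.

Group effects are carried by `hotspot_multiplier`: 1 preserves the hotspot,
0 erases it, intermediate values attenuate it. This is the simplest
generator whose bin-level consequences (Poisson counts with a localized mean
shift) match what the analysis assumes; it deliberately does **not** emulate
staining variability, section-to-section registration error, over-dispersed
(clustered) neuron placement, or count-dependent detection thresholds.
Passing calibration tests therefore demonstrates correctness of the
statistics under the stated model, not robustness to those real-data
artifacts.

Freezing values are Normal(mean, SD) per animal × phase, clamped to
[0, 100] after sampling (freezing is a bounded percentage). The bundled
six-arm demo (vehicle, three mirdametinib doses, SL327, trametinib; n = 6
per arm; baseline 180 neurons; hotspot multipliers 1.0 / 0.5 / 0.35 / 0.2 /
0.25 / 1.0; test-day freezing ~65% for controls, 35–45% for effective
drugs, SD 10) is qualitative: it encodes the *direction and layout* of a
reconsolidation pharmacology experiment, not fitted values.

**Reproducibility.** All randomness flows from the config seed. Per-animal
generators derive from the counter scheme
`default_rng([seed, stream, index])` (stream 0 = point patterns, stream 1 =
freezing; index enumerates animals in config order), so any single animal
can be regenerated without replaying the cohort, and identical configs give
bit-identical output. Pipeline reruns reproduce every CSV byte-for-byte;
the manifest records SHA-256 digests to verify this.

## Calibration and test problem sizes

The test suite checks, at sizes chosen to keep the default run in tens of
seconds on one core:

* exact agreement of the one-way ANOVA and BH q values with brute-force
  oracles on 1,000 randomized instances each (1e-9 relative for F, exact
  for q);
* empirical FDR ≤ 0.13 at q = 0.1 over 500 fully-null simulated cohorts
  (6 groups × 6 animals, 63-bin family, ~3 expected neurons per bin);
* ≥ 80% recovery of a planted hotspot whose per-bin standardized effect is
  ≈ 2 at n = 6 (amplitude A solves A/√(μ + A/2) = 2 for per-bin Poisson
  mean μ = 3) over 200 cohorts in the six-arm layout, plus correct
  drug-specific labeling in a three-arm layout at effect ≈ 3;
* type-I error of the mixed ANOVA group test within 0.05 ± 0.02 over 1,000
  null cohorts, and Monte-Carlo power (3,000 simulated-and-fitted cohorts
  under a compound-symmetric model whose group-mean spread equals f = 0.58)
  within ±0.03 of the noncentral-F computation at N = 36.

## Known limitations

* Bin-family membership by center-in-polygon makes boundary-bin membership
  sensitive to grid placement; no partial-area weighting is offered.
* No spatial smoothing, cluster-extent inference or permutation maxT
  correction — bins are treated as exchangeable univariate tests.
* The mixed ANOVA assumes compound symmetry for its within-subject tests
  (no Greenhouse–Geisser/Huynh–Feldt correction is applied); the power
  routine exposes ε but the fitting routine does not estimate it.
* The generator's truncated-Gaussian hotspots ignore anatomical boundaries
  other than the ROI contour itself.
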