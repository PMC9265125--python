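# Methods

This note records the modeling choices, conventions and limitations of the
pipeline, in the order the data flow through it.

## Synthetic cohorts

Each case is a pair of 3D volumes (sequence roles "GD" and "T2") sharing
one ellipsoidal VOI mask on a common grid. A volume is

    value = 100 + 20 · G_σ(white noise)/sd + noise_sd · white noise,

with an additional class-specific mean shift added inside the VOI. G_σ is
a Gaussian filter of width σ in millimetres (so anisotropic voxel spacing
matters), giving the within-VOI texture a single interpretable correlation
length that texture matrices demonstrably detect. The two classes differ
in σ and in the VOI mean shift; the single knob `effect_size` interpolates
both class parameter pairs about their midpoints: 0 makes the classes
identically distributed, 1 reproduces the configured pairs, larger values
widen the gap proportionally. Class separation in mean VOI intensity is
therefore linear in `effect_size` by construction.

Defaults (fixed once, before any evaluation): grid 48×48×20 voxels at
1×1×3 mm (slice thickness above in-plane resolution, the MRI norm), VOI
radii drawn uniformly in 11–14 mm per axis (ellipsoid volumes ≈5.6–11.5
cm³, the scale of skull base tumors), texture scales (2.0, 3.5) mm,
intensity shifts (0, 10), noise SD 5. Ellipsoids are axis-aligned so an
analytic volume is available for morphology checks, and are placed with
one voxel of margin so masks never touch the grid border.

What the generator does **not** model: MRI physics (bias fields, coil
profiles, k-space artifacts), inter-observer mask variability, class
overlap structure beyond second-order statistics, and scanner-to-scanner
feature instability. Passing tests therefore demonstrate that the
machinery is correct and recovers planted structure — not that it would
reach any particular accuracy on clinical data.

## Image I/O

Grids are ordered (x, y, z) following the NIfTI affine; spacing comes from
the header and is used for every physical quantity. There is no resampling
stage: a volume/mask grid mismatch (shape, or spacing beyond 1e-4 mm) is
an error, never a silent interpolation. Mask voxels are foreground when
their stored value exceeds 0.5, tolerating fractional exports from
treatment-planning systems.

## Wavelet subbands

Single-level, undecimated (stationary) separable Coiflet-1 analysis
filtering along x, y, z in all 8 L/H combinations, plus the original
image. Undecimated is the only alignment-preserving choice: subbands stay
voxel-aligned with the VOI so no mask resampling is needed. Boundaries use
half-sample symmetric (edge-repeating) padding; filters are the standard
orthonormal Coiflet-1 analysis taps with no extra rescaling; subband label
letters order the axes as (x, y, z). These three conventions (undecimated,
padding mode, letter order) are package conventions, not facts fixed by
any upstream description. Correctness is pinned by a brute-force separable
convolution oracle (impulse responses to 1e-10) and a linearity property.

## Discretization

Fixed-bin-number quantization over the within-VOI range of each image:
level = floor(n_bins·(x−min)/(max−min)) + 1, maximum clamped to n_bins, a
constant region mapping to level 1. Every wavelet subband is re-quantized
independently (subbands have unrelated dynamic ranges). Texture features
use 16/32/64/128 bins; histogram features fix 64. The scheme is monotone
and invariant to affine intensity maps, which makes every downstream
texture family affine-invariant as well.

## First-order and morphology features

Intensity moments use the population (divide-by-N) convention; skewness
and excess kurtosis of a constant region are defined as 0; percentiles
interpolate linearly; the robust mean absolute deviation averages over the
closed 10–90th percentile band (0 if the band is empty); coefficient-of-
variation-style ratios return 0 on zero denominators. Histogram entropy is
base 2; mode ties break to the smallest level; the histogram gradient uses
central differences with one-sided ends.

Morphology meshes the mask indicator with marching cubes at level 0.5
using header spacing. The indicator is first smoothed with a Gaussian of
0.8 voxels: meshing a raw binary grid overestimates surface area by the
staircase factor (a digitized ball of radius 15 voxels reads sphericity
0.92 raw vs 0.99 smoothed); masks so small that smoothing drops the peak
below 0.5 are meshed raw. Mesh volume comes from the divergence theorem
over the oriented triangles, so sphericity, compactness 1 and
compactness 2 are mutually consistent (compactness 2 = sphericity³ by
construction). The maximum 3D diameter is the largest pairwise distance
between VOI voxel centers (convex-hull accelerated), floored at the
largest voxel spacing so a single-voxel VOI still spans one voxel.

## Texture families

All five families run on the quantized VOI cropped to its bounding box,
with the 26-neighborhood at Chebyshev distance 1:

- **GLCM** — counts merged over the 13 unique directions and both
  orientations (symmetric), normalized once; merged-matrix aggregation is
  chosen over per-direction averaging for determinism and cost.
- **GLRLM** — maximal equal-level runs per direction, counts merged over
  the 13 directions; run percentage divides by (voxels × 13) so it stays
  in (0, 1].
- **GLSZM** — 26-connected equal-level zones (scipy labelling), direction-free.
- **NGLDM** — dependence = number of identical-level neighbors (α = 0);
  matrix indexed by (level, dependence+1).
- **NGTDM** — per-level sums of |level − neighborhood mean|; coarseness
  denominator guarded at 1e-6; contrast/busyness/strength return 0 in
  their degenerate cases, as does GLCM correlation when the gray-level
  variance vanishes.

The per-family rosters (11/13/13/16/5) live in a versioned registry file
(`data/feature_registry.yaml`) that is the single source of truth for
names, counts and column order; extraction refuses to run if the registry
violates the counts. The roster identities beyond the handful of
externally anchored names (GLCM correlation and inverse difference moment;
GLRLM gray-level non-uniformity and gray-level variance; GLSZM HGZE, ZSV,
LGZE, GLN) are declared package conventions in the standard
texture-analysis style. Every family is verified feature-by-feature
against an independent brute-force enumeration oracle (plain-Python pair,
run, zone and neighborhood enumeration) to 1e-8.

## Feature table and normalization

Columns render as `{bins}_{seq}_{subband}_{family}_{name}` with the bins
token `log2(bins)bit`; intensity features render the bins field as `-`;
morphology renders as `{seq}_MORPH_{name}` (the sequence token is kept so
the per-case table has 4876 unique columns). Z-scores use the sample
(N−1) standard deviation, are fit on the training table only and applied
unchanged to validation tables; constant columns are flagged and map to 0.

## Selection

RFE importance is |coefficient| of an L2 logistic regression (C = 1) on
z-scored features; one feature is removed per refit, ties removing the
lexicographically last name, so survivor sets are nested across k. The
feature number 1..10 is chosen by 4 stratified subgroups × 5 repeats
(stratified because small two-class cohorts can otherwise produce
single-class folds), maximizing mean held-out accuracy with ties to the
smaller k. Frequency voting runs one RFE per repeat on a re-randomized
stratified 3/4 subsample; ties in frequency break by mean elimination
rank, then name. Pruning computes Pearson correlations within each
sequence's features and repeatedly drops the lower-frequency member of the
worst pair above |r| = 0.7 (absolute value: anticorrelated features are
equally redundant), until the bound holds.

One-at-a-time elimination from thousands of columns costs one logistic fit
per removed feature. The end-to-end driver therefore uses a geometric
schedule — drop 20% of remaining columns per refit until 30 remain, then
one at a time — which preserves the small-k regime where the decisions
matter while cutting a ~2400-fit chain to ~50 fits. Strict one-at-a-time
elimination remains the default of `rfe_rank` and is what the selection
unit tests and the planted-recovery acceptance check exercise.

## Modeling and evaluation

Grids: logistic C ∈ {0.01, 0.1, 1, 10, 100}; SVM linear and RBF kernels
with the same C values and RBF γ ∈ {1/d, 0.01, 0.1, 1}. Tuning scores each
point by stratified 2-fold CV AUC on a stratified 80% subset drawn once
per seed; ties keep the earlier grid point. Evaluation is stratified
5-fold CV with normalization refit per fold; AUC is trapezoidal over all
thresholds; the report carries mean ± sample SD of the fold AUCs. The
hold-out model is refit on **all** training cases (not just the 80%
tuning subset) with training-only normalization; accuracy is reported as
an exact fraction. SVM ROC scores are signed margins — AUC is rank-based,
so probability calibration would change nothing.

The reader comparison is a two-sided one-sample t-test of the reader
accuracies against the model accuracy as the reference value, with a
Shapiro–Wilk normality check, the panel median, and a 95% CI of the mean
(t-quantile); p < 0.05 is the declared significance rule.

## Problem sizes used by the test and acceptance runs

Simulation-based checks use cohort sizes chosen as a balance of
statistical resolution and desk-scale runtime, fixed before evaluation:
planted-feature recovery uses 100 seeded replicates of 50 cases × 50
features; null calibration uses 100 label permutations on one extracted
cohort plus 6 effect-free cohorts (24 train / 10 validation at 24×24×12
voxels); the end-to-end separation check uses 6 replicates of a
47-train/10-validation cohort (27/20 and 5/5 by class) at 32³ voxels with
effect size 2.0, requiring hold-out accuracy ≥ 0.8 in at least 80% of
replicates. `scripts/acceptance.py` re-runs the same computations at
comparable sizes from a caller-supplied seed.

## Known limitations

- The synthetic phantoms carry no MRI physics; absolute feature values on
  clinical data will differ even where the machinery is identical.
- Feature-identity rosters beyond the anchored names are conventions; a
  different roster of the same sizes would change feature values but not
  counts, selection mechanics or evaluation behavior.
- No harmonization across scanners (feature stability is explicitly out
  of scope), no DICOM/planning-system I/O, no multi-level wavelets, no
  texture offsets beyond distance 1.
- With tens of cases, hold-out accuracy on 10 cases is a coarse statistic
  (steps of 0.1); the repeated-CV AUC is the more stable summary, and the
  pipeline reports both.
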