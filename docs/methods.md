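# Methods

This note documents the models, algorithmic conventions and design
choices behind `xaibench3d`, in the spirit of the methods documentation of
packages like statsmodels or msprime: what is computed, under which
assumptions, and where the genuinely open choices were made.

## Data model and adapter contract

A `Sample3D` is one of three modalities: a dense scalar volume (D, H, W),
a binary occupancy voxel grid (D, H, W) with values in {0, 1}, or a point
cloud (N, 3) of xyz coordinates. An `AttributionMap` carries one
relevance value per element (voxel or point), min–max normalized to
[0, 1]; a constant raw map normalizes to all zeros on the grounds that a
map that distinguishes no element assigns no relevance.

Classifiers enter through the `ModelAdapter` contract: `score(x)` returns
the per-class confidence vector consumed by the perturbation metrics;
`gradient(x, c)` differentiates the raw class score (the logit) with
respect to the input. Trained adapters report softmax probabilities as
confidence, which keeps AOPC/AUPC on the interpretable [0, 1] scale. The
analytic linear oracle adapter instead reports its raw score as
confidence so that every closed-form identity used in testing — saliency
= |w|, integrated gradients = w⊙x, single-element occlusion = w⊙x, the
AOPC trapezoid over hand-computable drops — holds exactly rather than
through a softmax.

## Attribution methods

- **Saliency**: |∂f/∂x| per grid element; per-point L2 norm over the
  three coordinate channels for clouds.
- **Integrated gradients**: midpoint-rule path integral with n steps
  (default 50), zero baseline by default. The midpoint rule is exact for
  linear scores at any step count and second-order accurate otherwise.
  Signed attributions (which satisfy the completeness identity
  Σ = f(x) − f(baseline)) are retained as metadata; the normalized map
  ranks by magnitude — per-element |·| on grids, per-point L2 norm on
  clouds — because the metrics need a single non-negative relevance per
  element and the sign convention for ranking negative evidence is not
  canonical.
- **Occlusion**: confidence drop when a region is set to the baseline.
  Grids use a sliding window (voxel default 4³, volumetric default
  dims/8) with stride = window (non-overlapping tiling) by default; a
  final window is clamped flush with the far edge so every element is
  covered, and overlapping coverage averages the drops per element.
  Point clouds are sorted along the Morton (z-order) curve of their
  quantized coordinates and chunked into contiguous clusters of 10; this
  is deterministic and spatially coherent without requiring a mesh or
  graph structure.
- **Grad-CAM**: channel weights are the spatial means of the layer
  gradients; the map is ReLU(Σ w_c A_c) — rectification before
  upsampling, the standard definition — trilinearly upsampled to input
  shape. For point models the per-centroid CAM values at the
  set-abstraction layer are propagated to each point from its nearest
  centroid (exact Euclidean comparison, ties to the lowest centroid
  index).
- **Intrinsic attention**: a named mask from the adapter (default the
  second soft stage, "soft2"), trilinearly upsampled and normalized.
  Point-cloud adapters raise an unsupported-method error: dense attention
  modules have no analogue in set-abstraction architectures.

Normalization is per map, over all of its elements. All methods are
deterministic: identical inputs and configuration give bit-identical
maps.

## Perturbation metrics

The schedule is k/K for k = 1..K (default K = 10). "Top fraction"
counts ceil(fraction · M) elements against the total element count M,
with ranking ties broken by ascending flat index. Point "removal"
replaces coordinates by the baseline constant (zero collapses points to
the origin) rather than deleting rows, keeping tensor shapes fixed.

AOPC integrates the drop curve by the trapezoidal rule with an implicit
(0, 0) origin; AUPC's curve starts at 0.0 by definition (empty input).
Removal and preservation are exact complements: at every fraction the
replaced set of one equals the kept set of the other.

Compactness counts elements at or above a threshold against the non-zero
elements of the input; every point counts as non-zero for clouds, where
occupancy is meaningless. The adaptive threshold is the value of the
ceil(a · M)-th largest attribution (the empirical (1 − a) quantile,
a = 0.1 by default) taken over **all** elements; taking it over only the
occupied elements is available as a configuration switch
(`CompactnessConfig.quantile_population`), since either reading is
defensible and the all-elements variant is what produces the
diagnostically interesting ratios above 1 on sparse occupancy grids.

Baselines are modality-specific: mean intensity for dense volumes
(removing structure without leaving an artificial void), zero for voxel
occupancy and point data (absence of structure), with an optional
Gaussian-blurred baseline (σ configurable).

## Statistics

Kruskal–Wallis H uses midrank tie correction (delegated to
scipy.stats.kruskal); the all-identical degenerate case returns H = 0,
p = 1 rather than an error. The effect size is the epsilon-squared-style
estimator η² = (H − k + 1)/(n − k), clamped at 0 when small samples push
it negative.

The Mann–Whitney U test is implemented with a genuine exact permutation
option: all C(n1+n2, n1) assignments of the pooled ranks are enumerated
and the two-sided p-value counts assignments at least as extreme in
|U − μ|. "Auto" mode uses the exact branch for pooled n ≤ 12 with
tie-free data, otherwise the tie-corrected normal approximation with a
0.5 continuity correction; the normal Z-score is always retained for
Cohen's r = |Z|/√n (interpretation bands 0.1/0.3/0.5). Bonferroni
correction multiplies by the number of method pairs within one
dataset–metric combination and caps at 1. Outlier filtering removes
values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] with linear-interpolation
quantiles; with fewer than 4 values the filter is skipped with a warning.

## Protocol

Per class, the benchmark selects ceil(s/2) correctly and floor(s/2)
incorrectly classified samples (default s = 5), ordered by sample id,
back-filling from the other stratum on shortfall. Incorrect predictions
are evaluated against the model's actual decision, not the true label.
Per metric, each method's scores are IQR-filtered, Kruskal–Wallis gates
pairwise Mann–Whitney tests at α = 0.05, and pairwise results are still
emitted (flagged exploratory) when the gate is non-significant.
Attribution maps are evaluated at the native sample resolution;
`resample_volume` (trilinear, cell-center convention) is exposed for
cross-resolution aggregation but not silently applied.

## Synthetic fixtures

The generators emulate the three modalities' essential structure, not
their appearance:

- **Blob volumes**: a compactly supported Gaussian bump (σ = 2 voxels,
  amplitude 1) at a class-specific site on a noisy background (noise σ
  default 0.1); class sites are rejection-sampled to be pairwise
  separated so classes cannot overlap. The ground-truth mask is the
  above-half-maximum support.
- **Voxel primitives**: solid cube, sphere shell, and three-bar cross
  with jittered pose; mask = occupancy.
- **Point clusters**: class c places c+1 Gaussian clusters at fixed
  template sites inside the unit sphere, with 75% cluster points and 25%
  uniform clutter; mask = cluster membership.

Grids default to 16³ and clouds to 128 points so the full protocol and
test suite run in minutes on one CPU; paper-scale shapes remain
configurable. What passing tests on these fixtures shows is that the
*measurement machinery* is correct and that the metrics detect planted
causal structure; it does not show how attribution methods rank on real
CT or scan data, whose texture, anisotropy and label noise the fixtures
deliberately omit.

The model adapters are small NumPy models with analytic gradients,
validated by central finite differences (tolerance 1e−4): a linear-score
oracle, a one-conv-layer CNN (8 seeded random filters, kernel 3, stride
2, ReLU, linear head), a Gaussian-kernel set-abstraction point model
(8 fixed centroids, 3 bandwidth channels), and an attention-gated CNN
whose two soft masks are sigmoids of block-averaged intensity and whose
gradient carries the full product rule through the gate. Fitting trains
only the linear head, with a deterministic multinomial logistic
regression (C = 10); this keeps training reproducible to the bit. The
fixture capacity (8 channels, moderate regularization) was chosen so
that the trained classifier reliably reaches high accuracy on the blob
task and its decisions demonstrably depend on the class-defining region
— the premise of the faithfulness sanity check, which compares
ground-truth-mask attributions against random maps by this package's own
exact one-sided Mann–Whitney test (9 vs 9 samples per repetition, K = 10
schedule, 50 seeded repetitions). Under-parameterized fixtures fail that
premise by producing near-chance classifiers whose confidences nothing
can faithfully explain.

## Numerical conventions

- Trilinear resampling uses cell-center coordinate mapping with boundary
  clamping; it preserves constants and commutes with affine intensity
  changes.
- Trapezoidal integration throughout; no higher-order quadrature.
- Exact-distance comparisons (no tolerance) with lowest-index tie-breaks
  wherever ordering matters, so every pipeline stage is deterministic.
- NPZ containers are written uncompressed with a JSON metadata record;
  round-trips are bit-exact.

## Limitations

- No DICOM/NIfTI ingestion, mesh voxelization, or dataset downloaders:
  real-data studies must supply samples and a `ModelAdapter` themselves.
- LIME/SHAP-style surrogate explanations and Grad-CAM variants are out of
  scope.
- The exact permutation test enumerates combinations and is practical
  only for small pooled samples (the auto switch is at pooled n = 12;
  explicit exact mode remains feasible to roughly 10 vs 10).
- Adaptive compactness is unstable on sparse inputs by construction —
  single-sample ratios can be arbitrarily large; the IQR filter is the
  protocol's mitigation, and fixed-threshold compactness is the more
  robust variant.
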