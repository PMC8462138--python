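# Methods

This note documents the models, algorithms and numerical choices behind
chromamesh, the parameters that matter, and what the synthetic-data tests
do and do not demonstrate.

## Coordinate conventions

All geometry uses raster coordinates: origin at the top-left pixel center,
x = column, y = row, 0-based, y down. TPS-dialect landmark files use a
bottom-left origin with y up; the conversion `y_int = (H − 1) − y_tps` is
applied once at the I/O boundary and is an involution, so read/write round
trips are exact. SCALE records are stored as pixels per centimetre (the
dialect itself does not say which way; we fix and document one reading).
Landmark files list traditional landmarks first and then semilandmarks,
which is not the outline's ring order; the ring order is carried by a
separate perimeter-map file consumed by the template builder.

Images are normalized by their maximum code value (255 or 65,535) to
[0, 1]. No gamma decoding or color-space conversion is applied: values are
analyzed in the encoded (sRGB) scale in which the camera pipeline delivers
them, and calibration (below) is defined on that same scale.

## Procrustes superimposition and sliding semilandmarks

Configurations are centered, scaled to unit centroid size, and rotated to
the running consensus by proper rotations only (det = +1, via SVD with sign
correction); a mirrored specimen is never reflected, it simply fits worse.
Iteration stops when the consensus moves less than `tol` (default 1e-8)
between passes; exceeding `max_iter` (default 100) raises a convergence
error. Collinear or duplicated landmark configurations are rejected with
the specimen named.

Semilandmarks slide along the chord between their two curve neighbors.
For one configuration Y with bending-energy matrix B (built from the
consensus anchors; the k × k upper-left block of the inverse TPS system
matrix), the slide amounts t minimize the quadratic
`trace((Y + Σ tᵢ eᵢ uᵢᵀ)ᵀ B (Y + Σ tᵢ eᵢ uᵢᵀ))`, a PSD linear system solved
exactly per pass — so bending energy never increases. Semilandmarks with
coincident neighbors are left unslid with a warning.

Sliding along the outline has a nearly energy-neutral direction — the
curve's own reparameterization — so a joint slide+GPA fixed point is
approached only linearly (contraction rate ≈ 0.93 measured on synthetic
outlines) and a coordinate-level 1e-8 criterion would never be met.
Following standard morphometrics practice the relaxation therefore runs a
fixed small number of cycles (`slide_iter`, default 5), each re-sliding
from the measured configurations so slide amounts cannot accumulate, after
which plain GPA iterates to `tol` with the slid semilandmarks held.

The consensus is rescaled to the mean input centroid size and translated
to the canvas center, so consensus, aligned shapes and unwarped images all
share one pixel frame (`frame_dims`, normally the common input image
dimensions). The overall consensus of several population consensuses is a
fresh GPA of the consensuses themselves, weighting each population equally
regardless of its sample size; population consensuses are re-normalized in
that GPA rather than kept at their original sizes (the alternative —
size-preserving averaging — differs only when population mean sizes
differ, which the equal-weight construction deliberately ignores).

## Thin-plate-spline unwarping

Kernel U(r) = r² log r with U(0) = 0 (the r² log r² convention differs by
a factor absorbed into the weights). The interpolant is exact at anchors
(checked to 1e-8) and reduces to the affine map with zero kernel weights
on affine data. Images are unwarped by backward mapping: a TPS is fitted
from consensus to specimen landmarks, every output pixel samples the
source by bilinear interpolation (order-1 `map_coordinates`), locations
outside the source get a fill color (default black) and a validity mask.
Bilinear order is a deliberate choice — forward splatting leaves holes and
higher orders can overshoot out of [0, 1]. Downstream sampling stays
inside the outline polygon, so fill never reaches the color matrix.

## Sampling template

Round k Delaunay-triangulates the current vertex set (scipy/Qhull),
discards triangles whose centroid falls outside the outline polygon
(shapely point-in-polygon; covers-the-boundary semantics), and appends the
retained centroids to the vertex set. Template membership is the perimeter
ring plus every round's centroids: on a convex b-gon in general position
this gives the exact count law T_k = (b−2)·3^(k−1) and
total = b + (b−2)(3^K − 1)/2 (2,462 for b = 62, K = 4). The prose
description "centroids serve as the template" is reconciled with this
arithmetic by accumulation across rounds plus perimeter inclusion — the
only membership rule consistent with the printed counts. Clipping by
centroid-in-polygon is a no-op on convex outlines (preserving the law) and
handles non-convex outlines safely; coincident centroids (possible under
degenerate symmetry) are deduplicated with a warning. Construction is
fully deterministic.

Sampling circles are integer-offset masks: (dx, dy) belongs to a
diameter-d mask iff √(dx² + dy²) ≤ d/2; diameter 1 is the single center
pixel ("no pixel averaging"). Template points round to the nearest pixel
(half-up); mask pixels falling off the raster are dropped from the mean
rather than zero-filled, since perimeter points may abut image edges.

## Calibration

Additive and per-channel: for each image, correction_c = mean over the
standard's 5 patches of (known_c − measured_c), added to every sampled
value and clamped to [0, 1]. The standard is measured on the original
(pre-warp) image at its own landmark coordinates. Additive correction
exactly inverts an additive cast for interior values; corrections larger
than 0.5 trigger a warning (suspect standard localization). Multiplicative
or affine models are out of scope.

## Population statistics

* **Vector correlation** — Pearson's r between two p-vectors, the cosine
  of the angle between centered vectors.
* **Bootstrap directions** — whole specimens (rows) are resampled with
  replacement within each population, preserving within-fish associations
  of channels and points; a replicate direction is the difference of
  resampled means (descendant − ancestor, i.e. low- minus high-predation).
  Replicate b of one river pairs with replicate b of the other; the CI is
  the percentile interval (2.5/97.5 at the default level; the BCa
  alternative is not implemented). Percentile intervals are only
  trustworthy when the estimator is approximately unbiased; the paired
  construction attenuates correlations by twice the per-direction noise
  share, so coverage experiments must keep the noise-to-signal ratio of
  the population means small (see Testing).
* **Random-vector null** — two B × p i.i.d. standard-normal matrices,
  row-pair correlations; the asymptotic null SD of each r is 1/√(p−1), so
  the null mean is ~0 ± 1/√(B(p−1)).
* **Trace of covariance** — sum of per-variable sample variances (n−1
  denominator), computed without forming the p × p matrix. The permutation
  test reshuffles predation labels over pooled specimens (whole rows,
  group sizes preserved); the statistic defaults to trace(LP) − trace(HP)
  (sign configurable — the source workflow states both orders in
  different places; the two-sided p-value `(1 + #{|perm| ≥ |obs|})/(n+1)`
  is unaffected).
* **REML variance components** — one-way random-intercept model with
  fixed year effects, estimated by profiling the restricted likelihood
  over λ = σ²_pop/σ²_resid. The group structure makes V⁻¹ closed-form
  (per-group shrinkage λ/(1 + λm_g)), and the optimization is a bounded
  scalar search over log λ ∈ [−18, 18] with the λ = 0 boundary always
  considered; estimates truncate at zero. Collinear fixed-effect columns
  (year constant within populations) are dropped by pivoted QR before
  profiling. In balanced designs without fixed effects the estimate
  coincides with the classical ANOVA estimator (verified to 1e-6); it also
  matches statsmodels MixedLM on general designs. `prop_within` is
  σ²_resid/(σ²_pop + σ²_resid), defined as 1 when both components are 0.
* **DAPC** — centering, PCA (SVD, no per-variable scaling since all
  channels share the [0, 1] scale), then linear discriminant analysis on
  the scores; at most (groups − 1) axes; per-axis share of the
  discriminant eigenvalue total reported. `n_pcs` must not exceed
  min(n − 1, p). When within-group variance is exactly zero (point-mass
  groups) the discriminant subspace degenerates to the span of the class
  means and assignment falls back to nearest-mean — the generalized
  eigenproblem is undefined there. Cross-validation uses stratified
  80/20 splits (the same splits at every grid value), reports the mean
  validation assignment success and RMSE = √(mean (1 − success)²) over
  replicates — RMSE over replicate successes, not membership
  probabilities, which is one of two defensible readings of the upstream
  convention.

## Synthetic studies

The generator emulates the study design the statistics assume: several
populations of a few dozen specimens photographed in one of two years,
62 perimeter landmarks (7 traditional, 55 semilandmarks), the 4-round /
diameter-1 sampling scheme as the default. Each "fish" is an elliptical
body with population-specific spot and body colors; spots are drawn in the
specimen's jittered shape frame (mapped through a TPS from the reference
outline), so unwarping restores spatial homology. A per-image additive
cast (default SD 0.05 per channel) is applied to the whole raster
including an embedded 5-patch standard, making additive calibration
exactly identifiable; default within-population color SD is 0.03 and
between-population mean shift 0.08, landmark jitter SD 1.5 px — values
chosen once as plausible for standardized specimen photography. Ground
truth (per-image casts, population mean vectors at the template points,
the reference shape, noise parameters) is written as JSON.

Not modeled: specularity/iridescence, sensor noise, chromatic aberration,
non-additive illumination. Tests passing on these fixtures demonstrate the
pipeline's arithmetic and statistical calibration, not robustness to real
photographic artifacts.

## Testing scales and numerical tolerances

The suite runs the statistical calibration experiments at reduced sizes
chosen to estimate each property precisely while keeping the whole suite
around a minute: permutation type-I error over 500 null data sets at
p = 300 with 199 permutations each (p-value granularity 1/200 is ample at
α = 0.05; the exact attainable rate is 0.045), KS uniformity on the same
500 p-values; bootstrap CI coverage over 200 repeats at p = 300, B = 500,
n = 30 per population with population-mean noise SD 0.1 against direction
magnitude 10 — the low noise-to-signal regime in which percentile
intervals are valid (coverage ≈ 0.92 there; heavier noise pushes the
double-attenuation bias past the interval width and coverage collapses,
which is a property of paired-bootstrap percentile CIs, not of the
implementation). Direction-vector recovery scores the pipeline against
ground truth with the generator's reference shape injected as the
consensus: the truth is defined at specific template points, and even
sub-pixel template displacement at sharp spot edges (a GPA consensus
differs from the reference by ~0.5 px) otherwise dominates the
comparison. GPA correctness is established separately by its invariance
properties.

Geometric assertions use 1e-6–1e-8 tolerances (TPS anchor exactness 1e-8,
GPA similarity-invariance 1e-6); 8-bit image round trips are asserted to
the 1/255 quantization bound, and cast recovery through PNG files to half
a code value.

## Known limitations

2-D landmarks only; no constrained Delaunay (outline edges are not forced
into the triangulation — centroid clipping stands in for it); no raw
camera format decoding, EXIF, or color-space conversion; additive-only
calibration; no receiver visual modeling or spatial autocorrelation
statistics. The DAPC does not infer the number of clusters.
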