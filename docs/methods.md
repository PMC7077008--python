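# Methods

This note documents the models, conventions and numerical choices
behind `glandrisk`, in the order the pipeline runs them.

## Coordinate and orientation conventions

All modules share one frame: 0-based `(x, y) = (column, row)` pixel
coordinates with pixel centers at integer positions. Polygons are
implicitly closed vertex lists in pixel units; a pixel belongs to a
rasterized polygon iff its center lies inside (even-odd rule, strict
containment). Gland orientation is *axial*: the undirected angle of
the principal axis of the mask's second central moments, in degrees on
[0°, 180°), measured from +x toward +y. When the two moment
eigenvalues differ by less than 1% the gland is flagged degenerate and
its angle set to 0 by convention — a disc has no meaningful
orientation, and propagating an arbitrary angle would inject noise
into the co-occurrence statistics.

## Synthetic tissue generator

The generator emulates the features of TMA cores that the pipeline
measures, not their photorealistic appearance.

* **Layout.** Each gland is an ellipse with semi-axes `a = r₀√AR`,
  `b = r₀/√AR` (`r₀` log-jittered around `mean_radius` = 14 px,
  mean axis ratio AR = 2) and a radial perturbation
  `r(φ) = r₀(φ)·(1 + Σ_{h=2..4} c_h cos(hφ + ψ_h))` whose total
  amplitude is bounded by `shape_noise` (default 0.10); polygons stay
  simple for `shape_noise ≤ 0.3`. Glands are placed by dart throwing
  with a circumscribed-radius clearance test (guaranteeing disjoint
  masks) in a 512 px field, 40 glands by default; packing failure
  after 200 retries per gland raises an error rather than silently
  under-filling.
* **Orientations.** Axial angles are sampled with the doubled-angle
  trick: φ ~ von Mises(2μ, κ) on the full circle, θ = (φ mod 360°)/2.
  κ = 0 is isotropic (maximal disorder); κ = 20 is strongly aligned.
* **Rendering.** Pseudo-H&E: pink stroma (235, 185, 205), purple
  epithelial ring (150, 110, 170), near-white lumen (250, 246, 250)
  with σ = 3 Gaussian noise. The lumen is the gland mask eroded by a
  Euclidean distance transform at depth 5 px, so the epithelial ring
  has uniform Euclidean width. By construction the lumen is the
  brightest of the three tissue classes — the property the segmenter
  keys on, and the property real colonic glands exhibit in H&E.
* **Outcomes.** Recurrence ~ Bernoulli(logistic(intercept +
  β·d(κ))) with disorder score d(κ) = 1/(1+κ); survival time ~
  Exponential(λ₀ · HR^recurrence) censored administratively at
  `censor_time` months. Defaults (β = 30, intercept = −10, λ₀ = 0.004
  /month, HR = 9.65, censoring at 96 months) give a strong, nearly
  deterministic disorder→recurrence linkage with a realistic ~8-year
  follow-up window; β = 0 with intercept 0 recovers the documented
  null (recurrence rate ½, no survival contrast at HR = 1).

What the generator does **not** emulate: nuclei, stain variation,
tissue folds, mixed tumor/stroma compartments, lumen debris, or
spatially correlated gland populations. Passing the synthetic
recovery benchmarks therefore demonstrates that the pipeline's
machinery (segmentation → features → selection → classifier →
survival) recovers a known architectural signal; it does not certify
performance on clinical slides.

## Gland segmentation

A deterministic classical stand-in for learned gland segmenters
(imported masks/contours are first-class inputs for real data):

1. Rec. 601 luminance; images whose luminance range is below 30 grey
   levels are returned empty (pure stroma/noise).
2. Three-class multi-Otsu thresholding; lumen seeds are pixels at or
   above `luminance_threshold ×` the *upper* threshold. A 3-class
   split is used because an H&E gland field is trimodal (epithelium <
   stroma < lumen); a plain 2-class Otsu lands between epithelium and
   stroma and would flood the lumen mask.
3. Seeds smaller than 20 px are dropped; remaining seeds are labeled
   in decreasing-area order (ties by centroid row, then column) for
   deterministic output.
4. Each seed grows outward by `ring_dilation` px with nearest-seed
   assignment (`expand_labels`), which is exactly a distance-transform
   watershed where two glands touch. `ring_dilation` should match the
   tissue's epithelial thickness; the default 5 px matches the
   renderer's ring. Holes are filled and components below
   `min_gland_area` = 200 px² removed.
5. Boundaries are traced at the 0.5 iso-contour, lightly decimated,
   and validated simple.

The glandular area fraction (union of gland masks over an explicit
tissue mask) feeds the two-tier manual grade: **low** grade iff at
least 50% of the tissue is gland-forming. The tissue denominator must
be supplied (whole image by default) because tumor delineation is out
of scope.

## Morphometry

* **Circularity** `4πA/P²` uses the mask area and the polygon
  perimeter; discretization keeps it within ±0.02 of the analytic
  value for smooth shapes of the sizes the generator produces.
* **Solidity** is polygon area over convex-hull area; eccentricity
  and minor/major **axis ratio** come from the moment eigenvalues.
* **Fractal dimension** is box counting on the rasterized boundary:
  occupied boxes N(s) for s ∈ {2, 4, 8, 16, 32, 64}, grid anchored at
  the bounding-box corner (no offset averaging, for determinism), FD
  = least-squares slope of log N vs log(1/s). Every boundary is first
  rescaled uniformly to a 512 px span. This normalization makes the
  estimate scale-invariant by construction and ensures the fixed box
  sizes probe the same relative scale range for every gland; without
  it, boxes below a curve's inner feature scale measure the smooth
  (dimension-1) regime and bias the slope low. Reference values with
  this estimator: straight segment 0.97, circle 1.01, 4-iteration
  Koch curve 1.260 (closed form log4/log3 ≈ 1.262).
* **Boundary Fourier harmonics**: the closed boundary is arc-length
  resampled to 128 points anchored at the lexicographically smallest
  vertex (making the spectrum exactly invariant to vertex-list
  rotation), transformed as x + iy, and harmonic k reported as
  √(|Z_k|² + |Z_{−k}|²) normalized by harmonic 1.
* **Local statistics** (mean/SD/entropy/energy) are computed over
  each gland's neighborhood — itself plus its k-nearest-neighbor graph
  neighbors. Entropy/energy bin values into `nbins` = 10 equal bins on
  the image-wide observed min–max range (bits; 0·log 0 = 0). A spread
  below 10⁻⁹ relative is treated as constant (entropy 0, energy 1):
  float-rounding jitter across identical glands must not register as
  heterogeneity. The bin count is recorded in the feature manifest.

## Orientation co-occurrence ("tensor") features

Neighborhoods come from a union-symmetrized k-nearest-neighbor graph
on gland centroids (k = 5, capped at n−1). For each gland, every edge
whose endpoints both lie within `radius_hops` = 1 of it contributes
symmetrically to a B×B joint distribution of quantized orientations
(B = 18 bins of 10°; bin = ⌊θ/(180/B)⌋). An isolated gland yields a
flagged uniform matrix rather than NaNs, so sparse cores degrade
gracefully. None of B, k, or the hop radius is dictated by the
application; the defaults follow common practice in orientation-
disorder pathology features and are config-exposed and recorded in
the manifest.

Contrast measures use the circular bin distance
d(i, j) = min(|i−j|, B−|i−j|) — orientation is periodic, and a linear
distance would make 5° and 175° maximally distant. With
q(d) = Σ_{d(i,j)=d} p(i,j): contrast average Σ d·q, contrast energy
Σ d²·q, contrast variance Σ (d−μ_d)²·q. Entropy, energy, information
measures IMC1/IMC2, correlation and marginal statistics follow the
standard grey-level co-occurrence definitions (IMC1 ≤ 0, equal to 0
exactly at independence; 0·log 0 = 0 and 0-entropy marginals map to 0
by convention). Image-level features are the mean and SD of each
measure across glands.

Two documented limits of these statistics: (i) measures that are
moments of the *linear* bin index (correlation, marginal average and
variance) are not invariant under a cyclic shift of bins — only the
circular-distance and permutation-invariant measures are, and the
invariance tests assert exactly that subset; (ii) the features are
intentionally density-sensitive, so near-duplicating every gland
changes them (each gland's nearest neighbor becomes its aligned twin)
— they are statistics of the neighbor structure, not of the gland
multiset.

## Feature catalog

The default catalog is frozen at 386 named features: 4 aggregations ×
18 descriptors (72), plus 4 aggregations × 18 descriptors × 4 local
statistics (288), plus mean/SD of 13 tensor measures (26). Names are
compositional (`<agg>_<descriptor>[_<stat>]`, `mean_tensor_<m>`,
`sd_tensor_<m>`), so the five features the locked classifier is known
by — `mean_tensor_info_measure1`, `mean_tensor_contrast_average`,
`mean_circularity_entropy`, `mean_tensor_contrast_energy`,
`sd_fractal_dimension_energy` — exist by construction.
"Mean circularity entropy" is read as the image mean of per-gland
neighborhood circularity entropy, and "SD energy of fractal
dimension" as the image SD of per-gland neighborhood FD energy: the
`{aggregation}-{descriptor}-{local statistic}` composition consistent
with their published descriptions as local-homogeneity measures.
Extraction is pure and gland-order invariant; an empty gland set
yields a zero vector with a warning flag. The manifest
(`feature_manifest`) records every feature's family and parameters in
extraction order.

## Feature selection and classifier

* **Discretization**: three levels per feature at μ ± σ (population
  SD); constant columns map to the middle level. Simple, monotone and
  reproducible; the bin edges are returned so validation data can be
  binned identically.
* **mRMR** (MID/difference scheme): first pick maximizes I(f; y);
  subsequent picks maximize I(f; y) − (1/|S|)Σ_{s∈S} I(f; s), with
  plug-in mutual information in bits and ties broken by column order.
  The greedy step is verified against exhaustive per-step search in
  the test suite. m = 5 by default.
* **Candidates**: linear SVM (C = 1, features standardized by
  training-fold statistics), random forest (500 trees, seeded) and
  linear discriminant analysis, all with class-weighted losses —
  recurrence cohorts run ~20% positive and an unweighted classifier
  collapses to all-negative. Stratified five-fold cross-validation
  with seeded shuffling records per-fold held-out accuracy; the final
  model is refit on all rows.
* **Lock-down** picks the highest mean CV accuracy (exact ties prefer
  SVM, then RF, then LDA) and freezes the model; prediction requires
  a locked model and binds features by name. Locked models serialize
  to plain JSON (scaler statistics + linear coefficients, or a full
  tree dump) and reload into self-contained predictors, so a locked
  classifier is auditable and independent of the training session.

## Survival and association statistics

Kaplan–Meier, the two-group log-rank test and Cox proportional
hazards are computed with lifelines. Cox uses Efron tie handling
(less biased than Breslow; switchable), Newton iterations at 1e−12
precision, and Wald 95% intervals exp(β ± 1.96 se); non-convergence
(typically monotone likelihood under complete separation) is reported
per covariate as `converged=False` rather than raised. The
implementation is cross-checked in the tests against direct numerical
maximization of the hand-written partial likelihood. The multivariate
recipe mirrors the usual clinical-table structure: covariates with
univariate p < 0.05 enter the joint model (configurable). Chi-square
association is Pearson's statistic without continuity correction,
1 d.f.; Cohen's kappa uses marginal-product expected agreement with
the pₑ = 1 convention (κ = 1 iff observed agreement is also perfect,
else 0). Biomarker cut-offs: Ki67 labeling index positive at ≥ 14%,
serum CEA elevated above 5 ng/ml. All p-values are two-sided with
significance at 0.05.

## Pipeline, determinism, problem sizes

`run_pipeline` executes load → extract (imported contours preferred,
else segmentation) → mRMR + CV training → lock → predict → survival,
writing features.csv, the feature manifest, model.json, risk.csv,
report.json and a run manifest with SHA-256 hashes of every output,
the seed and a config hash. Outputs are pure functions of (inputs,
config): a rerun reproduces byte-identical files.

The recovery benchmarks in the test suite and acceptance script use
ordered (κ = 20) vs disordered (κ = 0.5) cohorts of 100 + 100 cores
with 40 glands per core for the end-to-end run, 10 rendered fields
for segmentation recovery, and n = 250–1000 with 20–100 replicates
for the survival simulations — sizes chosen so the full suite
completes comfortably on a single CPU while keeping binomial/Monte
Carlo error well inside the asserted tolerances.

## Known limitations

* The classical segmenter assumes lumen-bearing glands on paler
  stroma; solid or cribriform growth patterns need imported
  segmentations.
* Physical pixel size is optional metadata and never required: all
  descriptors are either dimensionless or in pixel units, so
  cross-cohort comparability assumes comparable magnification.
* The feature catalog reproduces every published feature *family* and
  the five classifier features by name, but the original 797-column
  inventory is not public; column-for-column parity is out of reach
  and not attempted.
* Texture of the raster interior (grey-level co-occurrence of pixels)
  and nuclear-level morphometry are out of scope.
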