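# Methods

This note documents the models and procedures implemented in `hqcolony`,
the defaults chosen where the problem left the design open, and the limits
of what the synthetic experiments demonstrate.

## The Helstrom quantum classifier

### Model

Binary classification is cast as discrimination between two quantum
states. A feature vector **x** ∈ ℝⁿ becomes a pure state (rank-1 density
pattern) through one of two encodings:

- **Stereographic**: the inverse stereographic projection
  a = (2x₁, …, 2xₙ, ‖x‖² − 1) / (‖x‖² + 1) maps ℝⁿ onto the unit
  n-sphere; ρ_x = aaᵀ. Geometry-preserving; the vector's norm is folded
  into the sphere position.
- **Amplitude**: a = (x₁, …, xₙ, 1) / √(‖x‖² + 1); ρ_x = aaᵀ. The
  appended constant keeps the norm recoverable from the state (the
  round-trip x = a₁..ₙ/aₙ₊₁ is exact), at the price of an
  encoding-dependent scale.

Neither encoding needs complex amplitudes; all matrices here are real
symmetric. Taking m tensor copies ρ_x^⊗m (side (n+1)^m) embeds the data in
a larger space where the two classes can only become easier to tell apart:
discarding copies is a completely positive trace-preserving map, under
which the trace distance between the class centroids is non-increasing, so
the Helstrom bound is non-decreasing in m. This monotonicity is asserted by
test on 100 random two-class datasets.

Each class is summarised by its **quantum centroid** — the arithmetic mean
of its encoded patterns, a mixed state — with weight ½/½ (*equiprobable*)
or proportional to class cardinality (*weighted*). The Helstrom observable
Λ = w₊ρ₊ − w₋ρ₋ is eigendecomposed; P₊ collects the eigenvectors with
eigenvalue > 10⁻¹², P₋ = I − P₊, so the two projectors always resolve the
identity and per-sample scores tr(P₊ρ) and tr(P₋ρ) sum to exactly 1.
Zero-eigenvalue directions deliberately fall to P₋: ties are then handled
deterministically and a score of exactly ½ predicts the background class
(the conservative choice toward the majority class). The **Helstrom
bound** w₊tr(P₊ρ₊) + w₋tr(P₋ρ₋) = ½(1 + ‖Λ‖₁) — the optimal
discrimination probability — is stored on the fitted model and checked
against the closed form in the tests.

### Hyperparameters

| parameter | values searched | default | role |
|---|---|---|---|
| `rescale_factor` | {0.5, 1, 1.5, 2} | 1.0 | scales features before encoding; moves points on the hypersphere |
| `encoding` | stereographic, amplitude | amplitude | feature → state map |
| `n_copies` | 1–4 (3-channel sets), 1–5 (scalar) | 1 | tensor copies; cost O(nᵐ) |
| `class_weighting` | equiprobable, weighted | equiprobable | centroid weights |

The density-pattern side is capped at 4096 (configurable), which covers the
largest searched configuration (n = 3, m = 4 → side 256; n = 1, m = 6 →
side 64) with ample headroom; exceeding the cap raises a resource error
naming the computed side.

### Numerical choices

All arithmetic is double precision. Matrices are symmetrized before
`eigh`. Fitting never materialises per-sample patterns: the rows a^⊗m are
built by repeated Kronecker products of the amplitude vector and the
centroid is AᵀA/N, which is algebraically identical to averaging outer
products (the brute-force oracle in the tests does it the slow way and
agrees to 10⁻⁸ in scores, exactly in labels). Standardization statistics
(mean, population SD) are captured at fit time and re-applied at
prediction time; this is leakage-safe when the estimator is used inside
cross-validation. The whole-table standardization mode (standardize the
sampled table once, then split) is also available via
`dataset.standardize`, and is what `experiment.prepare_tables` does —
standardization is then applied before the estimator, whose internal
re-standardization of already-standardized folds is near-idempotent.
Rescaling is applied after standardization, inside the estimator.

## Texture features

GLCM descriptors use a 5×5 sliding window, L = 256 gray bins, a single
displacement (0, 1) with non-symmetric accumulation — the defaults of the
common MATLAB implementation of these descriptors; offset and window are
configurable. The gray source is the ITU-R 601 luminance of the RGB image,
rebinned over the data range (which makes the maps invariant to a constant
intensity shift). Borders are replicate-padded so every map keeps the
image shape.

Formulas, for normalized GLCM p(i, j): contrast Σ(i−j)²p, correlation
Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ), energy Σp², homogeneity Σp/(1+|i−j|). Note that
scikit-image's "homogeneity" squares the level difference and its
"energy" is √ASM; the test suite reconciles conventions when
cross-checking against it. A window with zero marginal variance has
undefined correlation; 0 is substituted with a single warning per image so
downstream standardization never sees NaNs.

The sliding maps are computed by vectorized pair enumeration (each window
holds only (ω−|dr|)(ω−|dc|) = 20 pairs), not by building a 256×256 matrix
per pixel; equality with explicit per-window GLCM evaluation is asserted
exactly in the tests. The entropy map is the Shannon entropy (bits) of the
25-pixel window histogram, in [0, log₂256].

## Ground truth

Reference masks are produced from the entropy map by spatial Fuzzy C-Means
with c = 2, fuzzifier 2, the membership-weighting correction
u′ᵢⱼ ∝ uᵢⱼᵖ·hᵢⱼᵠ (h = 5×5 neighbourhood sum of memberships, p = q = 1),
tolerance 10⁻⁵, ≤ 100 iterations, centroids initialised at the 25th/75th
percentiles (deterministic; the `seed` argument is reserved for randomised
initialisation). The higher-entropy cluster is the colony class. With
q = 0 the update reduces to plain FCM, verified against an independent
reference implementation. Post-processing applies a disk-opening (radius
1) and removes 8-connected components below 50 px — a pixel-area proxy for
the ≥ 50-cell colony rule; there is no universal px-per-cell conversion,
so `min_area` is exposed. Components of exactly 50 px are kept.

## Pixel tables and pre-processing

Column order is fixed: `x, y, features…, label` (x = column, y = row,
0-based, row-major). The chain is: per-feature affine normalization to
[1, 255] (per table, using table extrema); uniform sampling without
replacement of round-half-away(fraction·n) rows (0.002·90601 → 181);
z-scoring with the population SD; a label-stratified split with overall
development size round-half-away(0.8·n) (181 → 145 + 36) and per-class
counts by largest remainder. Sampling is unstratified (plain random
sampling); the split is stratified because at n = 181 an unstratified
split can produce a single-class side, which no classifier can fit.

## Evaluation protocol

Balanced accuracy ½(TPR + TNR), AUROC (trapezoidal via scikit-learn;
equal to the Mann–Whitney rank statistic, asserted in tests), Jaccard
TP/(TP+FP+FN) and Dice = 2J/(1+J). Grid search enumerates combinations in
the documented order (rescale, encoding, copies, weighting, each
ascending) over stratified 5-fold CV with a fixed shuffling seed; ties go
to the first combination. Classes with fewer than 5 members in the
development set cannot be stratified into 5 folds and raise an error (the
experiment harness records such runs as skipped). The copies-increment
protocol refits the winner with one extra copy, all else fixed, and
reports both test scores. The comparison harness maps the 18 named
conventional classifiers to scikit-learn estimators with small
conventional tuning grids fixed in `default_roster` — these grids are a
design choice of this package, so baseline comparisons are qualitative;
three of the 18 (Nearest Centroid, Passive Aggressive, Perceptron) expose
no probability-like score and are excluded when the objective is AUROC,
leaving 15.

## Synthetic wells

The generator emulates scanned crystal-violet-stained 6-well-plate crops
(default 301×301 px): a pale plate background with faint Gaussian scanner
noise (SD 1.5 gray levels), violet colonies rendered as smoothstep
radial-falloff blobs (edge width ∝ 1.05 − compactness) with
multiplicative speckle (SD 0.12 + 0.30·(1 − compactness)) modelling the
granularity of densely packed stained cells, blended by a contrast factor
in (0, 1]. Colony placement retries 200 times for non-overlap, then allows
overlap with a warning (real colonies merge). Geometry and noise use two
independent sub-streams of the master seed, so the mask — a threshold of
the noise-free signal at half its peak — depends only on geometry.

Four regimes span the difficulty axis observed across cell lines:
*compact* (radius ~16 px, contrast 0.75–0.95, compactness 0.85–0.95, the
easy high-contrast case), *evanescent* (large diffuse blobs, contrast
0.12–0.28, compactness 0.20–0.40, the faint hard case), *large-merging*
and *small-sparse* in between. Colony coverage lands around 4–15 % of the
well so that a 181-pixel sample retains enough minority pixels to
stratify 5 folds. A fixed probe (logistic regression on sampled RGB
pixels) confirms the compact regime is strictly more separable than the
evanescent one.

What the generator does **not** model: scanner vignetting and artifacts,
well-rim shading, plate reflections, inter-well bleed, non-Gaussian stain
blotches, and any real cell-line morphology. Passing end-to-end tests
therefore demonstrates the pipeline's internal correctness and its
qualitative easy/hard ordering — not performance on real well plates.

## Problem sizes in tests and the acceptance script

The end-to-end checks use 10 wells per regime with the homogeneity
feature and the full 80-combination grid (about a minute per regime on
one CPU); the brute-force classifier equivalence uses 20 datasets of ≤ 40
samples, ≤ 2 features, ≤ 3 copies; monotonicity uses 100 datasets. These
sizes were chosen to keep the whole suite fast while exercising every
code path at the dimensions the hyperparameter grids actually reach.

## Known limitations

- The sFCM parameterisation (p = q = 1, 5×5 neighbourhood) is a
  conventional choice, not a replication of any specific published
  parameter set; the exact morphological post-processing used to curate
  real ground truth is likewise under-determined, so defaults are
  documented rather than asserted as canonical.
- Per-well scores at a 181-pixel sample are noisy (a single misclassified
  test pixel can move balanced accuracy by several points); conclusions
  should be drawn from per-regime aggregates.
- `compare_classifiers` runs a full grid search per roster entry per
  dataset; with the default roster it is minutes per dataset and intended
  for batch use, not interactive calls.
- The multi-class case and complex-amplitude encodings are out of scope.
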