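# Methods

## Imaging model and projection

The pixel substrate is an unsigned-integer RGB z-stack `(slice, row, col,
channel)` at 8- or 16-bit depth. Coordinates are 0-based `(row, col)` with
pixel-centre addressing; pixel values stay in native integer units until
feature extraction. Stacks are collapsed by per-pixel, per-channel
maximum-intensity projection. The maximum (rather than mean or focus
stacking) is the natural operator for sparse bright spots on a dark
background: each particle is in focus in one slice, and the maximum retains
its peak brightness wherever it focused, while averaging would dilute it by
the slice count. Projection is idempotent, permutation-invariant over
slices, and dominates every slice pointwise; the test suite asserts all
three.

## Spot detection

Detection operates on the luminance, the per-pixel mean of R, G and B, so
no colour class is privileged at this stage. The steps:

1. **Local background subtraction.** A median filter of window
   `background_window_px` (default 15 px) estimates the background:
   pedestal, diffuse membrane-scatter clutter, and the raised floor that
   maximum projection of noise produces. The window dwarfs a
   diffraction-limited spot (σ ≈ 1.5 px), so spots do not bias their own
   baseline, while structures broader than the window's scale are removed.
2. **Smoothing.** Gaussian smoothing with `smoothing_sigma_px` (default
   1.0) suppresses single-pixel noise; matched-filter-style, roughly the
   spot scale.
3. **Candidate maxima.** Pixels that equal the 3×3 maximum filter. A flat
   plateau keeps all of its pixels as candidates.
4. **Threshold.** A candidate must exceed
   `max(threshold_rel × robust_max, noise_floor_k × σ̂)`, with
   `robust_max` the 99.9th percentile of the processed luminance (resistant
   to isolated hot pixels) and `σ̂` the scaled-MAD estimate of the smoothed
   background noise. The relative term (default 0.1) scales with exposure;
   the absolute noise floor (default 7σ̂) is what actually rejects noise
   maxima — across the ≈3·10⁴ local maxima of a smoothed megapixel noise
   field, excursions reach ≈4.5σ, so 7σ leaves comfortable headroom without
   approaching single-particle brightness (≥ 9σ̂ at the default amplitude).
5. **Suppression.** Candidates are visited in order of decreasing
   intensity, ties broken by (row, col); each kept centre claims a
   Chebyshev-ball of radius `min_distance_px − 1` (default `min_distance_px`
   = 5, matching the 5×5 feature ROI). This makes the output deterministic:
   a flat plateau yields its lexicographically smallest pixel, and raising
   the threshold can only remove a suffix of the candidate list, so the
   detection count is monotone in the threshold.

Detections closer than `border_margin_px` (default 2 = ⌊5/2⌋) to the image
edge are excluded so every ROI fits inside the image.

The validation harness matches detections to ground truth greedily by
increasing Euclidean distance, each point used at most once, pairs beyond
the match radius excluded; recall and precision follow. Empty-vs-empty is
defined as recall = precision = 1, empty-vs-nonempty as 0.

## HSV features

Each detection is summarized by the mean H, S and V of the 5×5-pixel ROI
centred on its integer peak (centres are integer maxima; no sub-pixel
interpolation). Pixels are scaled to [0, 1] by `2^bit_depth − 1` before the
hexcone RGB→HSV conversion; achromatic pixels get h = 0, s = 0. Hue is
angular with wrap-around at pure red, so ROI hues are combined by circular
mean (direction of the vector resultant), which equals the arithmetic mean
up to a cubic-in-spread bias whenever the hues cluster away from the wrap
point — the three default class hues (0.60, 0.33, 0.12) all do, so the
choice only matters for yellow-class noise near the origin. A vanishing
resultant falls back to h = 0.

Features are z-scored per column with mean and standard deviation fitted on
the training split only; the fitted normalizer is stored inside the model
so training-time and inference-time scaling cannot drift apart. Constant
columns are clamped to an epsilon scale and map to exactly zero.

## Classifiers

Two supervised classifiers operate on the normalized (h, s, v) vectors:

* **Gaussian naive Bayes** — per-class diagonal Gaussian likelihoods with
  empirical priors; the baseline. On data actually drawn from this family
  its validation error converges to the analytic Bayes error (checked
  against Φ(−1) = 15.87% on the unit-Gaussian means-0/2 benchmark).
* **SVM-RBF** — one-vs-one multiclass with kernel `exp(−γ‖x − x'‖²)`;
  defaults C = 1 and the scale heuristic γ = 1/(3·Var(X)) on the normalized
  features. The defaults are deliberate: the three-class hue geometry is
  nearly separable, so tuning buys little and reproducibility matters more.

Splits are stratified per class and seeded; the split is a partition and is
byte-identical under a fixed seed.

Fitting uses scikit-learn; the fitted parameters (support vectors, dual
coefficients, intercepts, γ; or class means, variances, priors) are
exported to a versioned JSON document together with the class set and
normalizer. Prediction runs from those JSON parameters in plain NumPy —
one-vs-one voting with libsvm's conventions (ties to the lowest class
index; two-class models store the opposite decision sign, handled
explicitly) — and the test suite verifies prediction-for-prediction
agreement with the scikit-learn estimators, so the portable representation
and the reference implementation cross-check each other.

The confusion matrix is row-normalized by true-class support (`c[i, j]` =
fraction of true-class-i validation particles predicted j); zero-support
rows stay all-zero.

## Count error propagation

Counts are exact multisets of the predicted labels. The error bar on class
k sums the expected misclassification flows through the validation
confusion matrix:

    Δn_k = Σ_{i≠k} c[i, k]·n_i  +  n_k·Σ_{j≠k} c[k, j]

with the observed (predicted) counts plugged in for the true abundances —
at inference on a real multiplexed image only predictions exist, and for
the near-diagonal confusion matrices this technique produces the plug-in
bias is second-order. Δn_k is linear in the counts, zero iff no off-
diagonal entry touching class k is active, and — being the *sum* of both
flows rather than their difference — bounds the typical realized count
error: a Monte-Carlo test pushes known labels through the misclassification
channel 1,000 times and requires the bound to hold in ≥ 95% of replicates.
Reports round Δn_k to the nearest integer in the human-readable "n ± Δ"
lines and keep full precision in CSV.

## Synthetic scenes

The generator emulates the structure of darkfield immunolabelling
micrographs, not their optics: no Mie scattering, no cell morphology, no
camera-specific calibration. What matters for the pipeline is the
chromatic cluster structure of the particle classes and the contrast
regime, and those are modelled directly.

* **Colour model.** Per class, independent Gaussians in HSV: hue means
  0.60 / 0.33 / 0.12 (blue, green, yellow) with sd 0.02, saturation
  0.8 ± 0.05, value 0.8 ± 0.1; draws wrap (hue) or clip (s, v). Spread and
  overlap are tunable to build harder benchmarks.
* **Geometry.** Default 512×512 px, 5 slices. Particle centres are
  rejection-sampled at ≥ 10 px minimum separation, ≥ 8 px from the border;
  a retry cap turns pathological requests into an error reporting the
  achievable count.
* **Optics.** Each particle is an isotropic Gaussian spot, σ = 1.5 px in
  focus. Its focal slice is uniform over the stack; away from it the
  amplitude falls off as a Gaussian in slice distance (σ = 1.2 slices) and
  the PSF widens by √(1 + (Δz/1.5)²).
* **Photometry.** 8-bit scenes, background 2 DN, Gaussian read noise
  sd 2 DN, Poisson shot noise at gain 1. Spot amplitude is N(30, 3) DN —
  15× the read noise, the moderate-contrast regime the benchmarks use.
  Diffuse clutter is 15 desaturated Gaussian blobs (σ 4–8 px) at ≤ 1.5 DN
  peak: membrane scatter in darkfield is far dimmer than resonant particle
  scattering, and the local-median background step removes it anyway.
* **Reproducibility.** One seed per scene; placement, colour, clutter and
  noise each consume a fixed sub-stream of it.

Two labelled-data mechanisms exist, and the distinction is load-bearing.
`sample_labelled_features` draws (h, s, v) directly from the colour model —
fast, convenient for classifier unit tests and statistical benchmarks.
`control_scene_features` renders a single-class scene, runs detection and
ROI extraction, and labels every extracted feature with the scene's class —
the mechanism by which single-NP-type control samples label training data
in practice. The two distributions differ substantially: a 5×5 mean over a
σ = 1.5 px spot on a near-black background concentrates ROI value near
0.06 and shifts saturation, whatever the underlying spot colour, while hue
is preserved. A classifier trained on direct draws therefore cannot be
applied to extracted features (the RBF kernel sees every real detection as
a far outlier and degenerates to a constant vote); all end-to-end counting
benchmarks train on control-scene features, matching how the pipeline is
used on real data. What passing synthetic tests shows is that the
*chromatic* discrimination chain works; they do not certify performance
under aggregation/clustering of particles, spatially varying illumination,
chromatic aberration, or spectral effects absent from the Gaussian-PSF
model.

## Benchmark problem sizes

The reproduction script trains on features from four 1024×1024 control
scenes of 500 particles per class (~2,000 labelled particles per class,
70/30 split) and evaluates single-class scenes of 500 particles, spot
amplitude 15× read noise — a desk-scale setting chosen so the entire
benchmark reruns in a couple of minutes on one CPU while keeping per-scene
counting statistics comparable to a real field of view. The statistical
property checks (Bayes-error convergence at n = 10,000, the 1,000-replicate
error-bound simulation) use the sizes stated in the tests.

## Known limitations

* No sub-pixel localization or PSF fitting; centres are integer pixels.
* Aggregates/clusters are not split or flagged; closely spaced particles
  merge under the minimum-separation rule.
* The plug-in Δn_k uses predicted counts for the true abundances; under
  heavily non-diagonal confusion this underestimates the flows of the
  rarer classes.
* The synthetic camera model (Poisson gain 1, white Gaussian read noise) is
  generic, not calibrated to any sensor.
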