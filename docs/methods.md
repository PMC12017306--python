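# Methods

This note documents the models, numerical choices and limitations of the
package, module by module.

## Stimuli

All stimuli are generated on a global time grid (no per-segment frame
snapping), with intensities in [0, 1] and background 0.5.  Dense noise is
*exactly* balanced: each pixel's sequence is a seeded shuffle of equal ON
and OFF counts, not a Bernoulli draw — "balanced" is taken literally, and
the exactness is what makes the reverse-correlation design well
conditioned at short durations.  The chirp's segment schedule (2 s
background, 3 s bright step, 3 s gray, 8 s frequency sweep 0.5→8 Hz, 2 s
gray, 8 s contrast ramp at 2 Hz, 2 s gray; 28 s per repeat) is a display
convention fixed as a config constant: only relative response features are
analyzed downstream, so any schedule preserving the step/sweep/ramp
structure is equivalent.  Spot-size order in the color-spot stimulus is a
seeded permutation per block, different across blocks.

## Synthetic ground truth

The recording generator is the forward model the analysis assumes: a
planted DoG spatial profile and unit-peak temporal kernel produce a linear
drive, rectified (`max(0, X·F)`), convolved with a single-exponential
indicator kernel (default τ = 0.35 s, OGB-1-like; glutamate indicators
are faster), shared by all pixels of an ROI, plus independent pixel noise
and an optional slow sinusoidal drift to exercise detrending.  Real
recordings additionally contain correlated noise, z-motion, indicator
saturation and neighboring-structure crosstalk; a green recovery test
therefore establishes correctness of the estimator under its own model
assumptions, not robustness to those artifacts.

Morphologies are random planar trees grown from ~6 primary dendrites and
rescaled so the convex-hull diameter equals a draw from N(400, 25²) µm
(nasal) or N(150, 10²) µm (temporal), matching the reported regional field
sizes.

Eye-view scenes are 395×395 px frames at 5 µm/px: a low-pass-filtered
noise background (σ = 200 µm, ~12% contrast around mid-gray — an arena
floor texture) drifting by a small random walk, and a cricket rendered as
a dark blurred ellipse (45% contrast reduction) whose pixel size follows a
small-angle retinal-magnification mapping (~31 µm of retina per degree; a
2-cm cricket at *d* cm subtends ≈ 710/*d* px).  Distance labels are
therefore monotone with rendered size by construction.  What these scenes
do **not** emulate: real hunt statistics, self-motion blur, occlusions, or
luminance changes between paired clips — paired present/removed clips
share the identical background, as in the reference dataset.

## ROI extraction

Dendritic pixels: SD ≥ 2× the field-mean SD (restricted to the dendrite
mask when one is supplied).  The correlation threshold is the mean of all
pairwise Pearson coefficients among the top-100 dendritic pixels — the
most direct reading of "mean of the resulting cross-correlation
coefficients".  Growth is seeded agglomeration in descending-SD order
(ties by raster order): a pixel joins an ROI when it lies within 3 µm of a
current member and correlates above threshold with that member.  Pixels
outside the top-100 never join.  The procedure is fully deterministic.

## Signal processing

Savitzky–Golay detrending uses a third-order polynomial with a 60-s
window (10 s for the short sine-spot presentation), applied to the
continuous recording before trial segmentation.  Normalization divides by
the SD of the detrended trace, giving exactly unit variance; a
zero-variance trace is an error, not a silent NaN.  The rectified
derivative uses a third-order Butterworth low-pass applied
forward-backward (zero phase, preserving transient timing; cutoff 3 Hz
for Ca²⁺, 5 Hz for glutamate) followed by a central finite difference at
the native rate.

## Receptive-field estimation

The RF is `F = S b` on a tensor-product cubic B-spline basis with clamped,
evenly spaced knots ((10, 12, 9) for Ca²⁺, (10, 16, 12) for glutamate over
x, y, τ).  The loss `mean_t(ċ − y₀ − X·Sb)² + β‖b‖₁` (β = 0.005) is
non-smooth, so "gradient descent" is implemented as proximal gradient
(ISTA) with Nesterov acceleration; the step size is 1/L with L from power
iteration on the design Gram matrix — the promised "short line search at
step 0".  Training runs ≥ 100 and ≤ 2000 steps with patience 5; because
proximal descent decreases monotonically to machine precision, "no
improvement" uses a relative min-delta of 1e-6.  The lowest-loss iterate
is kept.

Two structural choices resolve ambiguities in the printed configuration:

- `rf_dims` is a *rendering* resolution, decoupled from the stimulus
  grid: the regression evaluates the spline basis at the stimulus pixel
  centers and at trace-rate lag samples, while the output RF is rendered
  at any requested resolution (this is why an x-dimension of 45 can
  coexist with a 20-pixel-wide stimulus).
- The lag axis spans a configurable window (default −0.20 to 1.35 s)
  stored ascending, with negative lags acausal; the "main peak" of a
  temporal kernel is its smallest-lag peak.

The SVD decomposition fixes signs so the spatial peak is positive (ON
convention), scales `max|F_t| = 1` and `max|F_s| = max|F|`, and computes
the separability index from the unscaled rank-1 term.  Outline
estimation upsamples `F_s` 5× (bilinear), contours the peak-normalized map
at 0.25/0.30/0.35, and accepts the fit only if at every level one closed
contour covers ≥ 80% of that level's contour-union area (the per-level
reading is forced: across levels, even a perfect Gaussian's 0.35 contour
covers only 76% of its 0.25 contour).  The surround is everything outside
the outline expanded by 20 µm.  The transience index ignores |F_t| peaks
below 20% of the kernel maximum — fitted kernels carry spline ripple that
would otherwise masquerade as response lobes.

## Response metrics and quality

Index windows: Δt_r = Δt_b = 2 s (chirps), 1/0.25 s (sine-spot), 1/1 s
(color spots); the 90th percentile uses linear interpolation.  The
stimulus surround index is computed exactly as printed,
`SI = med[RI_wide] − max(0, med[RI_small])`; under this orientation a
strongly suppressed wide-field response gives a *negative* SI.  Downstream
comparisons are ordinal, and the orientation is documented here so users
can flip the sign consistently.  Quality rules: dendritic ROIs pass with
local-chirp OR global-chirp `QI_SNR ≥ 0.35`; somatic ROIs need
global-chirp AND color-spot `QI ≥ 0.5`.

## Clustering

Features are local+global chirp averages block-averaged over 4 samples
(trailing partial blocks averaged over their actual length) and
concatenated; no additional scaling (traces are already unit-variance).
Ward linkage on Euclidean distances; the dendrogram is cut either at a
distance threshold or at a target count (default 3 — the original absolute
threshold is dataset-scale dependent and was chosen from the dendrogram by
eye).

## Morphology

Hull metrics use the z-projection; dendritic distance is the shortest
path along the arbor (edge-weighted graph) from the nearest node to the
soma.  Field registration clips the time-averaged field to [0, 1] at its
20th/90th percentiles and minimizes MSE + λ·(Euclidean distance to the
expected position) over all xy offsets of each z layer of a blurred
skeleton raster; λ (default 1e-4 per µm) trades template fidelity against
the position prior and is calibrated on synthetic fixtures — the two terms
have different units, so the weight is necessarily free.  The hex-density
profile clips each projected segment exactly against a 16-µm hexagonal
tiling centered on the soma; the radial profile is fitted with
`A·exp(−r²/2·scale²)` truncated at a cutoff searched on an 8-µm grid
(the "truncated-Gaussian-like" form is otherwise unspecified).

## DoG fits and bipolar-cell kernels

The DoG ties center and surround mean and covariance up to a scalar
(> 1) on the covariance; amplitudes have opposite signs.  Fitting is
nonlinear least squares with log/arctanh reparameterization for
positivity, multi-started on the amplitude sign pattern.  Kernels are
built by averaging parameters (not rasterized kernels) of fits with
`QI_DoG ≥ 0.35` per cluster, rasterizing on a 65×65 grid at 5 µm/px, and
normalizing the maximum amplitude to one *after* averaging.

The default stand-in kernels (used when no measured cluster averages are
supplied) have a 20-µm center (single-BC RF centers are ~40–70 µm in
diameter) and a 4×-covariance surround, with surround strength set by the
surround/center *volume ratio*: −0.2 (weak) and −0.85 (strong).  The
volume ratio, not the peak amplitude, is the physically meaningful dial: a
strong-but-suppressive surround nearly cancels the uniform-field response,
whereas a ratio below −1 would invert the RF.

## Encoder

Valid convolution arithmetic: 395 → (395−65)/3+1 = 111 BC units per side.
The printed RGC grids (9 nasal, 19 temporal) are treated as normative and
cannot arise from a 111 grid by valid strided convolution, so the BC grid
is symmetrically cropped to 101 (nasal: kernel 21, stride 10) or
zero-padded to 117 (temporal: kernel 27, stride 5).  The sigmoid is
calibrated in closed form: `d = mean`, `b = ln(29/5)/SD` of the
pre-activation sample (training frames, interior units), giving
`f(mean) = 0.1` and `f(mean+SD) = 0.5` exactly.  Noise (σ = 0.1) is drawn
fresh per unit and frame.  The RGC layer pools the channel-weighted sum of
the two BC populations through one truncated-Gaussian kernel (the "3D
convolution" over two channels with a shared dendritic footprint); mixed
input uses weights (0.5, 0.5) — the measured cluster shares are not part
of the parameterization.  Default pooling scales/cutoffs (temporal 40/85
µm, nasal 95/190 µm) are plausible population means of the hex-density
fits and can be replaced by measured values.

## Decoder

No deep-learning framework is available in the target environment, so the
CNN (five 3×3 conv layers × 3 filters, ReLU, same-padding, L2 1e-3; one
2×2 max-pool; dense-8 ReLU, L2 3e-3; sigmoid unit) is implemented in
numpy with im2col convolutions and hand-written backprop (verified against
numerical gradients).  Adam minimizes binary cross-entropy; inputs are
z-scored with training-set statistics.  Desk-scale defaults: batch 128–512
(reference: 16,384), early-stopping tracking from epoch 20–50 (reference:
200), patience 10 with min-delta 1e-3, best-validation weights restored;
ensembles of 3 members (reference: 10), mean sigmoid output thresholded at
0.5.  With only hundreds of training frames the network can memorize
rather than generalize; the detection experiments therefore use ≥ ~500
training frames.

## Evaluation

Accuracy vs distance uses a logistic penalized-spline GAM (statsmodels
GLMGam, B-spline basis, no random effects); cricket-removed frames
inherit the distance of their paired present counterpart.  Pointwise Wald
intervals on the linear predictor are mapped through the logistic.  With
fewer distinct distances than spline degrees of freedom, the smoothing is
widened with a warning.

At desk scale (120 scene pairs, 4 frames each, 3-member ensembles), the
end-to-end comparison reproduces the qualitative ordering — strong-surround
temporal input best, weak-surround temporal and nasal equivalent and worst
— as an ordinal property with a bootstrap-confirmed strong-vs-weak margin.
Absolute accuracies are far below the reference configuration (which used
~54k real eye-view frames) and are not comparable.

## Known limitations

- The synthetic scene world is far simpler than real hunt footage; the
  encoder comparison is a property test of the mechanism (surround
  suppression isolates small dark objects from smooth background), not a
  reproduction of measured accuracy curves.
- The RF estimator's intercept and edge handling assume the stimulus
  statistics are stationary; trials with motion artifacts are out of
  scope (synthetic data is motion-free).
- GAM-based group comparisons with random effects per cell, stratification
  surfaces, and retinal-coordinate reconstruction are out of scope.
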