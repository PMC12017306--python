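# retidend

Dendritic signal analysis and population encoding models for retinal
ganglion cells.

Sustained ON alpha (sONα) ganglion cells differ systematically across the
retina: nasal cells have large dendritic fields (~400 µm) with weak
surround suppression, temporal cells small fields (~150 µm) with strong
surround suppression — the temporal region views the binocular field where
mice hunt prey.  This package implements, end to end and with synthetic
ground truth, the analysis chain used to characterize such regional
adaptations from two-photon Ca²⁺/glutamate imaging of dendrites, and the
encoder–decoder simulation that asks whether the temporal-retina circuit
configuration actually helps detect a cricket.

## What it computes

**Analysis chain** (for 64×16 px imaging movies at 31.25 Hz):

- **stimuli** — frame-exact generators for binary dense noise (exactly
  balanced per-pixel ON/OFF sequences), global/local chirps, clipped-sine
  spots and colored size-series spots.
- **roi** — SD-image thresholding (≥ 2× field mean), Pearson
  cross-correlation of the top-100 dendritic pixels, and seeded 3-µm
  neighborhood agglomeration above the mean-correlation threshold.
- **signals** — Savitzky–Golay detrending, baseline/variance
  normalization `r_norm = (r − median(r[t<t₀]))/SD[r]`, repeat averaging,
  the repeat-reliability index `QI_SNR = Var_t[⟨C⟩_r]/⟨Var_t[C]⟩_r`, and
  the rectified low-pass derivative `ċ = max(0, d/dt LP(r_norm))`.
- **rf** — spline-based linear-Gaussian receptive fields minimizing
  `mean_t(ċ − y₀ − X·Sb)² + β‖b‖₁` by proximal gradient descent;
  SVD decomposition into `F_t(τ)·F_s(x,y)` with separability index
  `QI_RF`; contour-based center outlines with equivalent-circle diameter;
  surround index `SI_RF = ΣF_s(surround)/Σ|F_s|`; transience index
  `TRi = 2A_pre/(A_pre + A_main)`.
- **metrics** — stimulus-derived surround/transience indices from
  wide-vs-small light-increment responses.
- **cluster** — Ward hierarchical clustering of downsampled chirp
  responses.
- **morpho / dog** — convex-hull field metrics, dendritic path lengths,
  field-to-morphology registration, hexagonal dendrite-density profiles
  with truncated-Gaussian fits, and tied-covariance difference-of-Gaussians
  (DoG) RF fits.

**Encoder–decoder model**: two bipolar-cell populations (weak/strong
surround DoG kernels, 65×65 at 5 µm/px, stride 3), a generalized sigmoid
`f(x) = 3/(1 + 29·e^(−b(x−d)))` calibrated so `f(mean) = 0.1` and
`f(mean+SD) = 0.5`, additive Gaussian noise (σ = 0.1), and a
truncated-Gaussian ganglion-cell pooling layer (temporal: 27×27 stride 5;
nasal: 21×21 stride 10) producing 19×19 or 9×9 population responses.  A
small CNN ensemble (numpy implementation) decodes cricket presence from
single frames; accuracy vs distance is smoothed with a logistic
penalized-spline GAM.

## Worked example

```python
import numpy as np
from retidend import stimuli, synthetic, roi, signals, rf

stim = stimuli.gen_dense_noise(20, 15, pixel_um=30, rate=5, duration=300, seed=0)
rec = synthetic.gen_recording(stim, n_rois=2, noise_sd=0.05, seed=1)
rois = roi.extract_rois(rec.movie, rec.pixel_um)
print(f"extracted {len(rois)} ROIs, {[len(r.pixel_set) for r in rois]} pixels each")

cfg = rf.RFFitConfig(knots=(10, 12, 9), rf_dims=(40, 30, 15), lag_range=(-0.2, 1.35))
design = rf.RFDesign(stim, 31.25, cfg)           # shared across ROIs
for i, r in enumerate(rois):
    gt = rec.rf_truth[rec.roi_truth[r.pixel_set[0]]]
    r_norm = signals.normalize(r.trace_raw, t0=1.0, sampling_rate=31.25)
    c_dot = signals.lowpass_gradient(r_norm, 31.25, f_cutoff=3.0)
    est = rf.SplineRFEstimator(knots=cfg.knots, rf_dims=cfg.rf_dims,
                               lag_range=cfg.lag_range).fit(design, c_dot)
    s = est.summarize()
    print(f"ROI {i}: QI_RF = {est.qi_rf_:.2f}, diameter = {s.diameter:.0f} um "
          f"(planted sigma {np.sqrt(gt.cov_um2[0, 0]):.0f} um), "
          f"SI_RF = {s.si_rf:+.2f}, TRi = {s.tri_noise:.2f}")
```

prints

```
extracted 2 ROIs, [9, 9] pixels each
ROI 0: QI_RF = 0.54, diameter = 270 um (planted sigma 87 um), SI_RF = -0.11, TRi = 0.36
ROI 1: QI_RF = 0.58, diameter = 196 um (planted sigma 66 um), SI_RF = -0.16, TRi = 0.33
```

Both planted ROIs are recovered pixel-exactly; the fitted RF diameters
track the planted Gaussian widths (the 0.25-level contour of a Gaussian of
width σ has diameter ≈ 2σ√(2 ln 4), i.e. ≈ 290 and 220 µm here), the
surround indices are negative as planted (suppressive surround), and the
transience indices are low (the planted temporal kernels are monophasic;
the residual ripple of the spline fit keeps them slightly above zero).

The full encoder–decoder comparison across ganglion-cell variants runs via
`retidend.pipeline.run_detection_experiment`; at desk scale (120 scene
pairs, 3 decoder members) the strong-surround temporal population detects
near crickets best, the weak-surround temporal and nasal populations worst.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
generates synthetic eye-view scenes, runs the encoder's bipolar-cell
linear stage on them, calibrates the generalized sigmoid from the
pre-activation distribution in closed form, and reports the nonlinearity
evaluated at the sample mean and at the mean plus one standard deviation.
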