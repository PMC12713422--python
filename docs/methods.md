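# Methods

This note records the models, numerical choices and known limitations behind
each analysis arm and the synthetic-data generators, at the level of detail a
user would need to judge what a passing test suite does and does not show.

## Thermal area trajectories

A particle's relative silhouette area along the heating ramp is modeled as

    A(T) = 1 + a·exp(−(T − T_swell)² / 2σ_s²) − (1 − f)·expit((T − T_shrink)/w) + shift

with the constant shift chosen so A equals exactly 1 at the ramp start.
The Gaussian bump (amplitude `a`, center `T_swell`, width σ_s = 20 °C) models
the transient swelling some tissue fractions show; the logistic sigmoid
(center `T_shrink`, scale `w`, floor `f`) models pyrolytic shrinkage.  Both
landmarks are directly interpretable: the analytic derivative's minimizer
sits at `T_shrink`, the local maximum near `T_swell`.  Per-fraction presets
place `T_shrink` at 375 °C for all five fractions and give cambium and
branch swelling bumps at 250 °C (amplitudes 0.08 and 0.05); the asymptotic
area floors (0.30–0.55) are plausible placeholders, not calibrated values.
The default ramp is 22→500 °C at 5 °C/min imaged every 30 s (192 frames);
trajectory noise is additive Gaussian with SD 0.02 in relative-area units.

Rendering draws one dark, mildly irregular blob (fixed random Fourier
perturbation of a disk, ≤ 2 % radial amplitude) on a bright field and scales
its linear size by √A, so pixel area tracks the trajectory up to
boundary-pixel rounding; measured round-trip error is < 0.005 relative-area
units for noiseless trajectories at 256×256 px.

## Morphometry

* **Threshold.** IsoData intermeans iteration `t ← (µ_low(t) + µ_high(t))/2`
  from the global mean, stopping when the update is below 0.5 intensity
  levels.  Deterministic; shift-equivariant; scale-equivariant up to the
  stopping tolerance.
* **Segmentation.** Polarity-selected threshold side, 8-connected
  components, minimum area 25 px, internal holes filled (areas are
  silhouette areas).  Frames where nothing survives are flagged, not fatal.
* **Tracking.** Largest component by default; nearest-centroid and
  sum-of-all-particles modes are provided because a field of arranged
  particles can also be measured in aggregate.  Lost particles yield NaN so
  the smoother skips them.
* **Smoothing.** Penalized cubic regression spline (P-spline) of relative
  area on temperature: 20 cubic B-spline basis functions on a clamped
  uniform knot vector, second-order difference penalty, penalty weight by
  GCV over a 12-decade grid.  Smoothing is done against temperature rather
  than time because the ramp is linear, which makes transition temperatures
  first-class.  The 95 % pointwise band is `fit ± 1.96·SD` over 200
  case-resampling bootstrap refits at the GCV-selected penalty; the normal
  form (rather than percentiles) keeps the band centered on, and therefore
  always containing, the full-data fit.  The derivative is the analytic
  spline derivative.
* **Transitions.** Landmarks are read off a 2001-point grid restricted to
  the interior 90 % of the temperature range (5 % trimmed per side) because
  spline fits are least reliable at the boundary.  A swelling peak is
  reported only when the fit exceeds 1 by `swell_margin` (default 0.01).
  With noisy, sparsely sampled series the 0.01 margin occasionally reports a
  small spurious swell in fractions that have none; raising the margin
  trades those false positives against sensitivity to genuine weak swelling.

## Stereometry

The renderer and the reconstruction share one symmetric orthographic
parallax model: a point at height z appears displaced by ±d/2 along the tilt
axis in the two views, with d = 2 z sin(θ/2)/s.  Perspective and
foreshortening terms of real eucentric SEM tilting are omitted on both sides,
so the model pair is self-consistent; absolute accuracy on real micrographs
is untested and absolute roughness values from real instruments are out of
scope.

* **Rendering.** Lambertian shading of the surface normal field multiplied
  by a fine-grained albedo texture (σ = 1.2 px, 40 % contrast) tied to
  surface points — emulating SEM surface texture and giving the matcher
  something to lock onto; cubic-interpolation warps by ±d/2.
* **Matching.** Zero-normalized cross-correlation over an 11 px block for
  integer shifts within ±16 px, parabolic sub-pixel refinement, validity
  threshold 0.5, border blocks rejected.  Two corrections matter at the
  0.1 px level: the raw match at pixel x estimates the disparity of the
  surface point midway along the displacement, so the field is resampled at
  x − d/2 ("recentering"); and a validity-weighted Gaussian post-filter
  (σ = 1.5 px) suppresses matching noise.  Block matching assumes disparity
  is locally constant, so accuracy degrades when the surface correlation
  length approaches the block size; the default synthetic surface
  (correlation length 25 µm at 0.5 µm/px, i.e. 50 px, roughly the tracheid
  scale of softwood) is well inside the valid regime, where the full
  pipeline recovers height fields to ≤ 5 % of Rq.
* **Levelling and parameters.** First-order least-squares plane removal
  (no higher-order form removal), then Rq/Sp/Sv over valid pixels.
* **Droplets.** High-pass by median subtraction (window 41 px, much larger
  than a droplet), local maxima above `min_height` (default 0.05 µm),
  half-maximum footprint growing, equivalent-circle diameters in nm;
  "coated" when footprints cover > 20 % of the valid area.  Droplet analysis
  presumes high-magnification data: at 20–40 nm pixels, sub-500 nm droplets
  stand proud of the nm-scale background, whereas at survey magnification
  they are invisible against µm-scale cell relief — hence the demo study
  carries a separate high-magnification tilt pair per sample.  At high
  droplet densities, merged half-maximum footprints undercount droplets and
  saturate the measured coverage below the true one.

## Raman quantification

* **Baseline.** Asymmetric least squares (smoothness λ = 10⁵, asymmetry
  p = 0.01, 10 iterations): the baseline hugs the underside of the peaks and
  removes the broad fluorescence background.  Narrow peaks lose ≲ 2 % of
  their area to the baseline; a small positive noise-floor offset remains in
  the subtracted spectrum.
* **Normalization.** Division by the mean intensity over the full recorded
  range, removing acquisition-gain differences so replicates pool; species
  scores are consequently homogeneous of degree 0 in overall gain.  A
  unit-vector alternative exists but is not the default.
* **Band integration.** Linear interpolation to a 0.1 cm⁻¹ grid (instrument
  grids of ~1 cm⁻¹ would put only 2–3 samples in a 2 cm⁻¹ window), local
  background as the line between the mean intensities of two 2 cm⁻¹ anchor
  windows at ±8 cm⁻¹, trapezoidal integration over center ± 1 cm⁻¹.
  Negative band values are retained with a flag — flooring them would bias
  replicate averages.  Anchor geometry is per-band overridable; the shipped
  band table is canonical only for the two cellulose bands (380,
  1100 cm⁻¹); the hemicellulose/lignin/resin centers are literature-informed
  placeholders and should be replaced for real instruments.
* **Calibration.** Per-species OLS of reference mass fraction on ambient
  score across anatomical fractions (≥ 3 required), goodness as Pearson r,
  model frozen before application to heated samples; estimate SE propagates
  as |slope|·SE(score).  Estimates below the ambient reference (or zero) are
  the degradation signal and are never clipped.
* **Known bias.** Because every score is divided by the spectrum's own mean
  intensity, a genuine loss of one species inflates the relative scores of
  the others and damps its own apparent loss.  The effect scales with the
  signature bands' share of total spectral intensity; with the realistic
  ~13 % share used in the synthetic study the recovered 40 % cellulose
  reduction reads ~37 %, and composition estimates stay within a few
  hundredths of mass fraction.  Methods that normalize by an internal
  standard would remove this bias but are outside the procedure implemented
  here.

## Synthetic spectra

Signature bands are unit-area Gaussians (σ = 5 cm⁻¹) scaled by composition ×
per-band cross-section (aromatic lignin modes, notably 1600 cm⁻¹, are set
several-fold stronger than carbohydrate modes, as in real wood spectra).
Study spectra add: a fixed composition-independent "matrix continuum" (a
pseudo-random sum of broad Gaussians kept ≥ 25 cm⁻¹ clear of signature
centers, amplitude 1.2× the signature peak scale) standing in for the shared
skeletal/C–H band structure that dominates real lignocellulose spectra; a
cubic fluorescence background several times the peak height; and white
Gaussian noise at 5 % of the common peak scale.  One intensity scale, noise
level and background is used for the whole study — detector noise and
fluorescence are acquisition properties — while gain invariance is exercised
separately in the normalization tests.  What the generators do **not**
emulate: real band shapes and overlaps, shot noise, cosmic rays, instrument
line-shape functions, per-sample fluorescence variability; passing tests
demonstrate the correctness of the procedure, not instrument-grade accuracy.

## Study orchestration

All randomness derives from the single manifest seed through SHA-256-based
sub-seeds, so `demo` + `run` are byte-reproducible.  Arms are independent
and per-sample failures are recorded without aborting the run (replicates
are independent).  Treatment temperatures default to the quench points
{22, 250, 375} °C but are configurable.  The demo study (five fractions ×
three temperatures, 96–192 frame series, 128² surfaces, four spectrum
replicates) runs end-to-end in well under five minutes on one CPU; the
heated compositions apply per-temperature degradation factors (early
cellulose/resin loss at 250 °C; strong cellulose/hemicellulose/resin and
mild lignin loss at 375 °C).

## Problem sizes

Defaults were chosen so a full test run completes in about a minute: 192
frames at 256² for transition recovery (5 replicates), 512² grids for
stereometric recovery, 1501-point spectra with 4 replicates × 5 fractions ×
20 seeds for composition recovery.
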