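# Methods

`qusresp` implements a quantitative-ultrasound (QUS) radiomics pipeline for
predicting breast-tumour response to neoadjuvant chemotherapy from
pre-treatment radiofrequency (RF) ultrasound data, together with a synthetic
RF generator that supplies labelled cohorts with known ground truth.  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic experiments do and do not demonstrate.

## RF synthesis

Frames are produced by a 2-D point-scatterer convolution model, synthesized
per scan line in the frequency domain:

* Scatterer positions are uniform i.i.d. in the imaging plane (Poisson count
  at the medium's `number_density`); amplitudes are constant per medium, the
  idealization of a homogeneous glass-bead phantom.  Each scatterer is
  assigned to its nearest scan line (effective beamwidth = one pitch; no
  elevational or lateral beam profile).
* Each echo is the pulse spectrum × the scatterer's amplitude response
  × two-way frequency-dependent attenuation × the propagation phase at its
  (fractional-sample) depth.  Synthesis in the frequency domain makes the
  depth-dependent attenuation filtering exact.
* The pulse has a Gaussian amplitude spectrum centred on the transducer
  centre frequency.  Band edges are interpreted as the **−20 dB points of
  the two-way power spectrum** (the conventional pulse-echo −20 dB
  bandwidth).  A wider convention (−6 dB) leaves several percent of the echo
  energy outside band ± 1 MHz once the f⁴ backscatter rise tilts the
  spectrum; −20 dB keeps >99% in band, which the band-limitation test
  asserts.
* The per-scatterer amplitude response is the square root of the
  unit-density theoretical backscatter coefficient (below), so the
  ensemble-mean power spectrum of any simulated medium is proportional to
  its theoretical BSC with a medium-independent constant.  The constant —
  and the deliberate unit mismatch of using `number_density` both per-mm²
  (2-D plane) and per-mm³ (analytic BSC) — cancels in reference-phantom
  normalization.  Absolute BSC values are therefore internally consistent,
  not absolutely calibrated.

Two system profiles mirror the acquisition hardware the analysis assumes:
6.5 MHz centre / 3–8 MHz band (0.30 mm pitch) and 6.0 MHz centre /
3.5–8.5 MHz band (0.23 mm pitch), both sampled at 40 MHz with c = 1540 m/s.
The reference phantom is fixed at 0.8 dB/cm/MHz and 1540 m/s.

## Scattering model

The theoretical BSC is the spherical Gaussian form-factor model

    σ(f) = C f⁴ a_eff⁶ n̄ γ₀² F(f, a_eff),   C = π²/(36 c⁴),
    F(f, a_eff) = exp(−0.827 k² (a_eff/2)²),

with `a_eff` the effective scatterer *diameter* (µm), `n̄` the number
density, `γ₀` the fractional impedance contrast, and k the wavenumber.  The
form-factor constant 0.827 is the conventional parameterization of the
Gaussian scatterer; it is held behind a named constant so alternatives
(fluid sphere, Faran) could be swapped in, though they are out of scope.
AAC is reported as 10·log₁₀(n̄γ₀²) with n̄ in mm⁻³; the absolute dB offset is
convention-dependent, and every recovery statement in the tests is relative,
so the convention cancels.

## Spectral chain

* **Windowing.** 2 mm × 2 mm kernels, 94% overlap (0.12 mm step; the axial
  step rounds to 6 samples at 40 MHz, the lateral step to one line).
  Hanning gating per line, periodogram by zero-padded FFT (nfft = 256,
  Δf ≈ 0.156 MHz), averaged across the window's lines.  Window centres must
  lie inside the ROI and the window inside the frame; windows straddling the
  ROI boundary are not excluded beyond the centre rule.
* **Attenuation.** The sample path is layered: 1 dB/cm/MHz for overlying
  breast tissue above the ROI top, the estimated tumour coefficient (ACE)
  below it.  ACE comes from the spectral-difference method: for each in-band
  frequency, the depth-slope of sample-minus-reference log power is
  −2 (α_m − α_r) f dB/cm; per-frequency excesses are averaged over the band.
  The pipeline estimates ACE per scan plane from all ROI (core + margin)
  window rows, weighted by the number of windows per row — the core alone
  gives an estimator ~4× noisier (σ ≈ 0.09 vs 0.02 dB/cm/MHz at desk-scale
  ROI sizes) with downstream bias in the form-factor fit.
* **Normalization.** σ_m(f) = σ_r(f) |S_m|²/|S_r|² exp[4(α_m−α_r)(R+Δz/2)],
  evaluated in dB with the layered path; σ_r(f) is computed analytically
  from the synthetic phantom's own scattering model (self-consistent at desk
  scale).  Reference spectra are depth-resolved means over laterally
  non-overlapping windows of several phantom frames.
* **Linear fit.** MBF/SS/SI from ordinary least squares on the
  attenuation-corrected normalized power spectrum over the system band; the
  MBF reference frequency is the band centre (the nominal centre frequency
  is the plausible alternative; at a fitted line the two differ only through
  SS, and the identity MBF = SI + SS·f_c holds pixelwise by construction).
* **Form-factor fit.** Log-domain least squares over (a_eff, n̄γ₀²); the
  concentration enters as a pure dB offset, so each candidate diameter has a
  closed-form offset and the diameter is found by a 100–120-point log-spaced
  grid search on [1, 300] µm refined by bounded scalar minimization (single
  curves) or parabolic interpolation (vectorized parametric imaging).
  Diameters pinned at a search bound are flagged (`at_bound`); all five
  images share one validity mask (ROI membership), as they are built in a
  single pass.

At desk scale the full-pipeline recovery has a small negative diameter bias
(−5…−10% median at 70 µm): periodogram leakage smooths the already-shallow
form-factor curvature and residual ACE noise tilts the spectrum.  This is
within the 20% / 3 dB acceptance envelope and is documented rather than
calibrated away.

## Texture and texture-derivate

Each parametric image is linearly min–max quantized over its own valid-pixel
range into 16 gray levels (per-image, not cohort-fixed; a constant image
maps to level 1 by convention).  Symmetric, mask-aware GLCMs are built at
distances 1–5 and angles 0°/45°/90°/135° (0° = lateral, 90° = axial — a
documented convention); contrast, correlation, energy and homogeneity are
averaged over the 20 matrices, skipping empty ones (small margin ROIs at
d = 5).  Correlation of a constant region is undefined and returns 0 with a
flag.

Texture-derivate features: a 15 × 15-pixel window slides over the image; at
each centre whose full neighbourhood is valid, the neighbourhood is
quantized over its **local** range (global quantization is available behind
a switch) and the mean distance-1, four-angle GLCM feature becomes the map
pixel.  Centres whose window exits the mask are dropped — padding would
fabricate texture at the tumour rim, the region of interest.  The second
pass applies the full first-pass protocol (distances 1–5, four angles) to
each of the four maps: 16 derivate features per parametric image.  The
15-pixel window is defined in pixels of the parametric-image grid; with the
0.12 mm step it spans ≈1.7 mm physically.

## Features and cohort table

Per region (core; 5-mm margin ring, built by Euclidean distance in mm on the
anisotropic pixel grid): 5 mean values + 20 texture + 80 derivate = 105
features, named `{Region}-{PARAM}[-{MAP}][-{FEATURE}]`.  Ten image-quality
features complete the 220-column table: CMR = mean(core)/std(margin) and
CMCR = [mean(core) − mean(margin)] / (½[std(core) + std(margin)]) per
parametric image.  Per-plane features are averaged across scan planes with
weights proportional to each plane's valid ROI pixel count (area weighting
privileges better-sampled planes and reduces to the plain mean for equal
planes); a feature unavailable on some planes is averaged over the planes
that have it, and any feature still missing after plane averaging (e.g. a
margin too thin for a 15 × 15 window on every plane) is imputed with the
cohort median and logged.

## Classification

Forward sequential feature selection (SFS) with the responder-class F1
score over deterministic 3-fold stratified inner validation; exactly four
features are selected (≈1/10 of the observations per class, the cap that
limits overfitting), ties breaking to the lowest column index.  Leave-one-
out cross-validation is the outer loop; by default SFS, z-score
standardization and hyperparameter choice are all refit inside each
training fold (nested, leakage-safe).  A non-nested mode (one global SFS
before the loop) emulates the simpler protocol common in radiomics reports;
both are exposed.  Classifiers: LDA (shared-covariance Gaussian posterior;
ridge-shrinkage refit on singular covariance), KNN (k ∈ {1, 3, 5} by inner
F1; Euclidean; score = vote fraction) and RBF-SVM (C ∈ 2⁻⁵…2¹⁵,
γ ∈ 2⁻¹⁵…2³ in powers of 4, by inner F1).  During SFS the family runs with
default hyperparameters (k = 5; C = 1, γ = 'scale'); k or (C, γ) are then
tuned on the selected features — tuning inside every SFS candidate
evaluation would multiply the fit count ~100-fold with no methodological
gain at these sample sizes.  The inner selection/tuning loop uses
closed-form LDA and vectorized KNN equivalents for speed; final per-fold
fits use scikit-learn estimators.  ROC metrics use the classifier's native
threshold for the confusion counts and the pooled continuous scores
(decision-function values or vote fractions) for the AUC (rank formulation,
half credit for ties).

## Synthetic cohorts — what they do and do not show

`CohortConfig` defaults mirror the study conditions the pipeline targets:
74 patients (42 responders — the Methods/Table-1 count; the abstract's 78 is
noted as a discrepancy and not used), two systems mixed 51:23, core plus
5-mm margin, three scan planes.  Responder tumours keep smaller effective
scatterers and weaker contrast; non-responders drift toward larger
scatterers, stronger contrast and a patchier margin as `effect_size` → 1;
`effect_size = 0` yields a null cohort.  Outcome metadata (sizes,
cellularity) are drawn per intended class and verified against the grading
rules: MR score 1–5 from RECIST-style size change (exactly 30% reduction
grades 2), responder iff reduction > 30% or residual cellularity ≤ 5%.
The imaged core defaults to 8 mm diameter — a representative central
cross-section kept deliberately compact so whole cohorts run at desk scale;
clinical LABC tumours are larger, and absolute texture scales would differ.

Passing tests on these cohorts demonstrate that the *computational chain* is
correct (spectral estimation, normalization identities, parameter recovery,
feature accounting, leakage-free cross-validation).  They do not
demonstrate clinical performance: real tumours have 3-D structure,
diffraction and aberration, inhomogeneous attenuation, operator variability
and far richer heterogeneity than the two-population patch model.  The
published clinical performance numbers require the original patient RF
data and are explicitly not reproduced here.

## Problem sizes and determinism

Tests and the acceptance script use scaled-down problems chosen as the
package's own desk-scale defaults: 18 × 16 mm frames, 4–20-patient cohorts
with one scan plane, 4–6 reference frames, 20-seed Monte-Carlo averages.
All generators are deterministic given a seed; the acceptance script
derives every sub-seed from its `--seed` argument.  Known limitations:
no electronic noise or depth-dependent diffraction in the simulator; ACE
assumed homogeneous below the ROI top; margin rings near the 15-pixel
window width can lose their derivate features on narrow geometries (the
imputation path covers this and logs it).
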