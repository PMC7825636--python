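# qusresp

Quantitative-ultrasound (QUS) radiomics for *a priori* prediction of
breast-tumour response to neoadjuvant chemotherapy — spectral parametric
imaging, texture-derivate feature extraction, and cross-validated response
classification, driven end to end by a synthetic RF-data generator so that
every stage is verifiable without patient data.

## Who this is for

Researchers building or auditing QUS spectroscopy pipelines: the package
turns beamformed radiofrequency (RF) frames into tissue-microstructure
parametric images, quantifies their spatial heterogeneity, and trains
leakage-safe response classifiers. Because clinical RF archives are rarely
shareable, a physics-based simulator generates labelled cohorts with known
scatterer properties, attenuation and outcomes, giving every estimator a
ground truth to be tested against.

## The pipeline

1. **Spectral parametric imaging.** A 2 mm × 2 mm window slides over the
   tumour ROI (94% overlap). Per window, Hanning-gated line periodograms
   are averaged and normalized by a reference phantom (0.8 dB/cm/MHz,
   1540 m/s) with layered attenuation compensation:

       σ_m(f) = σ_r(f) · |S_m(f)|²/|S_r(f)|² · exp[4(α_m − α_r)(R + Δz/2)]

   The tumour attenuation coefficient (ACE) is estimated by the
   spectral-difference method. A linear fit to the corrected normalized
   power spectrum gives **MBF**, **SS**, **SI**; fitting the Gaussian
   form-factor backscatter model σ(f) = C f⁴ a_eff⁶ n̄γ₀² F(f, a_eff) gives
   **ASD** (effective scatterer diameter) and **AAC** (acoustic
   concentration, 10 log₁₀ n̄γ₀²).
2. **Texture.** Each parametric image is quantized to 16 gray levels;
   symmetric mask-aware GLCMs at distances 1–5 and angles 0°–135° yield
   contrast, correlation, energy and homogeneity, averaged over the 20
   matrices.
3. **Texture-derivate.** A 15 × 15-pixel window builds texture-encoded maps
   (distance-1 GLCMs); a second texture pass over those maps yields 16
   derivate features per parametric image.
4. **Features.** Per region (tumour core and 5-mm margin ring):
   5 mean + 20 texture + 80 derivate = **105 features**; plus CMR/CMCR
   image-quality ratios per parameter = **220 combined**, plane-averaged
   with ROI-area weights.
5. **Classification.** Forward sequential feature selection (F1 metric,
   4-feature cap) nested inside leave-one-out cross-validation; LDA, KNN
   (k ∈ {1,3,5}) and RBF-SVM (grid-searched C, γ); sensitivity,
   specificity, accuracy, AUC, PPV, NPV from pooled predictions.

## Worked example

```bash
python examples/01_simulate_and_image.py
```

```
frame: 935 samples x 53 lines; 4420 analysis windows inside the ROI
estimated tumour attenuation (ACE): 1.04 dB/cm/MHz (simulated at 1.00)
 MBF: median    27.11 dB
  SS: median    -0.53 dB/MHz
  SI: median    29.97 dB
 ASD: median    61.80 um
 AAC: median    -3.73 dB/cm^3
```

A homogeneous 70-µm-scatterer "tumour" simulated at 1.0 dB/cm/MHz: the
spectral-difference ACE lands within a few percent of the simulated value,
and the median form-factor fit recovers the scatterer diameter (61.8 µm vs
70) and concentration within the pipeline's documented tolerance — the
residual bias comes from periodogram smoothing of the shallow form-factor
curvature, not from the normalization, as the other examples isolate.

The other examples cover texture/texture-derivate features on patchy vs
homogeneous images (`02`), attenuation-estimate recovery over seeds (`03`),
and a full synthetic cohort classified under nested and global feature
selection (`04`).

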