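# Methods

This note documents the models, conventions and design choices behind
`echogen`: a desk-scale testbed for B-mode→RF synthesis and quantitative
ultrasound (QUS) tissue characterization.

## 1. The phantom simulator

### Acoustic model

A scene is an ordered stack of homogeneous regions (one background plus
elliptical lesions; later regions override earlier ones inside their
geometry). Each region is a Poisson point process of sub-resolution
scatterers with number density `n` (mm⁻²), effective radius `a_eff` (µm) and
zero-mean Gaussian amplitudes with a region-specific variance. The
backscatter coefficient follows the spherical Gaussian form factor

    BSC(f) = κ · n · a_eff⁶ · k⁴ · exp(−0.827 k² a_eff²),  k = 2πf/c,

with κ a single named model constant (default 1) carried in calibration
metadata — absolute BSC calibration is out of scope, and κ cancels in the
reference-phantom normalization.

RF lines are synthesized in the frequency domain. Scatterers are binned to
the nearest scan line and to the axial sample `round(2·z·fs/c)`; each
(region, 64-sample depth block) spike train is filtered by

* the Gaussian pulse amplitude spectrum (center 10 MHz, −6 dB fractional
  bandwidth 0.6, fs = 40 MHz, c = 1540 m/s by default, mirroring a linear
  array in a research acquisition mode),
* the amplitude form-factor filter `√κ · a_eff³ · k² · exp(−0.4135 k² a_eff²)`
  so that expected echo power tracks the BSC model exactly,
* a block-wise attenuation filter `10^(−2·α·f·z/20)` evaluated at the block
  center, with the cumulative one-way path `∫α dz` integrated through the
  region map per scan line.

This yields the contract the estimators rely on: for a homogeneous region,
the window-averaged power spectrum equals system response × BSC × round-trip
attenuation (verified to < 1 dB RMS over the analysis band with ≥ 200 lines
averaged). Synthesis is 2-D (single plane, densities in mm⁻²); full 3-D
wave propagation, elevational focusing, lateral beam correlation, nonlinear
propagation and TGC are deliberately not modeled. Consequences: speckle is
laterally uncorrelated between scan lines (slightly optimistic spectral
averaging), and there is no electronic noise floor, so estimator recovery
at high frequencies is cleaner than on a real scanner. Passing recovery
tests therefore demonstrates estimator correctness, not robustness to
scanner noise.

### B-mode formation

Envelope = |analytic signal| per line (Hilbert transform), log-compressed to
[−DR, 0] dB relative to the frame peak (DR = 60 dB default), rescaled to
[0, 1], optionally resampled. An all-zero frame maps to an all-zero image.

### The paired benign/malignant cohort

Defaults encode the class contrast reported in the QUS breast literature:
benign lesions a_eff ~ U(80, 110) µm, density U(6, 10) mm⁻², homogeneous;
malignant lesions a_eff ~ U(40, 70) µm, density U(12, 20) mm⁻², doubled
amplitude variance, and 15 % within-lesion jitter realized as per-plane
multiplicative N(1, 0.15) perturbations of radius and density. Background:
a_eff 25 µm, density 12 mm⁻², α = 1.0 dB/MHz/cm (the standard intervening
breast-tissue value, so the default two-layer correction prior is
consistent); lesion α defaults to the same value so that class contrast is
carried by microstructure, not attenuation. Each lesion is imaged on 4
discrete planes with jittered elliptical cross-sections (a continuous sweep
is not emulated). Everything is deterministic given `(config, seed)`.

Desk-scale frames are 512 × 128 (≈ 9.9 × 40 mm); the clinical 2080 × 510
geometry is available via configuration.

## 2. QUS spectral analysis

* **Windows**: 2 × 2 mm Hann-gated windows at 94 % overlap (step = 6 % of
  the window size, computed in physical units over the ROI bounding box);
  windows whose center lies in the core + 5 mm margin are kept, and windows
  spilling outside the frame are shifted inward and flagged. Spectra are
  line-wise periodograms (demeaned, Hann gate, zero-padded to a 1024-point
  FFT) averaged across the window's lines.
* **Reference normalization**: sample dB spectrum minus the reference
  phantom's spectrum in the same window. The reference phantom (a_eff
  12.5 µm, n = 100 mm⁻², α = 0.786 dB/MHz/cm, c = 1540 m/s) is simulated
  with known microstructure recorded as calibration metadata.
* **Analysis band**: the −6 dB band of the mean reference spectrum
  intersected with an absolute band, default 3–13.5 MHz. The absolute band
  was chosen to cover the 10 MHz pulse's −6 dB band (≈ 7.7–13.3 MHz): a
  band that poorly overlaps the transducer passband leaves < 1 MHz of
  usable bandwidth and makes the form-factor fit ill-conditioned (up to
  40 % ESD error in our measurements, vs < 2 % with the matched band).
* **Attenuation**: α is one-way in dB/MHz/cm everywhere; round-trip
  compensation carries an explicit factor 2 (`+2·Σ αᵢ·f·pathᵢ` dB; the
  Np-domain equivalent would carry a factor 4 on amplitude). Because the
  reference-normalized spectrum already contains the reference phantom's
  own attenuation, the map pipeline compensates *differential* coefficients
  (layer α minus 0.786); the standalone `correct_attenuation` op applies
  whatever coefficients it is given, so its forward/inverse round trip is
  exact. The tumor coefficient (ACE) is estimated once per lesion by the
  spectral-difference method — per-frequency least-squares depth slopes of
  the normalized spectrum over depth-binned core windows, then a linear
  fit of `α(f)·f` on `f` — and requires ≥ 3 depth bins spanning ≥ 0.5 cm.
  Desk-scale lesions are shallower than that, so the pipeline falls back to
  the configurable tumor prior (1 dB/MHz/cm, matching the simulated value);
  ACE recovery itself is validated on synthetic spectra with adequate span
  (±0.1 dB/MHz/cm).
* **Parametric fits**: SS/SI by ordinary least squares of dB power on
  frequency; MBF ≡ SS·f_center + SI with f_center the band midpoint (exact
  identity, asserted per window). ESD/EAC by the linearized Gaussian
  form-factor fit: `y = ln BSC − 4 ln k` regressed on `k²`; slope
  b₁ → a_eff = √(−b₁/0.827), intercept b₀ → EAC = 10·log₁₀(e^{b₀}/(κ a_eff⁶)),
  which for the self-consistent simulator equals 10·log₁₀ of the effective
  concentration `n × amplitude variance`. Using `4 ln k` rather than
  `4 ln f` absorbs the constant `(2π/c)⁴` into the regression variable so
  the intercept is directly interpretable. A non-negative slope is flagged
  degenerate (a_eff = 0, window masked invalid).
* **Scaling properties** (asserted): multiplying RF amplitude by `s` shifts
  MBF, SI and EAC by 20·log₁₀(s) dB and leaves SS and ESD unchanged.

## 3. Texture features

Each parametric map is quantized into 16 levels over the valid-window range
(floor binning, max → top level; affine rescaling of a map therefore leaves
all textures invariant). Symmetric GLCMs at distances 1–5 pixels and angles
0/45/90/135° are accumulated on the raw window-center grid — not on
display-interpolated maps — with mask-aware pair counting (pairs with an
invalid member are skipped; skimage's GLCM is not mask-aware, which is why
this is in-package, with skimage and a brute-force enumerator as test
oracles). Contrast, correlation, energy and homogeneity
(HOM = Σp/(1+|i−j|), the inverse difference, not skimage's inverse
difference moment) are averaged over the 20 GLCMs. Degenerate correlation
(zero marginal spread, e.g. a constant map) is defined as 1: a constant map
is maximally self-correlated and NaNs must not propagate into feature
tables. The per-lesion vector is 5 map means + 4 textures × 5 maps = 25
features, averaged elementwise across imaging planes; features default to
core + margin (configurable).

## 4. Translators and training

The three generators and the patch discriminator run on a small reverse-mode
autograd over numpy (float32 by default; gradient checks run in float64).
All geometry is parametric; the desk preset uses base 16 U-Net filters
(cap 128), ViT embed 64 with 4 heads, and discriminator filters
(16, 32, 64) + (128, 1), while the full-size configuration mirrors the
clinical design (64…512, embed 256, 8 heads, (64, 128, 256) + (512, 1)).

* **Pix2Pix U-Net**: stride-2 4×4 convs, BN + LeakyReLU(0.2); filters double
  from the base up to the cap; decoder mirrors with transposed convs,
  dropout 0.5 on the first three decoder stages, skip connections pairing
  mirror resolutions, sigmoid head. The level count defaults to
  min(7, ⌊log₂ min(rows, cols)⌋) — 7 at 2048 × 512, 6 at 256 × 64 — because
  a 7-level encoder does not fit a 64-column frame; an explicitly requested
  depth that violates divisibility is an error.
* **ViT generators**: 16 × 16 patch embedding + learned positional
  embeddings; 2 (shallow) or 5 (deep) pre-norm transformer blocks
  (MHSA + GELU MLP, ratio 4); tokens reshaped to an (embed, rows/16,
  cols/16) map and upsampled by four transposed convs (BN + LeakyReLU on
  the first three, sigmoid head). The deep variant adds skip paths: blocks
  1 and 3 feed decoder stages 2 and 1 via reshape → nearest-neighbor
  upsample → 1×1 conv → add.
* **Initialization**: Pix2Pix and the discriminator keep the original
  small-scale (normal, σ = 0.02) convention. The ViT decoders use
  fan-in-scaled (He) init for hidden stages with the 0.02 init retained for
  the sigmoid output head: a uniform 0.02 init across a four-stage decoder
  starves early gradients and training stalls at the
  constant-prediction reconstruction floor, whereas the fan-in/small-head
  combination reaches the lowest validation reconstruction loss we observed
  in any configuration.
* **Discriminator**: channel-concatenated (B-mode, RF); three 3×3 stride-2
  conv blocks with channel layer-norm + LeakyReLU, then 3×3 stride-1 convs
  (512, 1) with a sigmoid — a (rows/8, cols/8) patch probability map.
* **Losses and schedule**: generator loss = BCE(D(fake), 1) + 1000·L1 +
  100·L2; discriminator loss = BCE(D(real), 1−ε) + BCE(D(fake), 0) with
  ε = 0.1 on real labels only; adversarial weight 1. Adam (β₁ = 0.5,
  β₂ = 0.999), decoupled weight decay 1e-4, lr 1e-4 (G) / 1e-5 (D), batch
  size 1. Training runs a main phase then a selection phase in which the
  checkpoint with the lowest validation reconstruction (weighted L1+L2)
  loss is kept. The smoke protocol used in the tests is 32 pairs at
  256 × 64 for 20 + 5 epochs — enough to cut validation reconstruction
  loss roughly in half for every variant on one CPU; it demonstrates that
  the training loop optimizes what it should, not that desk-scale models
  reach clinical fidelity. B-mode→RF translation is fundamentally
  ill-posed (the envelope discards carrier phase), so at this scale the
  learnable margin below the constant-prediction floor is small.

## 5. Evaluation and classification

* NRMSE/NMAE are percentages of the reference quantity's global dynamic
  range over the evaluation cohort; SSIM uses the 11 × 11 Gaussian window
  (σ = 1.5, K1 = 0.01, K2 = 0.03, edges cropped, cross-checked against
  scikit-image to 1e-6); PSNR uses the declared peak (1.0 for normalized
  data, 255 for 8-bit) and returns +∞ for identical inputs.
* UMAP (n_neighbors 15 clipped to cohort size − 1, min_dist 0.1, fixed
  seed) is fitted on z-scored original feature vectors; synthetic vectors
  are projected into the same embedding and compared by mean paired
  Euclidean distance.
* Classification: features are z-scored with training-lesion statistics
  only; top-20 mutual information (nearest-neighbor estimator, fixed seed)
  → elastic-net logistic regression (l1 ratio 0.7, C = 1, SAGA, ≤ 10 000
  iterations) retaining |coef| > mean |coef|; RBF SVC grid-searched over
  C ∈ 10^[−2,3], γ ∈ 10^[−4,1] (6 × 6) by stratified 5-fold CV AUC;
  bootstrap evaluation with 1000 lesion-level resamples reporting
  mean ± SD percentages (sensitivity defined on the malignant class;
  metrics undefined on a resample are skipped and counted). The four
  experiment conditions share the lesion split and bootstrap seeds.

## 6. Problem sizes used in the test suite

Unit tests run on 512-sample frames with 128–256 lines; the smoke-training
benchmark uses 32 pairs at 256 × 64 for 25 epochs; the end-to-end study
uses 40 lesions × 4 planes with an identity translator (synthetic RF ≡
original RF), which isolates the QUS + classification path from generator
quality. The acceptance script runs scaled-down versions of the same
computations (16-pair smoke training, 20-lesion study). These sizes were
chosen so the whole suite runs on a single CPU in minutes while every
statistical check retains adequate power.

## 7. Known limitations

* No lateral point-spread function: speckle is uncorrelated across scan
  lines, so spectral estimates average faster than on a real scanner.
* No noise floor, no TGC, no scan conversion (linear array only).
* EAC is self-consistent with the simulator's κ but not absolutely
  calibrated against bead-size distributions.
* Desk-scale translators are smoke-trained; their synthetic RF is not
  expected to preserve QUS parameters the way a fully trained clinical
  model would. The identity-translator study and the parameter-recovery
  suites are the quantitative anchors.
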