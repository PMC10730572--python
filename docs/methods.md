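# Methods

This note documents the models, estimators, defaults and design choices in
`qusnac`, in the spirit of a model-description appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

Breast tumours treated with neoadjuvant chemotherapy (NAC) split into
responders (R) and non-responders (NR) only months after treatment starts.
Quantitative ultrasound (QUS) characterizes tissue microstructure from raw
radiofrequency (RF) echoes — calibrated backscatter spectra rather than
B-mode brightness — and QUS-derived features of the tumour core and its
5-mm margin, together with molecular subtype, carry pre-treatment
information about eventual response. The package implements the complete
chain: RF data → QUS parametric maps → texture and texture-derivative
features → core/margin feature engineering → nested cross-validated
classification. Patient RF data of this kind are confidential, so the
package ships a physics-based synthetic generator that reproduces the
statistical structure the analysis relies on; every stage is exercised
end-to-end on synthetic cohorts.

## RF simulation (`qusnac.phantom`, `qusnac.rfsim`)

The simulator is a 1.5-D convolution model, not a wave solver. Discrete
scatterers are drawn as a homogeneous Poisson process per region (areal
density in the imaging plane), with Gaussian-distributed radii. Per RF
line, scatterer echoes form a delta train weighted by a Gaussian lateral
beam profile (sigma = 1.5 line spacings, truncated at 4); echo amplitude is
proportional to impedance contrast times radius cubed (Rayleigh-regime
proxy). Each region's train is spectrally shaped by the amplitude form
factor `(f/fc)^2 exp(-0.827 k^2 a^2 / 2)` — the square root of the
spherical-Gaussian-model (SGM) power law — using the region's mean radius;
individual radius variation modulates amplitude only. Depth-dependent
attenuation and the pulse (Gaussian-modulated cosine at 6.5 MHz, 60%
fractional bandwidth at -6 dB) are applied in the frequency domain over
50%-overlapped Hann segments (overlap-add).

Attenuation convention: for a coefficient `alpha` in dB/MHz/cm, an echo
from depth `z` loses `4 * alpha * f_MHz * z_cm` dB of round-trip *power*
(amplitude multiplied by `10^(-4 alpha f z / 20)`). This is the convention
in which `alpha_dB = 4.343 * alpha_Np`; the spectral-difference estimator
inverts the same factor, so simulator and estimator are exactly
self-consistent, and normalizing the reference phantom against itself
recovers its own 0.786 dB/MHz/cm.

Acquisition noise: additive Gaussian noise whose standard deviation is a
fixed fraction (default 0.02) of the local, depth-resolved signal RMS —
i.e. gain-referred noise that tracks the time-gain-compensated echo level,
as on a clinical scanner after TGC. The clinical system's actual noise
figure is not publicly specified; this default is a free parameter of the
simulator, not a claim about the device.

Acquisition geometry defaults mirror the emulated clinical system: 6.5 MHz centre
frequency, 3–8 MHz band, 40 MHz sampling, 512 lines over 6 cm lateral;
axial depth 4–6 cm (cohort runs use 4 cm, the low end of the range, for
cost). The calibration reference phantom is uniform with attenuation
0.786 dB/MHz/cm and sound speed 1540 m/s; its scatterers (25 um radius,
1e8/m^2, unit contrast) define the unit of acoustic concentration, so AAC
is reported in dB relative to the reference phantom.

### Tumour phantoms

A tumour phantom is an elliptical core (~2.2 x 1.8 cm, centred laterally,
jittered ±2 mm per seed), a 5-mm surrounding ring, and background tissue.
Class defaults encode the reported group differences:

| property                      | non-responder (NR) | responder (R) |
| ----------------------------- | ------------------ | ------------- |
| core density (1/m^2)          | 1.5e8              | 0.8e8         |
| core radius (um)              | 45 ± 4             | 65 ± 6        |
| core impedance contrast       | 1.30               | 0.90          |
| margin density / radius / contrast | 1.4e8 / 47 / 1.25 | 1.1e8 / 55 / 1.10 |
| background                    | 0.8e8 / 55 / 1.00  | same          |
| attenuation (dB/MHz/cm)       | 1.0                | 1.0           |
| core heterogeneity (density, radius) | 0.18, 0.09  | 0.50, 0.25    |
| margin heterogeneity          | 0.14, 0.07         | 0.30, 0.15    |

Directions: NR tumours have higher backscatter (density x contrast^2) in
core and margin, smaller scatterers, and margins statistically similar to
their cores; R tumours have larger scatterers, cores distinct from margins,
and stronger intra-tumoural heterogeneity. Scatterer diameters stay within
the 80–182 um range of breast lobule diameters. Heterogeneity is a smooth
random field (signed Gaussian bumps, 3.5 mm correlation length) modulating
local density (by thinning) and radius; its class contrast was calibrated
once so that ultrasound texture separates the classes well but not
perfectly, leaving molecular subtype complementary signal — mirroring the
reported structure in which texture-derivative features and subtype
together outperform either alone. These defaults are the package's study
conditions and are not adjusted per experiment.

Ground truth (density, radius, contrast, attenuation, relative acoustic
concentration) travels with every phantom and frame so estimators can be
scored for recovery.

## Spectral QUS estimation (`qusnac.spectral`)

Analysis windows are 10 wavelengths square (123 samples x 20 lines at the
default geometry), stepped at the non-overlapping fraction of the block
(94% overlap → 7-sample / 1-line steps); only windows fully inside the ROI
are used. Window spectra are Hann-tapered per-line periodograms averaged
across the block's lines (Welch-style; the estimator choice is ours — the
clinical literature rarely states one), zero-padded to a 256-point FFT.
Reference spectra come from simulated reference-phantom frames at the same
depths, averaged over all lines and frames.

The reference-phantom method then gives, per window,

    BSC_dB(f) = 10 log10(S_sample/S_ref) + 10 log10(BSC_ref(f))
                + 4 (alpha_s - alpha_r) f z

with `BSC_ref` the reference's SGM model and the last term the
attenuation-difference compensation at the window depth (point
compensation; the sample's own attenuation estimate is used). The usable
band is the -6 dB band of the reference spectrum at that depth, clipped to
3–8 MHz.

* **MBF / SS / SI** — ordinary least squares of `BSC_dB` against frequency
  over the usable band: SS is the slope (dB/MHz), SI the 0-MHz value, MBF
  the line's value at the band centre.
* **ACE** — spectral-difference method: per frequency, the dB ratio
  `10 log10(S_s/S_r)` is regressed against depth (slope `-4 (alpha_s -
  alpha_r)` dB/cm), then `alpha_s(f)` is fitted through the origin against
  frequency. One scalar per tumour ROI (row-averaged spectra), reused for
  both core and margin normalization.
* **ASD / AAC** — linearized SGM inversion: `ln BSC - 4 ln f` regressed on
  `k^2`; slope `-0.827 a_eff^2` gives ASD = `2 a_eff`; the intercept, after
  removing the `C0 a_eff^6` term (C0 = 1 by the reference-relative
  convention), gives AAC in dB. Windows with no measurable decay (implied
  diameter below 1 um) are flagged missing rather than reported.

Parametric maps are rasters on the window grid; flagged windows are NaN and
excluded from means, texture quantization and second-pass analysis. A
quality warning is recorded when more than half the ROI's windows flag.

## Texture and texture derivatives (`qusnac.texture`)

First pass: rasters are uniformly quantized to 16 grey levels over their
own min–max (missing cells excluded; the result is affine-invariant), and a
grey-level co-occurrence matrix is accumulated at distance 1 over four
angles (0/45/90/135 degrees), symmetrized and pooled. Four features are
computed: contrast CON, correlation COR, energy ENE, homogeneity HOM. COR
is undefined (missing) for zero-variance matrices. Level count, distance
and angles are configurable; the clinical papers do not state them.

Second pass ("texture derivatives"): a 15 x 15-pixel sliding window (valid
mode, stride 1) produces four texture-encoded maps; the same GLCM feature
extraction applied to each map yields 16 features named FIRST-SECOND (e.g.
`ASD-ENE-HOM`: homogeneity of the energy map of the ASD image).
Quantization is per window, so local texture is measured relative to the
local dynamic range; the per-map alternative is available via the same
functions. A compiled (numba) kernel implements the sliding analysis; a
pure-numpy reference implementation is kept and the two are asserted equal
in the tests.

## Feature engineering (`qusnac.features`)

The margin is the set of pixels outside the core within 5 mm Euclidean
distance (anisotropic pixel spacing honoured via a sampled distance
transform). The canonical per-patient census is fully crossed: per region
(core, margin) 5 mean QUS parameters + 20 texture + 80 texture-derivative
features; plus ACE, 5 CMR and 5 CMCR — 221 ultrasound features, plus 4
subtype indicators when enabled. (The clinical literature's printed totals
for this census are internally inconsistent; the fully crossed enumeration
is used and is configurable.)

Core-to-margin parameters per map: CMR = mean_core / mean_margin; CMCR =
(mean_core - mean_margin) / sqrt(sd_core^2 + sd_margin^2), a
contrast-to-noise-style definition. The source literature describes these
only qualitatively; these exact forms are this package's documented choice
and are swappable.

Molecular subtype follows the receptor logic ERBB2+ (ER-, PR-, HER2+),
triple negative (ER-, PR-, HER2-), Luminal-A (ER+ and/or PR+, HER2-),
Luminal-B (ER+ and/or PR+, HER2+), one-hot encoded.

Feature-set presets: I = QUS means + texture + core-to-margin; II =
texture derivatives; III = subtype; IV = I+II (ultrasound only); V =
I+III; VI = II+III; VII = everything.

## Classification (`qusnac.classify`)

Per training set (outer-fold): z-score standardization on training
statistics → mRMR ranking (mutual-information difference criterion, 4-bin
quantile discretization, top 50) → SMOTE over-sampling of the minority
class to exact parity (k = 5 minority neighbours, `x + u (x_nn - x)`) →
sequential forward selection (at most 10 features, greedy on inner
validation accuracy, ties broken by candidate order, stopping when no
strict improvement) → hyperparameter tuning (KNN k in {1,3,5}; SVM-RBF C in
2^8..2^15, gamma in 2^-18..2^-5) → final fit. Held-out rows never
influence any of these steps. The positive class is the non-responder.

Inner validation is a single seeded stratified 50/50 train/validation
split per outer fold, used for both SFS scoring and grid search; during
SFS the classifier runs with fixed defaults (KNN k = 3, the grid median;
SVM C = 1, gamma = 1/n_features). The source protocol says only that
parameters were "tuned"; a single-split inner layer keeps ~160 rows on
each side after SMOTE and makes nested leave-one-out tractable on one CPU.
These are the package's protocol choices, exposed in `SelectionSpec`.

Outer validation: nested leave-one-out (n outer models, predictions pooled
into one confusion matrix and one ROC — pooling chosen over per-fold
averaging, which is ill-defined for single-sample folds), and repeated
stratified hold-out (10 seeded splits at 20% or 10% test). For hold-out,
`bias_error` = 100% - mean test accuracy and `variance_error` = standard
deviation of test accuracy across repeats; the literature reports such
errors without a reproducible formula, so these definitions are ours and
are labelled as such. Metrics: sensitivity, specificity, accuracy, PPV,
NPV (percent) and trapezoidal ROC AUC; KNN scores are positive-neighbour
fractions, SVM scores signed decision values.

A deliberately leaky variant (`loo_cv_with_global_selection`) is provided
purely as a diagnostic yardstick for leakage tests: it greedily selects
features to maximize the pooled leave-one-out AUC computed over *all* rows
— the very statistic reported afterwards — which is the textbook form of
selection-before-validation bias. On label-independent features it inflates
the apparent AUC far above chance. It must never be used for reporting.

## Synthetic cohorts (`qusnac.cohort`)

Cohort composition defaults to the emulated cohort's 161 responders / 47
non-responders with subtype mixtures (ERBB2+, TN, LumA, LumB) = (14, 25,
36, 25)% in responders and (0, 26, 64, 11)% in non-responders (the printed
non-responder column sums to 101 due to rounding; it is normalized).

* `make_feature_cohort`: class-conditional Gaussian features over the full
  census. Ten designated discriminating features (core/margin MBF, core
  AAC and ASD, CMR-MBF, CMR-AAC, CMCR-AAC, and three core ASD-ENE-*
  texture derivatives) receive a standardized mean difference of 0.8 by
  default, signed per the reported group direction; everything else is
  exchangeable noise. Zero effect sizes give an exact null cohort.
* `simulate_cohort_features`: one simulated RF frame per patient through
  the full extraction chain, with subtypes drawn from the class mixtures.
  Cohort runs default to 80% window overlap (not the clinical 94%): a
  reduced window density whose parametric maps (~35 x 45 cells per region)
  remain large enough for 15 x 15 texture-derivative analysis, at
  desk-scale cost. One 4-cm-depth frame per patient stands in for the
  clinical acquisition's several planes per patient.

## What the synthetic data do and do not show

The generator reproduces: incoherent speckle statistics with the k^4 /
Gaussian-form-factor spectral law, frequency-dependent attenuation,
class-conditional core/margin scatterer differences, intra-tumoural
heterogeneity at a realistic correlation length, the cohort's class
imbalance and subtype mixtures. It does not model: diffraction and
focusing, phase aberration, nonlinear propagation, electronic noise
spectra, anatomical tissue layers, multi-plane acquisition, or
inter-patient variability beyond seed jitter and Poisson/field randomness.
Passing end-to-end tests therefore demonstrates that the pipeline recovers
the structure this model family encodes — not clinical performance on
patient data. The headline clinical numbers (accuracy ~80–85%, AUC
0.83–0.87 on 208 patients) are context, not reproduction targets: the
patient data are confidential.

## Numerical choices and degenerate inputs

* Window grids round 10-wavelength blocks to whole samples/lines; steps
  are at least one sample/line. ROIs smaller than one block raise.
* All-zero spectra, non-positive band references, sub-1-um SGM decays and
  zero-variance GLCMs flag missing values that propagate as NaN and are
  excluded from means and quantization ranges.
* The -6 dB usable band needs >= 3 points for line fits and >= 4 for SGM.
* Distances in the inner CV run in float32 (memory bandwidth); final
  estimators are ordinary scikit-learn KNN/SVC in float64.
* All randomness flows from `numpy.random.default_rng(seed)`; per-fold
  seeds derive from the outer seed, so every CV result is bit-reproducible.

## Problem sizes in the test and acceptance runs

Unit tests run on reduced geometries (128-line probes, 3-4 cm depths,
70-80% window overlap). The end-to-end acceptance experiment uses the full
208-patient cohort at 512 lines / 4 cm / 80% overlap; attenuation-recovery
checks use uniform phantoms at the full geometry; the leakage canary uses
the full 208 x 221 null feature cohort across 20 seeds. These sizes are the
package's validation conditions, chosen to run on a single CPU.

## Known limitations

* The convolution model has no diffraction; attenuation estimates on
  strongly heterogeneous media (responder-like phantoms) carry a
  backscatter-trend bias of order 10-20%, visible as inflated ASD for
  large-scatterer media. Directional group contrasts are robust to this.
* CMR on dB-valued maps (MBF/SS/SI) divides signed quantities; it is kept
  for census fidelity but is scale-fragile, and the synthetic cohorts do
  not rely on it.
* SMOTE interpolates in the mRMR-reduced standardized space; its synthetic
  rows are convex combinations there, not in raw feature space.
* Single-split inner validation trades selection stability for speed; with
  ~320 balanced training rows the induced variance is modest, but SFS
  subsets vary more across folds than a full inner 5-fold would give.
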