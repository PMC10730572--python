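# qusnac

**A-priori prediction of breast-tumour response to neoadjuvant chemotherapy
from quantitative-ultrasound RF data.**

Not all breast tumours respond to neoadjuvant chemotherapy (NAC), and the
clinical verdict — pathology after surgery — arrives months after treatment
begins. Quantitative ultrasound (QUS) offers a pre-treatment window:
calibrated radiofrequency (RF) backscatter spectra characterize tissue
microstructure (scatterer size, concentration, attenuation), and texture
patterns of the resulting parametric maps, together with the tumour's
molecular subtype, correlate with eventual response. `qusnac` implements
that analysis chain end to end for researchers in ultrasound tissue
characterization and radiomics:

* **Spectral QUS** — reference-phantom normalization; mid-band fit (MBF),
  spectral slope (SS) and 0-MHz intercept (SI) by linear regression of the
  normalized backscatter spectrum over the −6 dB band; attenuation
  coefficient estimate (ACE) by the spectral-difference method; average
  scatterer diameter (ASD) and acoustic concentration (AAC) by spherical
  Gaussian model (SGM) inversion,
  `BSC(f) = C₀ k⁴ a⁶ n exp(−0.827 k²a²)`.
* **Texture and texture derivatives** — grey-level co-occurrence matrices
  (16 levels, distance 1, four angles pooled) yielding contrast (CON),
  correlation (COR), energy (ENE) and homogeneity (HOM); plus a second GLCM
  pass over 15×15 sliding-window texture-encoded maps ("texture
  derivatives", e.g. `Core ASD-ENE-HOM`).
* **Core/margin feature engineering** — tumour core and 5-mm margin
  regions, core-to-margin ratio `CMR = μ_core/μ_margin` and contrast ratio
  `CMCR = (μ_core−μ_margin)/√(σ²_core+σ²_margin)`, molecular-subtype
  one-hot encoding (ERBB2+/TN/Luminal-A/Luminal-B from ER/PR/HER2), and a
  221-feature canonical census.
* **Classification** — nested leave-one-out and repeated hold-out
  cross-validation with mRMR ranking (top 50), SMOTE class balancing,
  sequential forward selection (≤10 features), and tuned KNN (k∈{1,3,5})
  or SVM-RBF (C∈2⁸..2¹⁵, γ∈2⁻¹⁸..2⁻⁵) classifiers; sensitivity,
  specificity, accuracy, PPV, NPV and ROC AUC with the non-responder as
  the positive class.
* **Synthetic phantoms** — patient RF data of this kind are confidential,
  so a seeded convolution-model simulator generates reference phantoms
  (0.786 dB/MHz/cm, 1540 m/s) and two-class tumour phantoms whose
  core/margin scatterer statistics follow the reported group differences;
  every stage is testable without any download.

See `docs/methods.md` for the model descriptions, defaults and design
choices.

## Worked example

Simulate a non-responder tumour and a calibration phantom, extract its
feature vector, and classify a synthetic cohort:

```python
import numpy as np
from qusnac import (TransducerSpec, make_reference_phantom_spec,
                    make_tumour_phantom, core_mask_for_phantom,
                    simulate_rf_frame, extract_patient_features)

t = TransducerSpec(axial_extent=0.04)        # 6.5 MHz, 512 lines, 40 MHz
refs = [simulate_rf_frame(make_reference_phantom_spec(t), t, seed=s)
        for s in (900, 901)]
phantom, core = make_tumour_phantom("NR", seed=1, transducer=t)
frame = simulate_rf_frame(phantom, t, seed=11)
feats = extract_patient_features(frame, core_mask_for_phantom(core, t),
                                 refs, overlap=0.8)
print(round(feats["Core MBF"], 1), round(feats["Core ASD"], 1),
      round(feats["ACE"], 2))
```

prints

```
-91.3 103.2 0.93
```

— the non-responder core's mid-band fit is −91.3 dB (several dB above a
responder's, reflecting its denser, higher-contrast scatterers); the
average scatterer diameter estimate is 103 µm against a ground-truth class
mean of 90 µm (responders, built with ~130 µm scatterers, estimate larger
still); and the recovered tumour attenuation is 0.93 dB/MHz/cm against a
true 1.0 — both estimates within the accuracy the convolution model
supports on a single heterogeneous frame.

Classifying a full synthetic cohort (161 responders / 47 non-responders)
from texture-derivative + subtype features with a nested-LOO SVM:

```python
from qusnac import simulate_cohort_features, nested_loo_cv, ClassifierSpec, SelectionSpec
from qusnac.features import canonical_census, feature_set_columns, SUBTYPE_NAMES

df = simulate_cohort_features(seed=7)            # ~3 min: 208 RF frames
cols = feature_set_columns(canonical_census() + list(SUBTYPE_NAMES), "VI")
res = nested_loo_cv(np.nan_to_num(df[cols].to_numpy()),
                    df["response"].to_numpy(),
                    ClassifierSpec(kind="SVM-RBF"), SelectionSpec(), seed=11)
print(f"AUC {res.metrics.auc:.3f}  accuracy {res.metrics.accuracy:.1f}%")
```

prints `AUC 0.888  accuracy 83.2%`: on phantoms built with the reported
group differences, texture-derivative features plus molecular subtype
separate the response classes well, with every selection and tuning step
confined to each fold's training data.

A thin CLI wraps the same library calls:

```bash
qusnac simulate --phantom NR --seed 4 --out tumour.h5
qusnac simulate --phantom reference --seed 3 --out ref.h5
qusnac extract --rf tumour.h5 --roi tumour.core.npy --reference ref.h5 --out features.json
qusnac classify --features cohort.csv --feature-set VI --classifier SVM-RBF --cv loo --seed 1 --out result.json
```

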