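# thyradiomics

A radiomic normal-tissue-complication-probability (NTCP) pipeline for
**radiation-induced hypothyroidism (RIHT)** after head-and-neck
radiotherapy.  RIHT develops in a quarter or more of irradiated patients;
the established predictors are dosimetric (mean thyroid dose D_mean,
thyroid volume V_thyroid), but CT texture of the gland may encode
baseline susceptibility that is *independent of the dose plan*.  This
package provides the full analysis chain needed to test that idea and to
benchmark texture-based classifiers against classical dose-response
models — exercisable entirely on synthetic thyroid phantoms, so every
stage ships tested without patient data.

For: medical-physics and imaging-biomarker researchers who need a
reproducible, leakage-audited radiomics pipeline with transparent feature
definitions.

## What it computes

* **Synthetic cohorts** (`synth`): two-lobe thyroid phantoms with a
  controllable correlated-texture amplitude, emulating a 98-patient,
  3-center cohort (28% RIHT prevalence, center-specific grids, batch
  effects, log-normal dose/volume marginals) with a logistic outcome
  `logit P = b0 + b1 z(D_mean) + b2 z(V_thyroid) + b3 z(texture)`.
* **Geometric preprocessing** (`volio`): isotropic 1 mm resampling
  (B-spline image / nearest-neighbour mask) and 10 mm padded ROI crop.
* **1316-feature catalog** (`features`): 14 shape + 93 intensity features
  (18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM) on the
  original image and 13 filtered variants (square, square root,
  logarithm, gradient, exponential, 8 stationary-wavelet subbands).
  Every texture family is tested against brute-force enumeration.
* **Stability screening** (`stability`): random affine mask perturbations
  (±1 mm, ±2°, ±2% per axis) and per-feature mean ICC(2,1) with
  excellent/good/moderate/poor classes.
* **Preprocessing & harmonization** (`preproc`): sample-mean
  normalization, [−1,1] scaling, Yeo–Johnson, second scaling, parametric
  empirical-Bayes ComBat (validated against `sva::ComBat`), and the three
  split variants (center-based without/with ComBat; pooled stratified
  38-patient training set with 10 events).
* **Feature filtration** (`filtration`): stability gate, Welch t-tests
  with Benjamini–Hochberg control, 1−r average-linkage clustering cut at
  0.3, lowest-q representatives (q < 0.1) plus all q < 0.01 features.
* **Modelling** (`modeling`): ten scikit-learn architectures, sequential
  forward selection (2–5 features, stratified 5-fold CV AUC), validation
  metrics with DeLong AUC standard errors, AND/OR/PROBA ensembles, and
  DeLong's paired test for correlated AUCs.
* **NTCP models** (`ntcp`): parameterized logistic, Lyman–Kutcher–Burman
  and mixture dose-response forms with a citation-tagged coefficient
  registry, and a side-by-side comparison against the pipeline's models.

See `docs/methods.md` for formulas, defaults and limitations.

## Worked example

```python
from thyradiomics.synth import default_cohort_config, generate_cohort, records_to_frame
from thyradiomics.features import ExtractionSettings
from thyradiomics.pipeline import cohort_feature_table
from thyradiomics.modeling import ModelSpec, run_variant

config = default_cohort_config(seed=3)
images, records = generate_cohort(config)
clinical = records_to_frame(records)
print(f"cohort: {len(clinical)} patients, {clinical.riht.sum()} with RIHT")

features = cohort_feature_table(images, clinical, ExtractionSettings(filters=()))
print(f"feature table: {features.shape[0]} patients x {features.shape[1]} features")

result = run_variant("II", clinical, features, specs=[ModelSpec("logistic")], seed=1)
for (pool, name), rep in result.reports.items():
    print(f"{pool:18s} AUC {rep.auc:.2f} +/- {rep.auc_se:.2f}  "
          f"sens {rep.sensitivity:.2f}  spec {rep.specificity:.2f}  F {rep.f_score:.2f}")
print(result.delong.round(3).to_string(index=False))
```

prints

```
cohort: 98 patients, 26 with RIHT
feature table: 98 patients x 107 features
clinical           AUC 0.56 +/- 0.09  sens 0.00  spec 0.98  F 0.00
radiomic           AUC 0.87 +/- 0.05  sens 0.25  spec 0.95  F 0.36
radiomic+clinical  AUC 0.89 +/- 0.05  sens 0.31  spec 0.95  F 0.43
            model  delta_auc_vs_clinical    se     p
         radiomic                  0.314 0.105 0.003
radiomic+clinical                  0.331 0.102 0.001
            PROBA                  0.267 0.081 0.001
```

Reading this: the synthetic cohort realizes 26/98 events around the
configured 28% prevalence.  On the pooled Variant II split (38 training
patients, 10 events), the texture-bearing radiomic model reaches
validation AUC 0.87 ± 0.05 versus 0.56 for the clinical model — the
generator planted a texture-heterogeneity effect, and the pipeline's
filtration and forward selection recover it; DeLong's paired test puts
the AUC difference at p ≈ 0.003.  Sensitivity at the default 0.5 cut is
low because the classes are imbalanced; the PROBA ensemble re-derives its
threshold from the training ROC.

A CLI mirrors the library:
`thyradiomics synth-cohort`, `extract`, `stability`, `run`,
`ntcp-predict` (see `thyradiomics --help`).

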