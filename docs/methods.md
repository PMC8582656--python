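# Methods

`thyradiomics` implements a CT-radiomics pipeline for modelling
radiation-induced hypothyroidism (RIHT) risk from the thyroid gland on
radiotherapy planning CT, together with the synthetic data needed to test
every stage without patient images.  This note documents the models,
parameter choices, numerical details and limitations.

## Synthetic phantoms and cohorts

A phantom is a two-lobe thyroid: two ellipsoids (default semiaxes
8 × 7 × 22 mm per lobe, centres at x = ±12 mm) joined by a cylindrical
isthmus (radius 4 mm), voxelized on an axis-aligned LPS-like grid at the
acquiring center's spacing.  In-mask intensity is

    I(x) = base + T(x) + e(x),        x inside the gland,

with `base` = 90 HU (thyroid is hyperdense relative to the 40 HU
soft-tissue background), `e` white Gaussian noise (default sigma = 10 HU),
and `T` a stationary correlated Gaussian field: white noise smoothed with
a Gaussian kernel whose sigma equals the correlation length (default
3 mm), then rescaled by the kernel's exact l2 norm so that the field's
marginal variance equals the configured amplitude squared.  The amplitude
`texture_sigma` is the single controllable "heterogeneity" dial that the
texture features are expected to track.

The default cohort emulates a 98-patient, three-center head-and-neck
radiotherapy population: center A (n = 38, 0.98 × 0.98 × 3.0 mm),
center B (n = 12, 1.27 × 1.27 × 2.5 mm), center C (n = 48,
0.98 × 0.98 × 3.0 mm).  Summary doses (D_mean, D50, D_min, D_max),
thyroid volume, baseline TSH/fT4 and the per-patient texture amplitude
are drawn from log-normal marginals parameterized by per-center
median/IQR; sex and stage from per-center marginal frequencies.  Dose
ordering D_min <= D50 <= D_max is enforced by clipping; the recorded
thyroid volume is the realized mask volume after scaling the reference
gland geometry to the sampled target.  Centers B and C carry
additive/multiplicative batch effects on in-mask intensities
(B: ×1.05 + 10 HU; C: ×0.95 − 8 HU), emulating scanner differences.

The binary outcome is logistic in the z-scored covariates:

    logit P(RIHT) = b0 + 0.8 z(D_mean) − 0.8 z(V_thyroid) + 1.2 z(texture_sigma)

with the intercept calibrated numerically so the expected prevalence
equals the configured fraction (default 27/98 ≈ 28%).  The signs encode
the intended epidemiology: higher mean dose, smaller glands and more
heterogeneous glands are at higher risk.  The effect sizes are free
parameters of the generator — chosen once as a realistic moderate signal
(≈1 log-odds per SD) — and are *not* calibrated to any real cohort.
Tests that specifically probe signal *recovery* plant a deliberately
strong heterogeneity effect (3.5 log-odds per SD) so the signal is
present in every 38-patient training draw; with the default moderate
effect, a 10-event training set simply lacks power on a minority of
draws, which is a property of small cohorts rather than of the pipeline.

What the generator does not emulate: realistic anatomy beyond the
two-lobe geometry, dose gradients inside the gland, oblique acquisitions,
contouring style differences between observers, and scanner-specific
texture (the batch effect is location/scale only).  Passing tests on this
synthetic cohort therefore demonstrate the pipeline's statistical
machinery, not clinical performance on real CT.

## Geometric preprocessing

Image and mask are resampled to 1 × 1 × 1 mm isotropic voxels (order-3
B-spline for intensities, nearest neighbour for the mask so it stays
binary), then cropped to the mask bounding box padded by 10 mm per side
(clipped to the volume).  Padding is interpreted in millimetres; at the
1 mm target grid this equals 10 voxels.  Resampling precedes cropping;
the two are equivalent to a fused implementation for these operations.

## Feature catalog

A full extraction yields exactly 1316 features:

* 14 shape features from the mask (mesh volume, voxel volume, surface
  area, surface/volume ratio, sphericity, maximum 3D diameter, three
  per-plane maximum 2D diameters, major/minor/least axis lengths defined
  as 4·sqrt of the principal-moment eigenvalues, elongation, flatness).
  Mesh quantities come from a marching-cubes triangulation at iso-level
  0.5 on the zero-padded mask; 2D diameters are maximum in-plane
  voxel-centre distances per plane.
* 93 intensity-based features per image variant: 18 first-order
  statistics, 24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM and 14 GLDM features.
* 14 image variants: the original image plus 13 filtered ones — square,
  square root, logarithm, exponential (all rescaled so the output range
  stays comparable to the input range M = max |x|), gradient magnitude
  (spacing-aware central differences), and the 8 subbands of a
  single-level stationary coiflet-1 wavelet decomposition (undecimated,
  so no mask resampling is needed; odd axes are edge-padded to even
  length and cropped back).

Algebraic filter formulas (M = max |x| over the cropped image):

| filter      | formula                                   |
|-------------|-------------------------------------------|
| square      | x² / M                                    |
| squareroot  | sign(x) · sqrt(M·abs(x))                  |
| logarithm   | sign(x) · M · log(abs(x)+1) / log(M+1)    |
| exponential | exp(x · log(M) / M)                       |

Discretization uses a fixed bin width of 25 HU relative to the ROI
minimum: level(x) = floor(x/w) − floor(min/w) + 1.  Texture matrices use
distance-1 neighbourhoods over the 13 unique 3D direction classes; GLCM
matrices are symmetrized and normalized per direction and features are
averaged over directions (likewise GLRLM).  GLSZM zones are 26-connected
equal-level components; GLDM dependence uses tolerance alpha = 0 with the
dependence *size* counting the centre voxel (so a lone voxel has size 1);
NGTDM coarseness is capped at 1e6 when its denominator vanishes, and a
ROI with no voxel pair yields NaN for every GLCM feature (flagged, never
silently dropped).  Entropies are log base 2 over positive probabilities.
Feature names follow `<variant>_<family>_<feature>` and the lexicographic
ordering of (variant, family, feature) is the stable public contract.

Every texture family is verified against an independent brute-force
oracle (explicit enumeration of voxel pairs, runs, zones and
neighbourhoods) on random <= 5×5×5 level maps at 1e-9 tolerance.

## Stability screening

Contouring inaccuracy is simulated by random affine mask perturbations:
three translations (uniform within ±1 mm per axis), three rotations
(±2°), three zooms (±2% per axis), composed in uniformly random order
about the mask centroid (centring avoids translation leakage from
rotations) and applied to the mask by nearest-neighbour resampling.
Features are re-extracted on each of (by default) 100 perturbed masks;
agreement with the original values across patients is measured by
ICC(2,1) — two-way random effects, absolute agreement, single
measurement — computed from the classic ANOVA mean squares.  Absolute
agreement is the stricter standard choice for a robustness screen.
Negative ICC estimates are kept (clipping would bias the mean upward);
a feature with zero total variance and identical columns scores 1.  The
per-feature mean ICC is classified excellent (> 0.9), good (0.75, 0.9],
moderate (0.5, 0.75] or poor (<= 0.5); the downstream gate keeps
excellent and good.

## Feature preprocessing

Fitted on training rows only, applied frozen to validation rows:

1. per-sample normalization: each row of the raw table divided by its
   mean across features;
2. min-max scaling of each feature to [−1, 1];
3. Yeo–Johnson transform, per-feature lambda by maximum likelihood
   (bounded search in [−5, 5], tolerance 1e-5);
4. second min-max scaling to [−1, 1];
5. (Variant Ib only) ComBat harmonization.

Sample normalization deliberately precedes the scalings.  Its rationale —
borrowed from high-throughput assays, where most features are expected
not to differ between samples — applies to raw radiomic panels, whose
row means are large positive per-patient loading factors (energy alone
reaches 1e10).  After scaling to [−1, 1] row means straddle zero, and
dividing by them is numerically meaningless (empirically it destroys all
univariate signal); a guard rejects rows whose mean is within 1e-8 of
zero rather than amplifying them.

ComBat is the standard parametric empirical-Bayes location/scale
harmonization: batch means define a size-weighted grand mean and pooled
within-batch variance; standardized per-batch location/scale estimates
are shrunk toward their across-feature priors (normal / inverse-gamma,
method-of-moments hyperparameters, iterative solution to 1e-6).  The
implementation agrees with Bioconductor `sva::ComBat` to ~1e-13 on toy
tables.  The outcome label is never passed to ComBat.  Two consequences
worth knowing: EB shrinkage means a planted additive offset is removed
essentially exactly only when per-feature standardized offsets agree
(with independent per-batch noise a residual of a few percent remains —
`sva` behaves identically), and the per-feature grand mean is preserved
only approximately, not to machine precision.  A single-batch fit is an
identity by construction.  For unseen validation batches the training
standardization is frozen and the new batch's own EB adjustments are
estimated relative to it, so no training parameter ever depends on
validation data.

Split variants: Ia/Ib train on center A and validate on centers B+C
(without/with ComBat); Variant II pools all centers and draws a
stratified random training set of exactly 38 patients with exactly 10
events, reproducible for a fixed seed.

## Feature filtration

On the preprocessed training table only: (1) stability gate (mean
ICC > 0.75); (2) per-feature Welch two-sample t-tests between outcome
groups (Welch rather than Student because group sizes and variances
differ; a config flag restores Student), Benjamini–Hochberg adjusted
across all tested features; (3) average-linkage hierarchical clustering
on the distance 1 − r (Pearson), dendrogram cut at 0.3; (4) per cluster,
keep the feature with the lowest adjusted q provided q < 0.1, plus every
feature with q < 0.01 regardless of correlation.  Ties on minimal q break
lexicographically by feature name.  Distances are clipped to [0, 2] to
guard correlation rounding.

## Modelling

Ten architectures (logistic regression, MLP, k-NN, SVC, decision tree,
random forest, AdaBoost, Gaussian process, Gaussian naive Bayes, QDA)
with defaults in `data/model_grids.yaml`; logistic/SVC/tree/forest also
run with inverse-class-frequency weights.  Input features per model are
chosen by greedy sequential forward selection from 2 to 5 features,
maximizing stratified 5-fold cross-validated AUC on the training rows —
the internal CV (rather than raw training AUC) keeps the greedy
criterion from trivially overfitting.  Three feature pools: clinical
(D_mean, D50, V_thyroid, sex, stage, TSH, fT4; min-max scaled),
radiomic (filtration survivors), and their union.

Evaluation reports rank-statistic AUC with its DeLong (placement-value)
standard error and sensitivity/specificity/accuracy/F1 at probability
threshold 0.5 (F-score means F1).  The best model per pool is the one
with the highest validation F-score.  Best clinical and radiomic models
are combined as AND (positive only if both positive), OR (positive if
either), and PROBA (averaged probability, threshold chosen by Youden's J
on the *training* ROC).  Correlated AUCs are compared with DeLong's
paired test (two-sided normal p).  Permuting validation labels leaves
every fitted transform, filter output and model parameter bit-identical;
this is enforced by test.

## NTCP model forms

Three parameterized families cover published external RIHT models:
logistic (p = expit(b0 + sum b_i x_i) over named clinical covariates),
Lyman–Kutcher–Burman (p = Phi((gEUD − TD50)/(m·TD50)); with only summary
doses available gEUD := D_mean, the uniform-organ n = 1 reduction), and
a weighted mixture of logistic components.  The bundled registry
(`data/ntcp_models.yaml`) tags five models with citation DOIs; its
coefficient values are illustrative defaults to be verified against the
cited sources, and the tests exercise only the functional forms
(midpoints, slopes, monotonicity, the logit≈probit link at factor
1.702, for which the agreement is within 0.01 absolute probability).

## Problem sizes used in tests and the acceptance script

Phantom-level checks run on single phantoms (ROI ≈ 11k voxels after
resampling).  Cohort-level pipeline checks extract the original-image
panel (14 shape + 93 intensity features) for all 98 patients; the full
14-variant catalog is exercised on single phantoms.  The stability study
in the acceptance script uses a 9-patient sub-cohort with 10
perturbations; the calibrated-ICC check uses synthetic feature tables
directly (100 patients, 50 perturbations, 50 seeds).  These sizes were
chosen so each stage is exercised end to end at desk scale.

## Known limitations

* Feature definitions follow the common fixed-bin-width, distance-1,
  direction-averaged conventions documented above; other radiomics
  software may differ in aggregation, gray-level handling of empty bins,
  or mesh construction, so absolute feature values are comparable only
  under matching settings.
* The LKB gEUD reduction uses summary doses only; no DVH support.
* ComBat is parametric EB only; nonparametric and covariate-preserving
  variants are out of scope.
* The synthetic outcome is a clean logistic in three covariates; real
  RIHT risk involves follow-up time, baseline function and dose-volume
  interplay that the generator does not model.
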