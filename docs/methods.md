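# Methods note

This note documents the analytical model implemented by `pzrad`, the
numerical conventions chosen where a convention had to be fixed, the
design of the synthetic cohort generator, and the limitations of the
package.

## 1. Problem setting

The package grades peripheral-zone prostate tumors into two
aggressiveness classes — low (ISUP grade group 1) versus
intermediate/high (grade group ≥ 2) — from two MRI channels per tumor: a
T2-weighted (T2W) volume and a multi-b-value diffusion-weighted (DW)
series, with a histology-matched tumor volume of interest (VOI) on the
same voxel grid. The study design is explicitly multicenter: every step
that could leak institutional signal (intensity normalization, the
feature screen, the evaluation protocol) is built around that.

## 2. Preprocessing

### Dual-reference intensity normalization

Raw T2W intensities are not quantitative; inter-scanner differences are
modeled as an affine map per acquisition. Each scan carries two
reference-tissue intensities, fat and muscle, and normalization maps them
to nominal T2 relaxation values (fat 121 ms, muscle 40 ms) with the
unique affine transform through those two points. Because a composition
of affine maps is affine, any affine site effect is cancelled *exactly*
(to floating-point precision); this is verified as an acceptance
criterion rather than assumed.

### Outlier exclusion

Within each VOI, values outside μ ± 3σ (sample SD, ddof = 1) are excluded
in a single pass before any feature computation. The same rule is applied
to the pseudo-T2 and the ADC VOI samples. With σ = 0 (constant VOI)
nothing is excluded.

## 3. ADC mapping

The DW signal is modeled as monoexponential, S(b) = S₀·exp(−b·ADC). The
default estimator is the closed-form ordinary-least-squares fit of
ln S(b) against b restricted to the *nonzero* b-values (100, 400,
800 s/mm²); b = 0 is excluded because perfusion contaminates the low-b
signal. Nonpositive voxel signals cannot be log-transformed; such voxels
get ADC 0 and are counted in a QC field. A nonlinear least-squares
option (`method="nonlinear"`, via `scipy.optimize.curve_fit`) is provided
for comparison; on noiseless data both are exact, and their disagreement
under noise is small (tested at a 3% tolerance on adversarial triplets).

## 4. Feature extraction

Each tumor yields 51 features.

### First-order histogram features (11 per channel)

Mean, median, SD, minimum, maximum, percentiles 10/25/75/90, skewness and
kurtosis of the kept VOI values — computed once on ADC (`adc_`) and once
on normalized T2W (`t2w_`). Skewness/kurtosis are the population (biased)
moment estimators; kurtosis is excess (Fisher). A constant sample is
reported with SD 0, skewness 0, kurtosis 0 rather than an undefined
ratio.

### Texture features (29, T2W only)

Quantization is fixed-bin-number: Ng = 32 equal-width bins spanning the
min–max of the whole 3D VOI's kept values (the maximum maps to level Ng;
a constant VOI maps to level 1). Sharing the bin edges across slices is
deliberate: texture is computed per slice, but slices must live on one
grey-level scale.

Matrices are 2D, per axial slice, for the four in-plane directions
(0°, 45°, 90°, 135°) at inter-pixel distance 1. Slices are thick
(3.6 mm) relative to the in-plane resolution (0.6 mm), so
through-plane co-occurrences are not meaningful. The GLCM is
symmetric (each pair counted in both orders) and normalized; the GLRLM
counts maximal constant-level runs, with runs broken at mask boundaries.
18 co-occurrence features and 11 run-length features follow the IBSI
formulations, with logarithms base 2 and the convention 0·log 0 = 0.

Aggregation is the nested "2D average": features are computed per
(slice, direction) cell, averaged over slices within each direction, then
averaged over directions. Cells without a single valid pixel pair are
skipped entirely (not zero-filled); a VOI with no valid cell at all is an
error, not a silent zero.

Degenerate-case conventions (all exercised by tests): a constant slice
has correlation 1, IMC1 0; IMC2 is 0 when both marginal entropies vanish.

## 5. Group statistics

Per feature: tie-corrected Spearman correlation against grade group
(1–5), and a two-tailed Mann–Whitney U test between the two classes. The
Mann–Whitney p is computed by exact enumeration of all group labelings
(tie-safe) when the combined sample size is ≤ 12, otherwise by the
normal approximation with tie correction. Each p-value family is
adjusted with an own-code Benjamini–Hochberg step-up (FDR 0.05),
verified against a from-the-definition oracle.

### Institution screen

A two-way type-II ANOVA (institution × class) is fitted per feature;
features with a significant institution main effect *or* interaction at
α = 0.05 are dropped. Strictly positive features are analyzed on the log
scale, which stabilizes multiplicative (gain-like) site effects; features
spanning zero are analyzed on the raw scale. A data-driven positivity
shift (log(x − min + 1)) was deliberately rejected: anchoring the sample
minimum where the logarithm is steepest makes the residual variance
class-dependent and inflates the interaction test far above its nominal
level (observed ≈38% vs ≈2% false-drop rate on class-effect-only
synthetic features). Sites contributing a single tumor are excluded from
the screen fit with a warning. Inside the classification protocol the
screen is re-fitted on the training sites of each split only, so the
held-out site never influences feature filtering.

## 6. Classification protocol

Hold-one-institution-out: each site in turn is the external test set.
On the training sites, a linear SVM (L2-regularized squared hinge — the
`LinearSVC` objective — with inverse-class-frequency sample weights) is
selected by stratified, patient-level 10-fold cross-validation (folds
group all tumors of a patient; the fold count drops to the patient-level
minority class count when that is below 10). The misclassification cost
C (7 log-spaced values, 10⁻¹…10¹) and the feature subset (recursive
feature elimination by smallest absolute weight, one feature per step,
all subset sizes) are selected *concurrently* by minimal mean balanced
error over validation folds; ties break toward fewer features, then
smaller C. The decision threshold is the Youden-optimal cut on the
pooled out-of-fold scores of the winning configuration (ties toward the
higher threshold, i.e. higher specificity) and is transferred unchanged
to the test site.

The SVM is solved by an in-package primal Newton method with an active
set and backtracking line search, on the exact `LinearSVC` objective
(including the regularized intercept); agreement with `LinearSVC` to
~10⁻⁶ in the coefficients is a unit test. The in-package solver exists
purely for speed — the protocol refits thousands of small models.

Evaluation: AUC (trapezoidal, identical to U/(n₁n₀)) with DeLong 95%
confidence intervals; balanced accuracy, sensitivity (intermediate/high)
and specificity at the transferred threshold. The added value of texture
augmentation is tested per site by comparing the two models' correlated
AUCs, and across sites with paired t-tests on AUC and balanced accuracy.

Two calibration points deserve emphasis. First, the asymptotic DeLong
z-test is invalid on small held-out sites (a handful of cases per
class); when the minority class has fewer than 10 cases the comparison
is instead a model-exchangeability sign-swap permutation test on the
AUC difference (exactly enumerated up to 14 tumors, 5000 deterministic
draws beyond), which holds its level at any sample size. Second, the
augmentation analysis is one family of hypotheses (two paired t-tests
plus one comparison per site); the overall verdict applies
Benjamini–Hochberg across the entire family at FDR 0.05, because
testing ~8 components separately at 0.05 would flag a large fraction of
truly null cohorts by multiplicity alone. Both points are verified on
null cohorts as part of acceptance. Degenerate cases (a class absent
from a test site, zero-variance differences) are flagged, never
silently dropped.

## 7. Synthetic cohort generator

No public dataset pairs multiparametric prostate MRI with whole-mount
histology VOIs at usable scale, so the package generates cohorts that
carry precisely the structure the analysis claims to exploit:

* **Texture contrast by grade.** Tumor T2W texture is a stationary
  correlated random field: unit-variance in-plane-smoothed white noise
  (Gaussian kernel, width = correlation length) plus independent noise.
  Lower grades are smoother (longer correlation length 3.0 → 1.2 px,
  less noise 0.05 → 0.18 from GG1 to GG5); the generator's realism claim
  — longer correlation length ⇒ higher ASM after quantization — is
  itself a test, not an assumption.
* **ADC contrast by grade.** Mean VOI ADC falls from 1.5×10⁻³ (GG1) to
  0.65×10⁻³ mm²/s (GG5) with between- and within-tumor variability; the
  DW series follows S(b) = S₀·exp(−b·ADC) plus Gaussian (optionally
  Rician) noise.
* **Exact affine site effects.** Each of six institutions applies a gain
  (0.8–1.3) and offset (−15…+20) to raw T2W intensities. Reference
  regions are embedded with *exact* percentile anchors (fat 90th
  percentile, muscle 10th percentile rescaled to the nominal values), so
  normalization can be tested for exact cancellation.
* **Multicenter imbalance.** Six sites with 17/15/21/16/8/10 patients
  and per-site low-class fractions mirroring an imbalanced multicenter
  cohort (~30 low vs ~74 intermediate/high tumors overall; ~20% of
  patients contribute a second tumor).
* **Determinism.** Child generators are spawned from one `SeedSequence`
  per tumor; a (config, seed) pair reproduces the cohort bit for bit.

A `null_config()` variant removes every grade effect (identical texture,
noise and ADC parameters across grade groups) while keeping site effects
and imbalance; it calibrates the evaluation pipeline's behavior under
the null.

## 8. Numerical conventions

* Logarithms in texture features are base 2; 0·log 0 ≡ 0.
* Quantized levels are 1-based (1…Ng) in all formulas.
* Bin assignment is floor((v − min)/width) + 1 clipped to [1, Ng]; a
  value exactly on an interior bin edge belongs to the upper bin.
* Sample SD uses ddof = 1 for outlier exclusion; feature SD likewise;
  standardization inside the SVM uses ddof = 0.
* BH adjustment is monotone (step-up from the largest rank) and capped
  at 1.
* All randomness flows through explicit `numpy.random.Generator`
  objects; nothing reads global RNG state.

## 9. Limitations

* The cohort is synthetic. Absolute performance numbers characterize the
  generator plus pipeline, not clinical performance; only the *relative*
  structure (feature-set ordering, site-effect cancellation, null
  calibration) is meaningful.
* The texture model is stationary and isotropic in-plane; real tumor
  heterogeneity is neither.
* The affine site-effect model is exactly the model the normalization
  inverts. Real scanner effects include nonlinear components that
  dual-reference normalization would only approximate.
* The monoexponential ADC model ignores perfusion (beyond dropping
  b = 0) and kurtosis effects present in real DW data.
* With six sites, the paired t-tests across sites have five degrees of
  freedom; they are reported alongside per-site DeLong tests rather than
  relied on alone.
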