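# Methods

This package implements, end to end on synthetic data, a multimodal
predictor of five-year breast-cancer recurrence for women treated with
neoadjuvant chemotherapy (NAC): an imaging branch over multiparametric MRI
(DCE subtraction, ADC, Dixon water-only and fat-only volumes), a clinical
branch over tabular features, and a calibrated ensemble of the two, with a
full evaluation stack. The original study population (a private hospital
cohort) is not available, so the package ships generators that emulate its
structure; every accuracy claim made by the tests refers to recovery of the
generators' known ground truth, not to clinical performance.

## Study design emulated

Each patient has an index date at the pre-treatment MRI exam; the outcome is
recurrence (relapse or metastasis) within five years of diagnosis. Patients
diagnosed less than five years before data collection are *censored*: their
outcome is unobserved. Because exact dates are unavailable in this design,
survival regression (e.g. Cox models) is out of scope; instead censored
patients are pseudo-labeled for training and excluded from all evaluation.
Two nested cohorts exist: a clinical cohort (all patients) and an imaging
cohort (the subset with mpMRI).

## Synthetic data

**Phantoms.** A study is an axial grid (default desk-scale 24×40×48 voxels at
2.5 mm; array order z, y, x) containing two ellipsoidal breasts on an empty
background. Breast voxels are fat-dominant with probability `fat_fraction`
(default 0.55) and fibroglandular otherwise; lesions are ellipsoids inside
one breast. Each of the four volume types assigns a mean intensity per tissue
class plus additive Gaussian voxel noise — the simplest noise model that
still exercises the clustering; there are no bias fields, pharmacokinetics or
partial-volume effects, so segmentation accuracy on phantoms is an upper
bound on real-data behavior. Class means are validated to differ by ≥ 3 noise
SD per volume type, making clusters recoverable by construction. Lesions are
bright on subtraction, water-only and ADC. The high lesion ADC follows the
segmentation selection rule the pipeline implements (high-intensity areas on
ADC and water-only); clinically, cellular tumors often show *low* ADC — the
generator deliberately matches the rule rather than diffusion physics, and
this is a stated modeling choice, not an oversight. Two subtraction
timepoints are rendered with lesion enhancement scales 0.6 and 1.0; the
brightest is the annotated "selected" volume, and the slice with the most
lesion voxels is the annotated significant slice.

**Cohorts.** Clinical features (age, BMI, HER2, histological type,
progesterone, mitotic index, Ki67, grade, subtype, tumor size) are drawn with
plausible marginals and correlations (HER2-positive patients carry the HER2+
subtype code; Ki67 drives grade and the mitotic count). The outcome follows a
logistic model on standardized drivers with defaults BMI −0.8, age −0.6,
HER2 −0.8 (all protective) and log lesion volume +1.0; the intercept is
solved by bisection to hit the 16% positive rate. Censoring (40%) is assigned
independently of all features. Missing values are injected per feature at
registry-like rates (3–12%). Imaging patients' phantom lesion radii are
derived from their latent tumor volume, which ties the imaging signal to the
outcome model.

## Imaging branch

**Slice preparation.** The CNN input is the annotated significant slice of
the selected subtraction volume plus its three neighbours on each side (edge
slices are replicated — this preserves the 7-slice contract without
zero-padding artifacts). Slices are cropped to the tumor-side half at the
mid-sagittal column, flipped to a canonical orientation for right-sided
tumors, trimmed of contiguous margin rows/columns whose maximum is below 5%
of the stack maximum (one crop box for all 7 slices, from their maximum
projection), resized bilinearly to a fixed frame (512×256 production;
configurable for desk-scale runs) and min–max normalized per stack to [0,1].
Standardization is idempotent: a stack marked standardized is returned
unchanged. When slice thickness exceeds slice spacing, every ⌈thickness /
spacing⌉-th slice is retained — a committed reading of "under-sample
overlapping slices".

**Segmentation.** Two-phase fuzzy c-means (FCM), the classical alternating
scheme minimizing Σᵢⱼ uᵢⱼᵐ‖xᵢ−cⱼ‖². Phase 1 clusters every voxel on
(water, fat) intensity with k=3 (background / fat-dominant / water-dominant);
all non-background clusters count as breast — the committed reading when
both tissue clusters are strong. Phase 2 re-clusters voxels inside the
tumor-side mask on (water, ADC), or water alone when ADC is absent, again
with k=3. The lesion is the cluster(s) with the largest overlap fraction with
the "high-intensity area": in-mask voxels strictly above the 95th percentile
on every available channel. Numerical choices that matter:

- *Initialization*: deterministic farthest-point (maximin) seeding starting
  from the data medoid. Evenly spaced quantile seeding was tried first and
  discarded: with a lesion occupying ~2% of the mask all quantile centers
  land in bulk tissue and FCM converges to a local optimum that merges the
  lesion into fibroglandular tissue (Dice ≈ 0.09 instead of ≈ 1.0).
- *Strict percentile threshold*: with quantized (noise-free) intensities the
  95th percentile can equal the bulk-tissue value; `>` keeps the area to the
  genuine bright tail where `>=` would flood it.
- *Minimum overlap 0.2*: in a lesion-free breast only the noise tail touches
  the high-intensity area (observed max overlap fraction ≤ 0.11), while
  genuine lesions reach ≥ 0.36 even when large; below the floor an empty mask
  and a warning are returned.
- m = 2.0, tolerance 1e-4 on the max center shift, ≤ 300 iterations;
  defuzzification by argmax membership, ties to the lower cluster index;
  26-connectivity for all 3D region reasoning.

**Volumetric features.** On the largest connected lesion region: volume
(voxel count × voxel volume), surface area (marching-cubes isosurface at
level 0.5 scaled by spacing — voxel-face counting overestimates a sphere's
area by a known constant factor), region count, mean lesion intensity over
mean other-breast-tissue intensity on the water-suppression (fat-only
visible) Dixon volume, and spread = Σ over axes of (inclusive index extent ×
spacing). The intensity anchor is exposed in the API (the fat volume is
passed explicitly) because "water-only" and "water-suppression" name
different Dixon contrasts. The Dixon vector appends clinical metadata (age,
BMI, tumor size, grade); missing entries are imputed with training-fold
means.

**Network.** A shared-weight 2D residual trunk (stem 3×3/stride-2 conv +
2×2 max-pool; 7 residual blocks with filters 32, 64, 64, 128, 128, 256, 256,
stride-2 projections at each width increase; batch-norm and ReLU throughout)
is applied to each slice by folding the slice axis into the batch; per-slice
maps are stacked on a depth axis, passed through one 3D convolution
(3×3×3, 32 output channels) and a global average pool to 32 features. The
Dixon vector passes through dense layers (16, 16, 16, 32, 32) to 32
features; the concatenated 64 features pass through dense (64, 32, 1) to the
mpMRI logit. The backend is a small numpy layer library with manual
backpropagation written for this package (single precision; seeded He
initialization; verified against central differences), so training is
bit-deterministic given the seed. Training: Adam (lr 1e-3), class-balanced
binary cross-entropy, batches of 32, ≤ 8 epochs at desk scale with early
stopping (patience 3) on the fold-validation loss, keeping the
best-validation parameters.

## Clinical branch

Features are mean-imputed (on the raw scale) then min–max scaled to [0, 1]
with statistics from training folds only; out-of-fold values are clamped to
[0, 1] and constant columns map to zero. Candidates: random forest (500
trees, √p features), L2 logistic regression (C=1) and XGBoost (depth 4, 300
rounds, lr 0.05). Class imbalance: per-sample weights ∝ n/(2·n_class) for
forest and logistic regression; positive scale n_neg/n_pos for XGBoost. The
family with the best mean cross-validation AUC is selected.

**Attribution.** Shapley values by interventional permutation sampling
against a background dataset: features are switched from background to the
patient's values in random order and the model-output change is credited to
the switched feature. Efficiency (attributions sum to prediction minus base
value) and the null-player property hold exactly for any number of sampled
permutations, because each permutation telescopes; sampling only adds
variance to the split among correlated features. A complete-case mode
re-runs the explanation on patients without missing values.

## Cross-validation and censoring

Five folds, stratified so uncensored positive (and negative) counts differ by
at most one per fold both overall and within the imaging subset (imaging
patients are dealt first in one round-robin sequence); a patient keeps the
same fold in both cohorts because the assignment is made once on the full
cohort. Censored patients never enter validation folds; in training folds
they carry a pseudo-label (threshold 0.5) from a side model — a
class-balanced random forest on the uncensored patients' clinical features
(clinical-only, since it must label patients without imaging). The default
side model uses all uncensored patients; a stricter per-fold mode (one side
model per held-out fold, predictions averaged) is available behind a flag.
Censored patients are spread across folds ordered by side-model score so
training folds stay comparable. Audits assert, on every run: no censored
patient in any evaluation set; no patient scored by a model trained on their
fold; identical folds across cohorts; calibration preserves each model's
AUC.

## Ensemble and evaluation

Three seed variations per branch are trained (identical data, different
initialization seeds). Each variation's out-of-fold scores — never training
scores, to avoid optimism — are calibrated by Platt's method: a sigmoid
σ(a·logit(s)+b) fitted by maximum likelihood with Platt's prior-corrected
targets (N₊+1)/(N₊+2) and 1/(N₋+2). Fitting on the log-odds of the raw score
makes the identity map representable, so a well-calibrated model maps to
(a,b) ≈ (1,0). The ensemble score is the arithmetic mean of all available
calibrated scores per patient (clinical-only patients average their three
clinical scores). Holdout-style scoring reuses the CV calibrators.

Evaluation (uncensored patients only): AUC with a 2000-resample stratified
percentile bootstrap CI (desk-scale runs use 500); operating points at target
sensitivities 0.87/0.90/0.93 — the largest threshold whose sensitivity meets
the target, which maximizes specificity among qualifying thresholds — with
specificity, F1, balanced accuracy, PPV and NPV; McNemar tests on discordant
pairs (exact binomial below 25 discordant pairs, continuity-corrected χ²
otherwise — standard small-sample practice) against a Bonferroni threshold
α/12 = 0.0042; and a subgroup scan over all 432 = 4·4·3·3·3 combinations of
age band (≤50, 50–60, ≥60, missing; 50.0 falls in the first band and 60.0 in
the last, since the nominal bands overlap at their boundaries), cancer
subtype (luminal, TNBC, HER2+, missing), histological type (NST, other,
missing), grade (I–II, III, missing) and Ki67 (≤15%, >15%, missing). A cell
is analyzed iff it holds ≥ 10 patients with both outcomes present; analyzed
cells carry bootstrap AUC CIs and are reported sorted by AUC.

## Problem sizes and determinism

The default desk-scale profile runs the whole study — 800-patient cohort,
200 imaging patients with phantoms at 24×40×48 voxels, CNN slices at 32×16,
three variations per branch — in a few minutes on one CPU; unit tests pin
the 512×256 production slice frame separately. All randomness flows from a
single integer seed through `numpy.random.default_rng`; repeated runs are
bit-identical, including trained network weights.

## Known limitations

- Phantoms have no intensity inhomogeneity, motion, or anatomy beyond
  ellipsoids; FCM results on them do not predict clinical segmentation
  accuracy.
- The censoring generator is independent of features; the pseudo-label
  machinery is therefore tested under censoring-at-random only.
- At the desk-scale slice resolution the CNN contributes little beyond the
  Dixon head; the architecture is verified structurally (widths, sharing,
  equivariances, gradient checks) rather than by image-feature learning at
  production resolution.
- Platt calibration is fitted per variation on modest out-of-fold sample
  sizes; its regularized targets keep it stable but slightly conservative.
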