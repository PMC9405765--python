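# mmrecur

Multimodal prediction of five-year breast-cancer recurrence for women
treated with neoadjuvant chemotherapy (NAC), rebuilt as a tested pipeline
over synthetic data.

## The problem

Before NAC begins, a clinician has a clinical record (age, BMI,
immunohistochemistry, tumor measurements) and a multiparametric MRI exam
(DCE subtraction, ADC, and Dixon water-only/fat-only volumes). The question
is whether the cancer will recur — locally or as metastasis — within five
years of diagnosis. Two complications shape the modelling: patients
diagnosed recently are *censored* (their five-year outcome is unobserved),
and only a subset of patients has imaging.

The pipeline answers with a two-branch model:

- **mpMRI branch** — two-phase fuzzy c-means segmentation of the Dixon/ADC
  volumes into breast and lesion masks; five volumetric lesion features
  (volume mm³, surface area mm², region count, relative lesion intensity on
  the water-suppression Dixon volume, spread mm); a shared-weight residual
  2D CNN over 7 subtraction slices fused with a dense head over the
  volumetric features into the mpMRI score.
- **Clinical branch** — mean-imputed, [0,1]-scaled tabular features into the
  best of {random forest, logistic regression, XGBoost} under
  class-imbalance weighting, explained with Shapley attributions.

Each branch is trained in censoring-aware stratified 5-fold CV (censored
patients train with side-model pseudo-labels and never enter evaluation) in
three seed variations; the up-to-six scores per patient are Platt-calibrated
on out-of-fold predictions and averaged ("mean of all available scores").
Evaluation: AUC with stratified bootstrap CIs, metrics at sensitivity
operating points 0.87/0.90/0.93, McNemar tests with Bonferroni correction
(α/12 = 0.0042), and an AUC scan over 432 prognostic subgroups.

Because the original hospital cohort is private, the package ships
generators for phantom mpMRI studies (ellipsoidal breasts and lesions with
separable tissue intensities and known geometry) and clinical cohorts with a
known logistic risk structure (risk decreasing in BMI, age and HER2 status,
increasing in lesion volume; ~16% positive, ~40% censored). Everything
downstream is validated by recovering what the generators embedded. See
`docs/methods.md` for the model details and limitations.

## Worked example

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_segment_features.py --seed 1
python analysis/03_full_study.py --seed 1
```

`01` writes the cohort (`results/cohort.csv`) and a few example phantom
studies as NIfTI + manifest under `scratch/studies/`, printing

```
cohort: 800 patients, 200 with imaging
  uncensored: 478  positive rate (uncensored): 0.169
  censoring rate: 0.403
```

`02` segments the example studies and recovers their geometry exactly on
these clean phantoms:

```
P00005: Dice 1.000  volume 2384 mm^3  surface 931 mm^2  regions 1  spread 50 mm
```

(the embedded lesion is a 2376 mm³ sphere; the voxelized mask carries the
0.3% volume discretization error). `03` runs the full study — segmentation
and CNN training for all 200 imaging patients, clinical model selection,
calibration, ensembling, evaluation — in a few minutes on one CPU and
prints, at seed 1:

```
clinical family selected: xgboost
AUC [95% CI] on the imaging cohort (uncensored, out-of-fold):
  mpmri                  0.714 [0.600, 0.813]
  clinical               0.755 [0.620, 0.880]
  ensemble               0.773 [0.641, 0.889]
  clinical_full_cohort   0.756 [0.692, 0.813]
top-5 clinical features by mean |attribution|:
  tumor_size_mm  bmi  age  ki67  histological_type
subgroup scan: 13 of 432 candidate cells analyzed
McNemar: 0 of 6 comparisons significant at p < 0.0042
```

The ensemble beats both single modalities, and the attribution ranking
surfaces the generator's true risk drivers (BMI, age) at the top — the
qualitative behavior the method is designed to show. Result tables land in
`results/`.

## Layout

```
src/mmrecur/     library: synth, prep, segment, features, nn, mpmri,
                 clinical, shapley, cv, ensemble, evaluate, io, pipeline
analysis/        numbered narrative drivers over the library
tests/           pytest suite incl. end-to-end acceptance checks
scripts/         acceptance.py
docs/methods.md  model, parameters, numerical choices, limitations
```
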