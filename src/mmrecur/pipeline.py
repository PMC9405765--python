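"""End-to-end orchestration: cohort + phantoms -> branch models -> ensemble
-> evaluation.

The pipeline mirrors the study design: a clinical cohort with a censored
fraction and an imaging subset, censoring-aware 5-fold cross-validation with
side-model pseudo-labels, three seed variations per branch, Platt calibration
of out-of-fold scores, mean-of-available-scores ensembling, and the full
evaluation stack. The imaging profile controls the phantom grid and CNN
input size so the whole pipeline runs at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import clinical as clin
from . import cv as cvmod
from . import ensemble as ens
from . import evaluate as ev
from .features import DIXON_METADATA_FIELDS, DIXON_VECTOR_FIELDS, features_from_masks
from .mpmri import NetworkSpec, train_mpmri
from .prep import prepare_stack
from .segment import segment_study
from .shapley import AttributionReport
from .synth import CohortSpec, PhantomSpec, generate_cohort, generate_phantom, phantom_spec_for_patient

SENSITIVITY_TARGETS = (0.87, 0.90, 0.93)


@dataclass
class ImagingProfile:
    """Desk-scale image sizes; the production slice frame is 512 x 256."""

    phantom_shape: tuple[int, int, int] = (24, 40, 48)
    phantom_spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    slice_shape: tuple[int, int] = (32, 16)
    epochs: int = 10
    patience: int = 4
    lr: float = 1e-3
    batch_size: int = 16


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    plan: cvmod.FoldPlan
    clinical_family: str
    clinical_tables: list[pd.DataFrame]
    mpmri_tables: list[pd.DataFrame]
    ensemble_scores: pd.DataFrame
    aucs: dict[str, tuple[float, tuple[float, float]]]
    operating_points: pd.DataFrame
    mcnemar: pd.DataFrame
    attribution: AttributionReport
    subgroups: list[ev.SubgroupCell]
    imaging_features: pd.DataFrame
    audits: dict[str, bool] = field(default_factory=dict)


def build_imaging_data(
    cohort: pd.DataFrame,
    profile: ImagingProfile,
    seed: int = 0,
) -> tuple[list[str], np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Phantoms -> slice stacks + Dixon-ADC vectors for the imaging subset.

    Returns (ids, stacks (N,7,H,W), dixon table indexed by patient with the
    raw (possibly NaN) vector entries, volumetric feature table).
    """
    base = PhantomSpec(shape=profile.phantom_shape, spacing_mm=profile.phantom_spacing)
    img = cohort[cohort["has_imaging"] == 1]
    ids, stacks, dixon_rows, feat_rows = [], [], [], []
    for i, (_, row) in enumerate(img.iterrows()):
        spec = phantom_spec_for_patient(row, base=base, seed=seed * 100003 + i)
        study, _truth = generate_phantom(spec)
        study.patient_id = row["patient_id"]
        stack = prepare_stack(study, target_shape=profile.slice_shape)
        masks, _report = segment_study(study, seed=spec.seed)
        vf = features_from_masks(masks.lesion, study.fat, masks.tumor_side, study.spacing_mm)
        entry = vf.as_dict()
        feat_rows.append({"patient_id": row["patient_id"], **entry})
        for f in DIXON_METADATA_FIELDS:
            entry[f] = row[f]
        dixon_rows.append(entry)
        ids.append(row["patient_id"])
        stacks.append(stack.slices)
    dixon = pd.DataFrame(dixon_rows, index=ids)[list(DIXON_VECTOR_FIELDS)]
    return ids, np.asarray(stacks), dixon, pd.DataFrame(feat_rows)


def run_pipeline(
    seed: int = 0,
    cohort_spec: CohortSpec | None = None,
    profile: ImagingProfile | None = None,
    n_variations: int = 3,
    n_boot: int = 500,
    shap_permutations: int = 8,
) -> PipelineResult:
    """Run the full study on one synthetic cohort. Deterministic given seed."""
    profile = profile or ImagingProfile()
    cohort_spec = cohort_spec or CohortSpec(seed=seed)
    cohort = generate_cohort(replace(cohort_spec, seed=seed))

    # censoring handling and folds
    pseudo = cvmod.pseudo_label(cohort, seed=seed)
    plan = cvmod.make_folds(cohort, k=5, seed=seed, side_scores=pseudo.scores)
    labels_of = {
        p: int(o)
        for p, o, c in zip(cohort["patient_id"], cohort["outcome"], cohort["censored"])
        if c == 0
    }

    # imaging branch
    ids, stacks, dixon, feat_table = build_imaging_data(cohort, profile, seed=seed)
    train_lab = cvmod.training_labels(cohort, pseudo)
    spec = NetworkSpec(
        input_shape=profile.slice_shape,
        dixon_dim=dixon.shape[1],
        lr=profile.lr,
        epochs=profile.epochs,
        patience=profile.patience,
        batch_size=profile.batch_size,
        seed=seed,
    )
    mpmri_tables = []
    for v in range(n_variations):
        _models, scores, _logs = train_mpmri(
            ids, stacks, dixon, cohort, plan.assignment, train_lab,
            replace(spec, seed=seed * 10 + v),
        )
        mpmri_tables.append(scores)

    # clinical branch: select family once, then seed variations of the winner
    selection = clin.train_select(cohort, plan, pseudo, seed=seed)
    clinical_results = [
        clin.train_family(selection.best_family, cohort, plan, pseudo, seed=seed * 10 + v)
        for v in range(n_variations)
    ]
    clinical_tables = [r.scores for r in clinical_results]

    # calibration (out-of-fold scores only) and fusion
    calibrated = []
    audits: dict[str, bool] = {}
    for tab in clinical_tables + mpmri_tables:
        ct, _params = ens.calibrate_scores(tab, labels_of)
        y = np.array([labels_of[p] for p in ct["patient_id"]])
        ens.audit_calibration_preserves_auc(
            ct["raw_score"].to_numpy(), ct["calibrated"].to_numpy(), y
        )
        calibrated.append(ct)
    audits["calibration_preserves_auc"] = True
    ensemble_scores = ens.combine(calibrated)

    # audits on every score table
    for tab in calibrated:
        cvmod.audit_evaluation_purity(tab, cohort)
        cvmod.audit_no_fold_leakage(tab, plan)
    cvmod.audit_evaluation_purity(
        ensemble_scores.rename(columns={"score": "raw_score"}), cohort
    )
    cvmod.audit_cross_cohort(plan, cohort["patient_id"].tolist(), ids)
    audits["evaluation_purity"] = True
    audits["no_fold_leakage"] = True
    audits["cross_cohort_folds"] = True

    # evaluation on the imaging (MRI+Clinical) cohort, uncensored only
    img_unc = [p for p in ids if p in labels_of]
    y_img = np.array([labels_of[p] for p in img_unc])

    def scores_on(table: pd.DataFrame, col: str) -> np.ndarray:
        m = dict(zip(table["patient_id"], table[col]))
        return np.array([m[p] for p in img_unc])

    clinical_comb = ens.combine(calibrated[:n_variations])
    mpmri_comb = ens.combine(calibrated[n_variations:])
    s_clin = scores_on(clinical_comb, "score")
    s_mri = scores_on(mpmri_comb, "score")
    s_ens = scores_on(ensemble_scores, "score")

    aucs = {
        "mpmri": ev.auc_ci(s_mri, y_img, n_boot=n_boot, seed=seed),
        "clinical": ev.auc_ci(s_clin, y_img, n_boot=n_boot, seed=seed),
        "ensemble": ev.auc_ci(s_ens, y_img, n_boot=n_boot, seed=seed),
    }
    # clinical model on its full cohort as well
    full_ids = [p for p in labels_of if p in set(clinical_comb["patient_id"])]
    y_full = np.array([labels_of[p] for p in full_ids])
    m = dict(zip(clinical_comb["patient_id"], clinical_comb["score"]))
    aucs["clinical_full_cohort"] = ev.auc_ci(
        np.array([m[p] for p in full_ids]), y_full, n_boot=n_boot, seed=seed
    )

    op_rows, preds = [], {}
    for name, s in [("mpmri", s_mri), ("clinical", s_clin), ("ensemble", s_ens)]:
        for t in SENSITIVITY_TARGETS:
            opm = ev.metrics_at_sensitivity(s, y_img, t)
            preds[(name, t)] = (s >= opm.threshold).astype(int)
            op_rows.append(
                {
                    "model": name,
                    "target_sensitivity": t,
                    "achieved_sensitivity": opm.achieved_sensitivity,
                    "specificity": opm.specificity,
                    "f1": opm.f1,
                    "balanced_accuracy": opm.balanced_accuracy,
                    "ppv": opm.ppv,
                    "npv": opm.npv,
                }
            )
    mc_rows = []
    for name in ("mpmri", "clinical"):
        for t in SENSITIVITY_TARGETS:
            p, sig = ev.mcnemar_bonferroni(preds[(name, t)], preds[("ensemble", t)], y_img)
            mc_rows.append({"comparison": f"{name}_vs_ensemble", "target": t, "p": p, "significant": sig})

    attribution = clin.explain(
        clinical_results[0], cohort, n_permutations=shap_permutations, seed=seed
    )
    subgroups = ev.subgroup_scan(cohort, ensemble_scores, n_boot=min(n_boot, 500), seed=seed)

    return PipelineResult(
        cohort=cohort,
        plan=plan,
        clinical_family=selection.best_family,
        clinical_tables=clinical_tables,
        mpmri_tables=mpmri_tables,
        ensemble_scores=ensemble_scores,
        aucs=aucs,
        operating_points=pd.DataFrame(op_rows),
        mcnemar=pd.DataFrame(mc_rows),
        attribution=attribution,
        subgroups=subgroups,
        imaging_features=feat_table,
        audits=audits,
    )
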