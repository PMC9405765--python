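"""Censoring-aware, cohort-correlated stratified cross-validation.

Patients whose five-year outcome is unobserved (diagnosed less than five
years before data collection, ``censored=1``) cannot be evaluated, but their
features are still useful: they are excluded from every validation fold and
kept in training folds with a pseudo-label predicted by a side model — a
random forest trained on the uncensored patients' clinical features.

Folds are stratified so uncensored positives (and negatives) are spread as
evenly as possible, imaging patients are balanced across folds, and a patient
keeps the same fold in the imaging and clinical cohorts (the imaging cohort
is a subset of the clinical cohort and simply inherits the assignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .synth import CLINICAL_FEATURES


class FoldError(ValueError):
    pass


@dataclass
class FoldPlan:
    """Patient -> fold assignment (folds numbered 1..k)."""

    assignment: dict[str, int]
    k: int
    seed: int

    def fold_of(self, patient_id: str) -> int:
        return self.assignment[patient_id]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"patient_id": list(self.assignment), "fold": list(self.assignment.values())}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, k: int = 5, seed: int = -1) -> "FoldPlan":
        df = pd.read_csv(path)
        return cls(
            assignment=dict(zip(df["patient_id"], df["fold"].astype(int))),
            k=int(df["fold"].max()) if k is None else k,
            seed=seed,
        )

    def counts(self, cohort: pd.DataFrame) -> pd.DataFrame:
        df = cohort.assign(fold=cohort["patient_id"].map(self.assignment))
        unc = df[df["censored"] == 0]
        out = pd.DataFrame(
            {
                "positives": unc[unc["outcome"] == 1].groupby("fold").size(),
                "negatives": unc[unc["outcome"] == 0].groupby("fold").size(),
                "censored": df[df["censored"] == 1].groupby("fold").size(),
            }
        ).fillna(0).astype(int)
        return out.reindex(range(1, self.k + 1), fill_value=0)


def _deal(ids: list[str], k: int, start: int, assignment: dict[str, int]) -> None:
    for i, pid in enumerate(ids):
        assignment[pid] = 1 + (start + i) % k


def make_folds(
    cohort: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    side_scores: dict[str, float] | None = None,
) -> FoldPlan:
    """Build a stratified k-fold plan over the full cohort.

    Uncensored patients are dealt round-robin within outcome class, imaging
    patients first, so per-fold positive (and negative) counts differ by at
    most one both overall and within the imaging subset. Censored patients
    are dealt ordered by side-model score when available (so training folds
    stay comparable), otherwise shuffled. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    unc = cohort[cohort["censored"] == 0]
    n_pos = int((unc["outcome"] == 1).sum())
    if n_pos < k:
        raise FoldError(f"insufficient uncensored positives for {k}-fold CV: {n_pos}")

    assignment: dict[str, int] = {}

    def shuffled(mask: pd.Series) -> list[str]:
        ids = cohort.loc[mask, "patient_id"].tolist()
        rng.shuffle(ids)
        return ids

    for label in (1, 0):
        seq = shuffled(
            (cohort["censored"] == 0) & (cohort["outcome"] == label) & (cohort["has_imaging"] == 1)
        ) + shuffled(
            (cohort["censored"] == 0) & (cohort["outcome"] == label) & (cohort["has_imaging"] == 0)
        )
        _deal(seq, k, int(rng.integers(k)), assignment)

    cens = cohort[cohort["censored"] == 1]
    if side_scores is not None:
        for img in (1, 0):
            sub = cens[cens["has_imaging"] == img]
            ids = sorted(sub["patient_id"], key=lambda p: side_scores.get(p, 0.5))
            _deal(ids, k, int(rng.integers(k)), assignment)
    else:
        for img in (1, 0):
            seq = shuffled((cohort["censored"] == 1) & (cohort["has_imaging"] == img))
            _deal(seq, k, int(rng.integers(k)), assignment)

    return FoldPlan(assignment=assignment, k=k, seed=seed)


@dataclass
class PseudoLabelSet:
    """Side-model outputs for the censored patients."""

    labels: dict[str, int]
    scores: dict[str, float]
    threshold: float = 0.5
    feature_names: tuple[str, ...] = field(default=CLINICAL_FEATURES)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "patient_id": list(self.labels),
                "pseudo_label": list(self.labels.values()),
                "side_model_score": [self.scores[p] for p in self.labels],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, threshold: float = 0.5) -> "PseudoLabelSet":
        df = pd.read_csv(path)
        return cls(
            labels=dict(zip(df["patient_id"], df["pseudo_label"].astype(int))),
            scores=dict(zip(df["patient_id"], df["side_model_score"])),
            threshold=threshold,
        )


def _clinical_matrix(df: pd.DataFrame, means: pd.Series | None = None) -> tuple[np.ndarray, pd.Series]:
    X = df.loc[:, list(CLINICAL_FEATURES)].astype(float)
    if means is None:
        means = X.mean()
    return X.fillna(means).to_numpy(), means


def pseudo_label(
    cohort: pd.DataFrame,
    seed: int = 0,
    threshold: float = 0.5,
    n_estimators: int = 300,
    fold_plan: FoldPlan | None = None,
) -> PseudoLabelSet:
    """Pseudo-labels for censored patients from a clinical-feature side model.

    The side model is a class-weight-balanced random forest trained on all
    uncensored patients (default). When ``fold_plan`` is given, a stricter
    per-fold mode is used: the label applied to a censored patient is the
    mean prediction of k side models, each trained with one fold of
    uncensored patients held out. A cohort with no censored patients yields
    an empty set.
    """
    unc = cohort[cohort["censored"] == 0]
    cens = cohort[cohort["censored"] == 1]
    if len(cens) == 0:
        return PseudoLabelSet(labels={}, scores={}, threshold=threshold)

    X_unc, means = _clinical_matrix(unc)
    y_unc = unc["outcome"].astype(int).to_numpy()
    X_cens, _ = _clinical_matrix(cens, means)

    def fit(X, y, s):
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            class_weight="balanced",
            random_state=s,
            n_jobs=1,
        )
        rf.fit(X, y)
        return rf

    if fold_plan is None:
        rf = fit(X_unc, y_unc, seed)
        scores = rf.predict_proba(X_cens)[:, 1]
    else:
        folds = unc["patient_id"].map(fold_plan.assignment).to_numpy()
        preds = []
        for f in range(1, fold_plan.k + 1):
            rf = fit(X_unc[folds != f], y_unc[folds != f], seed + f)
            preds.append(rf.predict_proba(X_cens)[:, 1])
        scores = np.mean(preds, axis=0)

    ids = cens["patient_id"].tolist()
    return PseudoLabelSet(
        labels={p: int(s >= threshold) for p, s in zip(ids, scores)},
        scores={p: float(s) for p, s in zip(ids, scores)},
        threshold=threshold,
    )


def training_labels(cohort: pd.DataFrame, pseudo: PseudoLabelSet) -> dict[str, int]:
    """Observed outcome for uncensored patients, pseudo-label for censored."""
    out: dict[str, int] = {}
    for _, row in cohort.iterrows():
        pid = row["patient_id"]
        if row["censored"] == 0:
            out[pid] = int(row["outcome"])
        else:
            out[pid] = pseudo.labels[pid]
    return out


def audit_evaluation_purity(score_rows: pd.DataFrame, cohort: pd.DataFrame) -> None:
    """Assert no censored patient appears in any evaluation (out-of-fold) set."""
    censored_ids = set(cohort.loc[cohort["censored"] == 1, "patient_id"])
    bad = set(score_rows["patient_id"]) & censored_ids
    if bad:
        raise AssertionError(f"censored patients in evaluation set: {sorted(bad)[:5]}")


def audit_no_fold_leakage(score_rows: pd.DataFrame, plan: FoldPlan) -> None:
    """Assert every out-of-fold score comes from the patient's own held-out fold.

    A fold-f model is trained on all folds except f, so a score is leakage-free
    iff the scored patient's assigned fold equals the producing fold.
    """
    folds = score_rows["patient_id"].map(plan.assignment)
    if not (folds.to_numpy() == score_rows["fold"].to_numpy()).all():
        raise AssertionError("a patient was scored by a model trained on their fold")


def audit_cross_cohort(plan: FoldPlan, clinical_ids: list[str], imaging_ids: list[str]) -> None:
    """Assert imaging patients hold identical folds in both cohorts."""
    missing = [p for p in imaging_ids if p not in plan.assignment]
    if missing:
        raise AssertionError(f"imaging patients without fold assignment: {missing[:5]}")
    if not set(imaging_ids) <= set(clinical_ids):
        raise AssertionError("imaging cohort is not a subset of the clinical cohort")
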