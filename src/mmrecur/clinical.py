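"""The clinical (tabular) branch: preprocessing, three candidate classifiers
with imbalance handling, cross-validated model selection, and Shapley
explanations.

Candidates are random forest, L2 logistic regression and gradient boosting
(XGBoost). Features are mean-imputed and min–max scaled to [0, 1] with
statistics fitted on training folds only; the random forest and logistic
regression receive per-sample weights inversely proportional to class
frequencies, and the gradient booster a positive-class scale equal to the
negative/positive count ratio. The family with the best mean cross-validation
AUC is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from xgboost import XGBClassifier

from .cv import FoldPlan, PseudoLabelSet, training_labels
from .evaluate import auc
from .shapley import AttributionReport, shapley_values
from .synth import CLINICAL_FEATURES

FAMILIES = ("random_forest", "logistic_regression", "xgboost")


class Preprocessor:
    """Mean imputation (raw scale) followed by min–max scaling to [0, 1].

    Statistics are fitted on training-fold rows only. Transformed validation
    values outside [0, 1] are clamped; constant columns map to zero.
    """

    def __init__(self, feature_names: tuple[str, ...] = CLINICAL_FEATURES):
        self.feature_names = tuple(feature_names)
        self.means_: pd.Series | None = None
        self.min_: np.ndarray | None = None
        self.span_: np.ndarray | None = None

    def fit(self, df: pd.DataFrame) -> "Preprocessor":
        X = df.loc[:, list(self.feature_names)].astype(float)
        all_missing = X.columns[X.isna().all()]
        if len(all_missing):
            raise ValueError(f"column(s) entirely missing in training folds: {list(all_missing)}")
        self.means_ = X.mean()
        filled = X.fillna(self.means_).to_numpy()
        self.min_ = filled.min(axis=0)
        span = filled.max(axis=0) - self.min_
        self.span_ = np.where(span > 0, span, np.inf)  # constant column -> 0
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        if self.means_ is None:
            raise RuntimeError("Preprocessor not fitted")
        X = df.loc[:, list(self.feature_names)].astype(float)
        filled = X.fillna(self.means_).to_numpy()
        scaled = (filled - self.min_) / self.span_
        return np.clip(scaled, 0.0, 1.0)

    def fit_transform(self, df: pd.DataFrame) -> np.ndarray:
        return self.fit(df).transform(df)


def class_weights(labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-sample weights ∝ n_total / (2 n_class) and the positive scale n_neg/n_pos."""
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    n = labels.size
    w = np.where(labels == 1, n / (2.0 * n_pos), n / (2.0 * n_neg))
    return w, n_neg / n_pos


def make_classifier(family: str, labels: np.ndarray, seed: int):
    """Instantiate one candidate family with its imbalance handling."""
    _, pos_scale = class_weights(labels)
    if family == "random_forest":
        return RandomForestClassifier(
            n_estimators=500, max_features="sqrt", random_state=seed, n_jobs=1
        )
    if family == "logistic_regression":
        return LogisticRegression(C=1.0, max_iter=2000, random_state=seed)  # L2 default
    if family == "xgboost":
        return XGBClassifier(
            max_depth=4,
            n_estimators=300,
            learning_rate=0.05,
            scale_pos_weight=pos_scale,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    raise ValueError(f"unknown family {family!r}")


def _fit_family(family: str, model, X: np.ndarray, y: np.ndarray) -> None:
    if family == "xgboost":
        model.fit(X, y)  # imbalance via scale_pos_weight
    else:
        w, _ = class_weights(y)
        model.fit(X, y, sample_weight=w)


@dataclass
class ClinicalCvResult:
    """Per-family fold models, preprocessors and out-of-fold scores."""

    family: str
    fold_models: dict[int, object]
    fold_preprocessors: dict[int, Preprocessor]
    scores: pd.DataFrame  # patient_id, modality, fold, raw_score
    mean_auc: float


def train_family(
    family: str,
    cohort: pd.DataFrame,
    plan: FoldPlan,
    pseudo: PseudoLabelSet,
    seed: int = 0,
) -> ClinicalCvResult:
    """5-fold cross-validated training of one classifier family.

    Training folds contain uncensored patients with observed labels plus
    censored patients with side-model pseudo-labels; validation folds contain
    uncensored patients only. Scaler/imputer statistics come from the
    training folds of each iteration.
    """
    labels = training_labels(cohort, pseudo)
    df = cohort.assign(fold=cohort["patient_id"].map(plan.assignment))
    rows = []
    models: dict[int, object] = {}
    preps: dict[int, Preprocessor] = {}
    fold_aucs = []
    for f in range(1, plan.k + 1):
        train_df = df[df["fold"] != f]
        val_df = df[(df["fold"] == f) & (df["censored"] == 0)]
        prep = Preprocessor().fit(train_df)
        X_tr = prep.transform(train_df)
        y_tr = np.array([labels[p] for p in train_df["patient_id"]])
        model = make_classifier(family, y_tr, seed * 1000 + f)
        _fit_family(family, model, X_tr, y_tr)
        models[f] = model
        preps[f] = prep
        if len(val_df):
            s = model.predict_proba(prep.transform(val_df))[:, 1]
            y_va = val_df["outcome"].astype(int).to_numpy()
            if len(np.unique(y_va)) == 2:
                fold_aucs.append(auc(s, y_va))
            for p, sc in zip(val_df["patient_id"], s):
                rows.append(
                    {"patient_id": p, "modality": "clinical", "fold": f, "raw_score": float(sc)}
                )
    return ClinicalCvResult(
        family=family,
        fold_models=models,
        fold_preprocessors=preps,
        scores=pd.DataFrame(rows),
        mean_auc=float(np.mean(fold_aucs)) if fold_aucs else float("nan"),
    )


@dataclass
class SelectionResult:
    best_family: str
    per_family: dict[str, ClinicalCvResult] = field(default_factory=dict)

    @property
    def best(self) -> ClinicalCvResult:
        return self.per_family[self.best_family]


def train_select(
    cohort: pd.DataFrame,
    plan: FoldPlan,
    pseudo: PseudoLabelSet,
    seed: int = 0,
    families: tuple[str, ...] = FAMILIES,
) -> SelectionResult:
    """Train all candidate families and select by mean cross-validation AUC."""
    per_family = {fam: train_family(fam, cohort, plan, pseudo, seed) for fam in families}
    best = max(families, key=lambda fam: per_family[fam].mean_auc)
    return SelectionResult(best_family=best, per_family=per_family)


def explain(
    result: ClinicalCvResult,
    cohort: pd.DataFrame,
    n_permutations: int = 10,
    n_background: int = 25,
    seed: int = 0,
    complete_cases_only: bool = False,
) -> AttributionReport:
    """Shapley attribution report for a trained clinical family.

    Explains the fold-1 model on the uncensored cohort (each patient through
    the fold-fitted preprocessing), with a background of ``n_background``
    training-distribution rows. ``complete_cases_only`` restricts the
    explained patients to those without any missing clinical value (the
    missing-value robustness re-run).
    """
    f = min(result.fold_models)
    model, prep = result.fold_models[f], result.fold_preprocessors[f]
    df = cohort[cohort["censored"] == 0]
    if complete_cases_only:
        df = df[df.loc[:, list(CLINICAL_FEATURES)].notna().all(axis=1)]
    X = prep.transform(df)
    rng = np.random.default_rng(seed)
    background = X[rng.choice(len(X), size=min(n_background, len(X)), replace=False)]
    return shapley_values(
        lambda M: model.predict_proba(M)[:, 1],
        X,
        background,
        n_permutations=n_permutations,
        seed=seed,
        feature_names=list(CLINICAL_FEATURES),
    )
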