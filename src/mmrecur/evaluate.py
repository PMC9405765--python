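"""Evaluation stack: bootstrap-CI ROC AUC, fixed-sensitivity operating
points, McNemar tests with Bonferroni correction, and the prognostic
subgroup scan.

All evaluation is performed on uncensored patients only (the censoring-aware
CV design guarantees evaluation sets contain no censored patient; the audits
in :mod:`mmrecur.cv` enforce it).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

#: Discordant-pair count at or above which McNemar switches from the exact
#: binomial form to the continuity-corrected chi-square form.
MCNEMAR_EXACT_LIMIT = 25


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC: probability a random positive outranks a random negative
    (ties counted 1/2)."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Point AUC with a percentile bootstrap CI over patients.

    Resampling is stratified by outcome (positives and negatives resampled
    separately with replacement) so every replicate has both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    point = auc(scores, labels)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    stats = np.empty(n_boot)
    for i in range(n_boot):
        p = rng.choice(pos, size=len(pos), replace=True)
        n = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([p, n])
        stats[i] = roc_auc_score(labels[idx], scores[idx])
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return point, (float(lo), float(hi))


@dataclass
class OperatingPointMetrics:
    """Confusion-matrix metrics at a fixed-sensitivity operating point."""

    target_sensitivity: float
    achieved_sensitivity: float
    threshold: float
    specificity: float
    f1: float
    balanced_accuracy: float
    ppv: float
    npv: float
    warning: str | None = None


def metrics_at_sensitivity(
    scores: np.ndarray, labels: np.ndarray, target: float
) -> OperatingPointMetrics:
    """Metrics at the largest threshold whose sensitivity meets the target.

    A patient is predicted positive when ``score >= threshold``; the largest
    qualifying threshold minimizes predicted positives, i.e. maximizes
    specificity among thresholds reaching the target sensitivity. The
    achieved sensitivity is reported (score granularity can overshoot the
    target).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    warning = None
    thresholds = np.unique(scores)[::-1]  # descending
    chosen = None
    for t in thresholds:
        sens = float(((scores >= t) & (labels == 1)).sum()) / n_pos
        if sens >= target:
            chosen = t
            break
    if chosen is None:  # unreachable in principle only for empty input
        chosen = thresholds[-1]
        warning = "target sensitivity unreachable"
    pred = scores >= chosen
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = n_pos - tp
    tn = n_neg - fp
    sens = tp / n_pos
    spec = tn / n_neg
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    f1 = 2 * ppv * sens / (ppv + sens) if ppv + sens else 0.0
    if sens < target:
        warning = "target sensitivity unreachable"
    return OperatingPointMetrics(
        target_sensitivity=target,
        achieved_sensitivity=sens,
        threshold=float(chosen),
        specificity=spec,
        f1=f1,
        balanced_accuracy=(sens + spec) / 2.0,
        ppv=ppv,
        npv=npv,
        warning=warning,
    )


def mcnemar_bonferroni(
    preds_a: np.ndarray,
    preds_b: np.ndarray,
    labels: np.ndarray,
    n_tests: int = 12,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Paired McNemar test with Bonferroni-corrected significance.

    Discordant counts: ``b`` = A correct & B wrong, ``c`` = A wrong & B
    correct. The exact binomial form is used when ``b + c < 25``, the
    continuity-corrected chi-square otherwise. Returns ``(p, p < alpha /
    n_tests)``.
    """
    preds_a = np.asarray(preds_a).astype(int)
    preds_b = np.asarray(preds_b).astype(int)
    labels = np.asarray(labels).astype(int)
    if not (len(preds_a) == len(preds_b) == len(labels)):
        raise ValueError("prediction and label arrays must have equal length")
    a_correct = preds_a == labels
    b_correct = preds_b == labels
    b = int((a_correct & ~b_correct).sum())
    c = int((~a_correct & b_correct).sum())
    if b + c == 0:  # identical error patterns: no evidence of a difference
        return 1.0, False
    table = [[0, b], [c, 0]]
    exact = (b + c) < MCNEMAR_EXACT_LIMIT
    res = _sm_mcnemar(table, exact=exact, correction=True)
    p = float(min(res.pvalue, 1.0))
    return p, p < alpha / n_tests


# ---------------------------------------------------------------------------
# subgroup scan
# ---------------------------------------------------------------------------

#: Subgroup factor levels: name -> list of (level label, membership function).
#: Each factor includes a "missing" level; age-band boundaries: 50.0 belongs
#: to the <=50 band and 60.0 to the >=60 band.
SUBGROUP_FACTORS: dict[str, list[tuple[str, callable]]] = {
    "age": [
        ("<=50", lambda d: d["age"] <= 50),
        ("50-60", lambda d: (d["age"] > 50) & (d["age"] < 60)),
        (">=60", lambda d: d["age"] >= 60),
        ("missing", lambda d: d["age"].isna()),
    ],
    "cancer_subtype": [
        ("luminal", lambda d: d["cancer_subtype"].isin([2, 3])),
        ("TNBC", lambda d: d["cancer_subtype"] == 1),
        ("HER2+", lambda d: d["cancer_subtype"] == 4),
        ("missing", lambda d: d["cancer_subtype"].isna()),
    ],
    "histological_type": [
        ("NST", lambda d: d["histological_type"] == 1),
        ("other", lambda d: d["histological_type"].isin([2, 3, 4])),
        ("missing", lambda d: d["histological_type"].isna()),
    ],
    "tumor_grade": [
        ("I-II", lambda d: d["tumor_grade"].isin([1, 2])),
        ("III", lambda d: d["tumor_grade"] == 3),
        ("missing", lambda d: d["tumor_grade"].isna()),
    ],
    "ki67": [
        ("<=15%", lambda d: d["ki67"] <= 15),
        (">15%", lambda d: d["ki67"] > 15),
        ("missing", lambda d: d["ki67"].isna()),
    ],
}


@dataclass
class SubgroupCell:
    levels: dict[str, str]
    n_patients: int
    n_pos: int
    n_neg: int
    analyzed: bool
    auc: float | None = None
    ci: tuple[float, float] | None = None


def enumerate_subgroups() -> list[dict[str, str]]:
    """All candidate level combinations (4 x 4 x 3 x 3 x 3 = 432 cells)."""
    names = list(SUBGROUP_FACTORS)
    combos = itertools.product(*[[lab for lab, _ in SUBGROUP_FACTORS[n]] for n in names])
    return [dict(zip(names, combo)) for combo in combos]


def subgroup_scan(
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
    min_n: int = 10,
    n_boot: int = 2000,
    seed: int = 0,
) -> list[SubgroupCell]:
    """Ensemble-score AUC over every prognostic subgroup cell.

    ``scores`` has columns ``patient_id`` and ``score`` (the calibrated
    ensemble score); only uncensored patients are scanned. A cell is analyzed
    iff it holds at least ``min_n`` patients including at least one positive
    and one negative outcome. Cells are returned analyzed-first, sorted by
    AUC descending.
    """
    df = cohort.merge(scores[["patient_id", "score"]], on="patient_id", how="inner")
    df = df[df["censored"] == 0]
    level_masks = {
        name: {lab: fn(df).to_numpy() for lab, fn in SUBGROUP_FACTORS[name]}
        for name in SUBGROUP_FACTORS
    }
    y = df["outcome"].astype(int).to_numpy()
    s = df["score"].to_numpy()

    cells = []
    for combo in enumerate_subgroups():
        mask = np.ones(len(df), dtype=bool)
        for name, lab in combo.items():
            mask &= level_masks[name][lab]
        n_pos = int(y[mask].sum())
        n_neg = int(mask.sum() - n_pos)
        analyzed = mask.sum() >= min_n and n_pos >= 1 and n_neg >= 1
        cell = SubgroupCell(
            levels=combo,
            n_patients=int(mask.sum()),
            n_pos=n_pos,
            n_neg=n_neg,
            analyzed=bool(analyzed),
        )
        if analyzed:
            point, ci = auc_ci(s[mask], y[mask], n_boot=n_boot, seed=seed)
            cell.auc, cell.ci = point, ci
        cells.append(cell)
    cells.sort(key=lambda c: (not c.analyzed, -(c.auc if c.auc is not None else -np.inf)))
    return cells


def subgroup_table(cells: list[SubgroupCell]) -> pd.DataFrame:
    rows = []
    for c in cells:
        row = dict(c.levels)
        row.update(
            n=c.n_patients,
            n_pos=c.n_pos,
            n_neg=c.n_neg,
            analyzed=c.analyzed,
            auc=c.auc,
            ci_lo=c.ci[0] if c.ci else None,
            ci_hi=c.ci[1] if c.ci else None,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def roc_coordinates(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC curve coordinates (fpr, tpr, threshold) for plotting/export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int), np.asarray(scores, float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 12) -> float:
    """Corrected per-test significance threshold alpha / n_tests."""
    return alpha / n_tests
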