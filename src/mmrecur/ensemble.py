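"""Seed variations, Platt calibration and mean-of-available-scores fusion.

The final model receives up to six scores per patient: three clinical-model
variations and three mpMRI-model variations, each variation differing only in
its training seed. Every variation's scores are passed through a Platt
sigmoid fitted by maximum likelihood on its out-of-fold validation scores
(never on training scores), and the ensemble score is the arithmetic mean of
all scores available for the patient — patients without imaging contribute
clinical scores only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .evaluate import auc

_EPS = 1e-6


@dataclass
class CalibratorParams:
    """Fitted Platt sigmoid sigma(a * logit(s) + b) over the raw score s.

    The sigmoid is applied on the log-odds of the raw score so a perfectly
    calibrated model maps to (a, b) = (1, 0); the map is strictly monotone in
    the raw score (increasing for a > 0) with range (0, 1).
    """

    slope: float
    intercept: float

    def __call__(self, raw: np.ndarray) -> np.ndarray:
        x = _logit(np.asarray(raw, dtype=float))
        return 1.0 / (1.0 + np.exp(-(self.slope * x + self.intercept)))


def _logit(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, _EPS, 1.0 - _EPS)
    return np.log(s / (1.0 - s))


def fit_platt(raw_scores: np.ndarray, labels: np.ndarray) -> CalibratorParams:
    """Maximum-likelihood sigmoid fit with Platt's prior-corrected targets.

    Positive targets are (N+ + 1)/(N+ + 2) and negative targets 1/(N- + 2)
    rather than hard 0/1, the regularization from Platt's original procedure.
    """
    raw_scores = np.asarray(raw_scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not np.all(np.isfinite(raw_scores)):
        raise ValueError("scores must be finite")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to fit a calibrator")
    t = np.where(labels == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    x = _logit(raw_scores)

    def nll_grad(params):
        a, b = params
        z = a * x + b
        p = 1.0 / (1.0 + np.exp(-z))
        nll = -np.sum(t * np.log(p + 1e-12) + (1 - t) * np.log(1 - p + 1e-12))
        r = p - t
        return nll, np.array([np.sum(r * x), np.sum(r)])

    res = minimize(nll_grad, x0=np.array([1.0, 0.0]), jac=True, method="BFGS")
    return CalibratorParams(slope=float(res.x[0]), intercept=float(res.x[1]))


def make_variations(
    train_fn: Callable[[int], object], n: int = 3, base_seed: int = 0
) -> list[object]:
    """Train n model variations differing only in their initialization seed."""
    return [train_fn(base_seed + i) for i in range(n)]


def calibrate_scores(score_rows: pd.DataFrame, labels_of: dict[str, int]) -> tuple[pd.DataFrame, CalibratorParams]:
    """Fit Platt on one variation's out-of-fold scores and add a calibrated column."""
    y = np.array([labels_of[p] for p in score_rows["patient_id"]])
    cal = fit_platt(score_rows["raw_score"].to_numpy(), y)
    out = score_rows.copy()
    out["calibrated"] = cal(out["raw_score"].to_numpy())
    return out, cal


def combine(score_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Ensemble score = mean of all available calibrated scores per patient.

    Each table holds one variation's scores with columns ``patient_id`` and
    ``calibrated``. A patient missing from some tables (e.g. no imaging) is
    averaged over the tables that score them; a patient with no score at all
    raises.
    """
    if not score_tables:
        raise ValueError("at least one score table is required")
    frames = []
    for i, tab in enumerate(score_tables):
        frames.append(tab[["patient_id", "calibrated"]].assign(source=i))
    stacked = pd.concat(frames, ignore_index=True)
    if stacked["calibrated"].isna().any():
        raise ValueError("calibrated scores contain NaN")
    agg = stacked.groupby("patient_id")["calibrated"].agg(["mean", "count"]).reset_index()
    return agg.rename(columns={"mean": "score", "count": "n_scores"})


def audit_calibration_preserves_auc(
    raw: np.ndarray, calibrated: np.ndarray, labels: np.ndarray, tol: float = 1e-12
) -> None:
    """Assert the monotone calibration left the model's AUC unchanged."""
    if abs(auc(raw, labels) - auc(calibrated, labels)) > tol:
        raise AssertionError("calibration changed the ranking (AUC differs)")
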