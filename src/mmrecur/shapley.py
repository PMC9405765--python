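"""Shapley-value feature attributions by interventional permutation sampling.

For a model ``f``, a sample ``x`` and a background dataset ``Z``, the Shapley
value of feature ``j`` is its average marginal contribution over feature
orderings: features are switched from background values to ``x``'s values in
a random order and the change in ``f`` attributed to the feature switched.
Averaging over sampled orderings and background rows gives an unbiased
estimate of the Shapley values of the interventional game.

Two exactness properties hold by construction, whatever the number of sampled
permutations: the contributions of one sample sum to ``f(x) - E_Z[f]``
(efficiency, each permutation telescopes), and a feature the model never
reads gets attribution exactly zero (null player).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AttributionReport:
    """Per-patient, per-feature Shapley attributions plus the global ranking."""

    values: pd.DataFrame  # rows: patients, columns: features
    base_value: float
    predictions: np.ndarray

    @property
    def ranking(self) -> pd.Series:
        """Features ordered by global mean |attribution|, descending."""
        return self.values.abs().mean(axis=0).sort_values(ascending=False)

    @property
    def top10(self) -> list[str]:
        return list(self.ranking.index[:10])

    def efficiency_residual(self) -> np.ndarray:
        """Per-patient |sum(attributions) + base - prediction| (≈ 0 always)."""
        return np.abs(self.values.sum(axis=1).to_numpy() + self.base_value - self.predictions)


def shapley_values(
    predict: callable,
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 10,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> AttributionReport:
    """Sampling-based Shapley attributions for every row of ``X``.

    ``predict`` maps an ``(m, d)`` matrix to ``m`` scalar outputs (use the
    positive-class probability for classifiers). ``background`` is a small
    reference dataset defining the "feature absent" distribution.
    """
    X = np.asarray(X, dtype=np.float64)
    Z = np.atleast_2d(np.asarray(background, dtype=np.float64))
    n, d = X.shape
    b = Z.shape[0]
    rng = np.random.default_rng(seed)
    names = feature_names if feature_names is not None else [f"f{j}" for j in range(d)]

    base = float(np.mean(predict(Z)))
    fx = np.asarray(predict(X), dtype=np.float64)

    phi = np.zeros((n, d))
    # work array: one row per (sample, background) pair, reset per permutation
    tile_Z = np.repeat(Z[None, :, :], n, axis=0).reshape(n * b, d)
    for _ in range(n_permutations):
        order = rng.permutation(d)
        cur = tile_Z.copy()
        prev = predict(cur).reshape(n, b).mean(axis=1)
        for j in order:
            cur[:, j] = np.repeat(X[:, j], b)
            now = predict(cur).reshape(n, b).mean(axis=1)
            phi[:, j] += now - prev
            prev = now
    phi /= n_permutations

    return AttributionReport(
        values=pd.DataFrame(phi, columns=names),
        base_value=base,
        predictions=fx,
    )
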