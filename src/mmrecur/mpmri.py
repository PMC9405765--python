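"""The dual-component imaging (mpMRI) model.

A shared-weight 2D residual CNN is applied to each of the 7 standardized
subtraction slices; the per-slice feature maps are stacked along a depth axis,
passed through one 3D convolution and a global average pool, yielding 32 deep
subtraction features. In parallel a small dense head maps the Dixon-ADC
volumetric feature vector (augmented with clinical metadata) to 32 features.
Both 32-feature vectors are concatenated and transformed by dense layers of
widths (64, 32, 1) into the mpMRI score.

Training is 5-fold cross-validation with censored patients pseudo-labeled in
training folds and excluded from every validation fold; holdout scoring is
the arithmetic mean of the five fold-models' scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .features import DIXON_VECTOR_FIELDS

#: Architecture constants (fixed by the model definition).
RESIDUAL_FILTERS = (32, 64, 64, 128, 128, 256, 256)
DIXON_WIDTHS = (16, 16, 16, 32, 32)
FUSION_WIDTHS = (64, 32, 1)
SUBTRACTION_FEATURES = 32


@dataclass
class NetworkSpec:
    """Architecture and training hyperparameters of the mpMRI model."""

    residual_filters: tuple[int, ...] = RESIDUAL_FILTERS
    subtraction_features: int = SUBTRACTION_FEATURES
    dixon_widths: tuple[int, ...] = DIXON_WIDTHS
    fusion_widths: tuple[int, ...] = FUSION_WIDTHS
    conv3d_kernel: tuple[int, int, int] = (3, 3, 3)
    input_shape: tuple[int, int] = (512, 256)  # rows, cols of one slice
    dixon_dim: int = len(DIXON_VECTOR_FIELDS)
    lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 16
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.residual_filters) != RESIDUAL_FILTERS:
            raise ValueError(f"residual filter widths are fixed at {RESIDUAL_FILTERS}")
        if tuple(self.dixon_widths) != DIXON_WIDTHS:
            raise ValueError(f"dixon head widths are fixed at {DIXON_WIDTHS}")
        if tuple(self.fusion_widths) != FUSION_WIDTHS:
            raise ValueError(f"fusion head widths are fixed at {FUSION_WIDTHS}")
        if self.subtraction_features != SUBTRACTION_FEATURES:
            raise ValueError("the subtraction component outputs exactly 32 features")


class SubtractionNet:
    """Shared-weight 2D trunk over 7 slices + 3D conv + global average pool.

    Input ``(N, 7, H, W)``; output ``(N, 32)``. The identical trunk (same
    weights) is applied to every slice by folding the slice axis into the
    batch axis.
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        f = spec.residual_filters
        layers: list[nn.Layer] = [
            nn.Conv2d(1, f[0], 3, 2, 1, rng),
            nn.BatchNorm(f[0]),
            nn.ReLU(),
            nn.MaxPool2x2(),
        ]
        prev = f[0]
        for width in f:
            stride = 2 if width != prev else 1
            layers.append(nn.ResidualBlock(prev, width, stride, rng))
            prev = width
        self.trunk = nn.Sequential(layers)
        self.conv3d = nn.Conv3d(prev, spec.subtraction_features, spec.conv3d_kernel, rng)
        self.relu3d = nn.ReLU()
        self.pool = nn.GlobalAvgPool()

    def params(self):
        return self.trunk.params() + self.conv3d.params()

    def forward(self, stacks: np.ndarray, train: bool = True) -> np.ndarray:
        if stacks.ndim != 4 or stacks.shape[1] != 7:
            raise ValueError(f"expected (N, 7, H, W) slice stacks, got {stacks.shape}")
        n, s, h, w = stacks.shape
        x = np.asarray(stacks, dtype=nn.DTYPE).reshape(n * s, 1, h, w)
        feats = self.trunk.forward(x, train)  # (n*7, C, h', w')
        _, c, hh, ww = feats.shape
        self._fold = (n, s, c, hh, ww)
        vol = feats.reshape(n, s, c, hh, ww).transpose(0, 2, 1, 3, 4)  # (n, C, 7, h', w')
        out = self.pool.forward(self.relu3d.forward(self.conv3d.forward(vol, train), train), train)
        return out  # (n, 32)

    def backward(self, grad: np.ndarray) -> None:
        g = self.pool.backward(grad)
        g = self.relu3d.backward(g)
        g = self.conv3d.backward(g)
        n, s, c, hh, ww = self._fold
        g = g.transpose(0, 2, 1, 3, 4).reshape(n * s, c, hh, ww)
        self.trunk.backward(g)


class DixonHead:
    """Dense head: Dixon-ADC vector -> 32 features, widths (16,16,16,32,32)."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        layers: list[nn.Layer] = []
        prev = spec.dixon_dim
        for width in spec.dixon_widths:
            layers += [nn.Dense(prev, width, rng), nn.ReLU()]
            prev = width
        self.net = nn.Sequential(layers)

    def params(self):
        return self.net.params()

    def forward(self, x, train=True):
        return self.net.forward(x, train)

    def backward(self, grad):
        return self.net.backward(grad)


class FusionModel:
    """Full mpMRI model: subtraction net ⊕ dixon head -> (64, 32, 1) -> score."""

    def __init__(self, spec: NetworkSpec):
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        self.subtraction = SubtractionNet(spec, rng)
        self.dixon = DixonHead(spec, rng)
        fusion_in = spec.subtraction_features + spec.dixon_widths[-1]
        layers: list[nn.Layer] = []
        prev = fusion_in
        for i, width in enumerate(spec.fusion_widths):
            layers.append(nn.Dense(prev, width, rng))
            if i < len(spec.fusion_widths) - 1:
                layers.append(nn.ReLU())
            prev = width
        self.fusion = nn.Sequential(layers)

    def params(self):
        return self.subtraction.params() + self.dixon.params() + self.fusion.params()

    def forward_logits(self, stacks: np.ndarray, dixon: np.ndarray, train: bool = True) -> np.ndarray:
        if dixon.shape[1] != self.spec.dixon_dim:
            raise ValueError(
                f"dixon vector length {dixon.shape[1]} != spec dixon_dim {self.spec.dixon_dim}"
            )
        fs = self.subtraction.forward(stacks, train)
        fd = self.dixon.forward(np.asarray(dixon, dtype=nn.DTYPE), train)
        self._split = fs.shape[1]
        return self.fusion.forward(np.concatenate([fs, fd], axis=1), train)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.fusion.backward(np.asarray(dlogits, dtype=nn.DTYPE))
        self.subtraction.backward(g[:, : self._split])
        self.dixon.backward(g[:, self._split :])

    def predict(self, stacks: np.ndarray, dixon: np.ndarray, batch: int = 32) -> np.ndarray:
        out = []
        for i in range(0, stacks.shape[0], batch):
            z = self.forward_logits(stacks[i : i + batch], dixon[i : i + batch], train=False)
            out.append(nn.sigmoid(z.ravel()))
        return np.concatenate(out) if out else np.empty(0)

    def checksum(self) -> float:
        return nn.param_checksum(self.params())


@dataclass
class TrainLog:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": self.epochs, "train_loss": self.train_loss, "val_loss": self.val_loss}
        )


def class_balanced_weights(labels: np.ndarray) -> np.ndarray:
    """Per-sample weights inversely proportional to class frequencies."""
    labels = np.asarray(labels).astype(int)
    n = labels.size
    w = np.empty(n, dtype=np.float64)
    for c in (0, 1):
        n_c = (labels == c).sum()
        if n_c == 0:
            raise ValueError("both classes must be present")
        w[labels == c] = n / (2.0 * n_c)
    return w


def fit_fusion(
    model: FusionModel,
    stacks: np.ndarray,
    dixon: np.ndarray,
    labels: np.ndarray,
    val: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    log: TrainLog | None = None,
) -> FusionModel:
    """Train a fusion model with Adam, class-balanced BCE and early stopping.

    ``val`` is (stacks, dixon, labels) of the fold-validation set used for
    early stopping; training keeps the parameters of the best-validation
    epoch. Deterministic given the model's spec seed.
    """
    spec = model.spec
    rng = np.random.default_rng(spec.seed + 1)
    weights = class_balanced_weights(labels)
    opt = nn.Adam(model.params(), lr=spec.lr)
    best_val = np.inf
    best_state = None
    stall = 0
    n = stacks.shape[0]
    for epoch in range(1, spec.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, spec.batch_size):
            idx = order[i : i + spec.batch_size]
            opt.zero_grad()
            z = model.forward_logits(stacks[idx], dixon[idx], train=True)
            loss, dz = nn.bce_with_logits(z, labels[idx], weights[idx])
            model.backward(dz)
            opt.step()
            losses.append(loss)
        train_loss = float(np.mean(losses))
        if val is not None and val[0].shape[0] > 0:
            vz = []
            for j in range(0, val[0].shape[0], 32):
                vz.append(model.forward_logits(val[0][j : j + 32], val[1][j : j + 32], train=False))
            vloss, _ = nn.bce_with_logits(np.concatenate(vz), val[2])
        else:
            vloss = train_loss
        if log is not None:
            log.epochs.append(epoch)
            log.train_loss.append(train_loss)
            log.val_loss.append(float(vloss))
        if vloss < best_val - 1e-6:
            best_val = vloss
            best_state = [p.value.copy() for p in model.params()]
            stall = 0
        else:
            stall += 1
            if stall >= spec.patience:
                break
    if best_state is not None:
        for p, v in zip(model.params(), best_state):
            p.value[...] = v
    return model


def _scale_fit(train_x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = np.nanmin(train_x, axis=0)
    hi = np.nanmax(train_x, axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return lo, span


def _scale_apply(x: np.ndarray, lo: np.ndarray, span: np.ndarray) -> np.ndarray:
    return np.clip((x - lo) / span, 0.0, 1.0)


def train_mpmri(
    ids: list[str],
    stacks: np.ndarray,
    dixon_raw: pd.DataFrame,
    cohort: pd.DataFrame,
    fold_of: dict[str, int],
    train_labels: dict[str, int],
    spec: NetworkSpec,
) -> tuple[list[FusionModel], pd.DataFrame, list[TrainLog]]:
    """5-fold cross-validated training of the mpMRI model.

    ``train_labels`` maps every imaging patient to a training label (the
    observed outcome for uncensored patients, the side-model pseudo-label for
    censored ones). Censored patients appear only in training folds; the
    returned out-of-fold scores cover uncensored validation patients only.
    Dixon vectors are imputed with training-fold means and min–max scaled
    with training-fold statistics per fold.
    """
    ids = list(ids)
    censored = dict(zip(cohort["patient_id"], cohort["censored"]))
    outcome = dict(zip(cohort["patient_id"], cohort["outcome"]))
    folds = sorted(set(fold_of[p] for p in ids))
    models: list[FusionModel] = []
    logs: list[TrainLog] = []
    rows = []
    id_idx = {p: i for i, p in enumerate(ids)}
    raw = dixon_raw.loc[ids].to_numpy(dtype=np.float64)

    for f in folds:
        train_ids = [p for p in ids if fold_of[p] != f]
        val_ids = [p for p in ids if fold_of[p] == f and censored[p] == 0]
        tr = np.array([id_idx[p] for p in train_ids])
        va = np.array([id_idx[p] for p in val_ids], dtype=int)

        col_means = np.nanmean(raw[tr], axis=0)
        filled = np.where(np.isnan(raw), col_means[None, :], raw)
        lo, span = _scale_fit(filled[tr])
        X = _scale_apply(filled, lo, span)

        y_tr = np.array([train_labels[p] for p in train_ids], dtype=int)
        y_va = np.array([int(outcome[p]) for p in val_ids], dtype=int)

        fold_spec = replace(spec, seed=spec.seed * 1000 + f)
        model = FusionModel(fold_spec)
        log = TrainLog()
        fit_fusion(
            model,
            stacks[tr],
            X[tr],
            y_tr,
            val=(stacks[va], X[va], y_va) if len(va) else None,
            log=log,
        )
        models.append(model)
        logs.append(log)
        if len(va):
            scores = model.predict(stacks[va], X[va])
            for p, s in zip(val_ids, scores):
                rows.append(
                    {"patient_id": p, "modality": "mpmri", "fold": f, "raw_score": float(s)}
                )
        # keep fold-fitted preprocessing with the model for holdout use
        model.dixon_impute_means = col_means
        model.dixon_scale = (lo, span)
    return models, pd.DataFrame(rows), logs


def holdout_scores(models: list[FusionModel], stacks: np.ndarray, dixon_raw: np.ndarray) -> np.ndarray:
    """Holdout score = arithmetic mean of the five fold-models' scores."""
    per_model = []
    for m in models:
        filled = np.where(np.isnan(dixon_raw), m.dixon_impute_means[None, :], dixon_raw)
        X = _scale_apply(filled, *m.dixon_scale)
        per_model.append(m.predict(stacks, X))
    return np.mean(per_model, axis=0)
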