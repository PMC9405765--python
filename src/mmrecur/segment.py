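"""Two-phase fuzzy c-means (FCM) segmentation of Dixon/ADC volumes.

Phase 1 clusters every voxel of the study on its (water-only, fat-only)
intensity pair and labels the non-background clusters as breast tissue,
yielding a bilateral breast mask and, restricted to the annotated side's half
of the grid, a tumor-side breast mask. Phase 2 re-clusters the voxels inside
the tumor-side mask on (water-only, ADC) intensities — water-only alone when
no ADC series is available — and selects as lesion the cluster(s) with the
biggest overlap on the high-intensity areas of the ADC and water-only
volumes.

FCM minimizes the fuzzified within-cluster scatter
``J = sum_i sum_j u_ij^m ||x_i - c_j||^2`` subject to per-point memberships
summing to one, by alternating the classical membership and center updates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Percentile above which an in-mask voxel counts as "high intensity" for the
#: lesion-selection rule (top 5% on each of ADC and water-only, intersected).
HIGH_INTENSITY_PERCENTILE = 95.0

#: Connectivity used for all 3D region reasoning in the package.
CONNECTIVITY_3D = np.ones((3, 3, 3), dtype=bool)  # 26-neighborhood


class SegmentationWarning(UserWarning):
    pass


@dataclass
class FcmResult:
    """Converged state of one FCM run."""

    centers: np.ndarray  # (k, d)
    memberships: np.ndarray  # (n, k), rows sum to 1
    iterations: int
    objective: float
    objective_trace: list[float] = field(default_factory=list)

    def labels(self) -> np.ndarray:
        """Defuzzified hard labels: argmax membership, ties to the lower index."""
        return np.argmax(self.memberships, axis=1)


def fcm(
    points: np.ndarray,
    k: int,
    m: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 300,
    seed: int = 0,
) -> FcmResult:
    """Classical fuzzy c-means on an ``(n, d)`` point set.

    Centers are initialized at per-dimension quantiles spaced over the data
    (deterministic); a seeded, vanishingly small jitter breaks exact center
    collisions on degenerate inputs. Convergence is declared when the maximum
    center shift falls below ``tol``.

    Parameters follow the standard formulation: ``m > 1`` is the fuzziness
    exponent (``m -> 1`` approaches hard k-means).
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim == 1:
        points = points[:, None]
    n, d = points.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if m <= 1.0:
        raise ValueError("fuzziness m must be > 1")
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    n_distinct = np.unique(points, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")

    rng = np.random.default_rng(seed)
    # farthest-point (maximin) initialization: start at the medoid of the
    # data, then repeatedly seed the point farthest from all chosen centers.
    # Deterministic, and it gives a small outlying cluster (a lesion among
    # bulk tissue) its own starting center instead of absorbing it.
    mean = points.mean(axis=0)
    centers = [points[np.argmin(((points - mean) ** 2).sum(axis=1))]]
    min_d2 = ((points - centers[0]) ** 2).sum(axis=1)
    for _ in range(1, k):
        nxt = points[np.argmax(min_d2)]
        centers.append(nxt)
        min_d2 = np.minimum(min_d2, ((points - nxt) ** 2).sum(axis=1))
    centers = np.asarray(centers, dtype=np.float64)
    span = np.ptp(points, axis=0)
    span[span == 0] = 1.0
    centers = centers + rng.normal(0.0, 1e-9, size=centers.shape) * span

    exponent = 2.0 / (m - 1.0)
    trace: list[float] = []
    memberships = np.full((n, k), 1.0 / k)
    for it in range(1, max_iter + 1):
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)  # (n, k)
        # membership update: u_ij = 1 / sum_l (d_ij / d_il)^(2/(m-1))
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            ratio = d2[:, :, None] / d2[:, None, :]
            memberships = 1.0 / (ratio ** (exponent / 2.0)).sum(axis=2)
        zero_rows = d2.min(axis=1) == 0.0
        if zero_rows.any():
            memberships[zero_rows] = 0.0
            memberships[zero_rows, np.argmin(d2[zero_rows], axis=1)] = 1.0
        memberships = memberships / memberships.sum(axis=1, keepdims=True)

        um = memberships**m
        new_centers = (um.T @ points) / um.sum(axis=0)[:, None]
        trace.append(float((um * d2).sum()))
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    objective = float((memberships**m * d2).sum())
    return FcmResult(
        centers=centers,
        memberships=memberships,
        iterations=it,
        objective=objective,
        objective_trace=trace,
    )


@dataclass
class MaskSet:
    """The three binary 3D masks the Dixon-ADC branch is built on."""

    bilateral: np.ndarray
    tumor_side: np.ndarray
    lesion: np.ndarray

    def __post_init__(self) -> None:
        for name in ("bilateral", "tumor_side", "lesion"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if not (self.bilateral.shape == self.tumor_side.shape == self.lesion.shape):
            raise ValueError("mask shapes differ")
        # nesting: lesion <= tumor-side breast <= bilateral breast
        if np.any(self.tumor_side & ~self.bilateral) or np.any(self.lesion & ~self.tumor_side):
            raise ValueError("mask nesting violated (lesion ⊆ tumor-side ⊆ bilateral)")


def _side_half(shape: tuple[int, ...], side: str) -> np.ndarray:
    """Boolean mask of the given side's half-grid along the left–right axis."""
    nx = shape[2]
    half = np.zeros(shape, dtype=bool)
    if side == "left":
        half[:, :, : nx // 2] = True
    elif side == "right":
        half[:, :, nx // 2 :] = True
    else:
        raise ValueError(f"unknown side {side!r}")
    return half


def segment_breast(
    water: np.ndarray,
    fat: np.ndarray,
    tumor_side: str,
    k: int = 3,
    m: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, FcmResult]:
    """Phase 1: bilateral and tumor-side breast masks from Dixon volumes.

    Per-voxel (water, fat) intensity pairs are clustered with FCM (default
    k=3: background / fat-dominant / water-dominant tissue). The cluster with
    the lowest summed mean intensity is the background; all other clusters
    count as breast. The tumor-side mask restricts the bilateral mask to the
    annotated side's half of the grid.
    """
    if water.shape != fat.shape:
        raise ValueError("water and fat volumes must share a grid")
    pts = np.stack([water.ravel(), fat.ravel()], axis=1)
    result = fcm(pts, k=k, m=m, seed=seed)
    labels = result.labels().reshape(water.shape)
    background = int(np.argmin(result.centers.sum(axis=1)))
    bilateral = labels != background
    if not bilateral.any():
        warnings.warn("all voxels assigned to background; empty breast mask", SegmentationWarning)
    tumor_mask = bilateral & _side_half(water.shape, tumor_side)
    return bilateral, tumor_mask, result


def segment_lesion(
    water: np.ndarray,
    adc: np.ndarray | None,
    tumor_side_mask: np.ndarray,
    k: int = 3,
    m: float = 2.0,
    percentile: float = HIGH_INTENSITY_PERCENTILE,
    min_overlap: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, FcmResult | None]:
    """Phase 2: lesion mask inside the tumor-side breast mask.

    Voxels inside the mask are clustered on (water, ADC) intensities — water
    alone when the ADC series is absent. The "high-intensity area" is the set
    of in-mask voxels above the given percentile on every available channel;
    the cluster(s) with maximal overlap fraction (share of the cluster's
    voxels inside that area) form the lesion. If no cluster reaches
    ``min_overlap`` — only the noise tail of normal tissue touches the area,
    as in a lesion-free breast — an empty mask is returned with a warning.
    """
    if not tumor_side_mask.any():
        warnings.warn("empty breast mask; no lesion segmentation", SegmentationWarning)
        return np.zeros_like(tumor_side_mask, dtype=bool), None

    channels = [water[tumor_side_mask]]
    if adc is not None:
        channels.append(adc[tumor_side_mask])
    pts = np.stack(channels, axis=1)
    result = fcm(pts, k=min(k, np.unique(pts, axis=0).shape[0]), m=m, seed=seed)
    labels = result.labels()

    # strict inequality: on quantized intensities the percentile can land on
    # a bulk-tissue value, and >= would flood the area with that tissue
    high = np.ones(pts.shape[0], dtype=bool)
    for ch in range(pts.shape[1]):
        high &= pts[:, ch] > np.percentile(pts[:, ch], percentile)

    overlaps = np.zeros(result.centers.shape[0])
    for j in range(result.centers.shape[0]):
        members = labels == j
        if members.any():
            overlaps[j] = (members & high).sum() / members.sum()
    if overlaps.max() < min_overlap:
        warnings.warn("no cluster overlaps the high-intensity area", SegmentationWarning)
        return np.zeros_like(tumor_side_mask, dtype=bool), result

    selected = np.flatnonzero(overlaps == overlaps.max())
    lesion_flat = np.isin(labels, selected)
    lesion = np.zeros_like(tumor_side_mask, dtype=bool)
    lesion[tumor_side_mask] = lesion_flat
    return lesion, result


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two binary masks (1.0 for two empties)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    return 2.0 * int((a & b).sum()) / denom if denom else 1.0


def segment_study(study, seed: int = 0, use_adc: bool = True) -> tuple[MaskSet, dict]:
    """Run both phases on a study; return the MaskSet and a report dict."""
    bilateral, tumor_mask, phase1 = segment_breast(
        study.water, study.fat, study.annotations.tumor_side, seed=seed
    )
    adc = study.adc if use_adc else None
    lesion, phase2 = segment_lesion(study.water, adc, tumor_mask, seed=seed)
    report = {
        "patient_id": study.patient_id,
        "phase1_centers": phase1.centers.tolist(),
        "phase2_centers": phase2.centers.tolist() if phase2 is not None else None,
        "n_breast_voxels": int(bilateral.sum()),
        "n_lesion_voxels": int(lesion.sum()),
        "adc_used": adc is not None,
    }
    return MaskSet(bilateral=bilateral, tumor_side=tumor_mask, lesion=lesion), report
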