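"""Volumetric lesion features from the segmentation masks.

Five features, in physical units, computed on the largest connected lesion
region: tumor volume (mm³), tumor surface area (mm²), the number of separate
regions in the lesion segmentation, the mean lesion intensity relative to the
other breast tissue on the water-suppression (fat-only-visible) Dixon volume,
and the spread — the sum of the maximum extents along x, y and z in mm.

When segmentation yields several disjoint regions, only the largest is used
for the geometric features; the region count itself is the third feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from .segment import CONNECTIVITY_3D

#: Clinical metadata joined to the volumetric features in the Dixon vector.
DIXON_METADATA_FIELDS = ("age", "bmi", "tumor_size_mm", "tumor_grade")

#: Column order of the assembled Dixon vector.
DIXON_VECTOR_FIELDS = (
    "tumor_volume_mm3",
    "surface_area_mm2",
    "n_regions",
    "intensity_ratio",
    "spread_mm",
) + DIXON_METADATA_FIELDS


@dataclass
class VolumetricFeatures:
    tumor_volume_mm3: float
    surface_area_mm2: float
    n_regions: int
    intensity_ratio: float | None  # None when undefined (flagged missing)
    spread_mm: float

    def as_dict(self) -> dict:
        return {
            "tumor_volume_mm3": self.tumor_volume_mm3,
            "surface_area_mm2": self.surface_area_mm2,
            "n_regions": self.n_regions,
            "intensity_ratio": np.nan if self.intensity_ratio is None else self.intensity_ratio,
            "spread_mm": self.spread_mm,
        }


def count_regions(mask: np.ndarray) -> tuple[int, np.ndarray]:
    """Connected components of a binary mask under 26-connectivity.

    Returns the region count and the largest region (by voxel count) as a
    mask; ties go to the region containing the lowest linear voxel index. An
    empty mask yields ``(0, empty mask)``.
    """
    mask = np.asarray(mask, dtype=bool)
    labeled, n = ndimage.label(mask, structure=CONNECTIVITY_3D)
    if n == 0:
        return 0, np.zeros_like(mask)
    counts = np.bincount(labeled.ravel())[1:]  # skip background
    best = counts.max()
    tied = np.flatnonzero(counts == best) + 1
    if len(tied) == 1:
        label = tied[0]
    else:
        flat = labeled.ravel()
        first_index = {int(lab): np.argmax(flat == lab) for lab in tied}
        label = min(tied, key=lambda lab: first_index[int(lab)])
    return int(n), labeled == label


def compute_features(
    largest_mask: np.ndarray,
    n_regions: int,
    fat_volume: np.ndarray,
    breast_mask: np.ndarray,
    spacing_mm: tuple[float, float, float],
) -> VolumetricFeatures:
    """The five volumetric features of the largest lesion region.

    ``fat_volume`` is the water-suppression Dixon contrast (fat visible) on
    which the intensity ratio is anchored. Surface area comes from a
    marching-cubes isosurface of the binary mask at level 0.5, scaled by the
    voxel spacing. Spread uses the inclusive index extent: (max − min + 1) ×
    spacing per axis, summed.
    """
    if any(s <= 0 for s in spacing_mm):
        raise ValueError("spacing must be positive")
    largest_mask = np.asarray(largest_mask, dtype=bool)
    if np.any(largest_mask & ~np.asarray(breast_mask, dtype=bool)):
        raise ValueError("lesion mask must lie inside the breast mask")
    if not largest_mask.any():
        return VolumetricFeatures(0.0, 0.0, int(n_regions), None, 0.0)

    voxel_volume = float(np.prod(spacing_mm))
    volume = float(largest_mask.sum()) * voxel_volume

    padded = np.pad(largest_mask.astype(np.float64), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing_mm)
    surface = float(mesh_surface_area(verts, faces))

    idx = np.nonzero(largest_mask)
    spread = float(
        sum((idx[a].max() - idx[a].min() + 1) * spacing_mm[a] for a in range(3))
    )

    other = np.asarray(breast_mask, dtype=bool) & ~largest_mask
    if other.any():
        denom = float(fat_volume[other].mean())
        ratio = float(fat_volume[largest_mask].mean()) / denom if denom != 0 else None
    else:
        ratio = None

    return VolumetricFeatures(volume, surface, int(n_regions), ratio, spread)


def features_from_masks(
    lesion_mask: np.ndarray,
    fat_volume: np.ndarray,
    breast_mask: np.ndarray,
    spacing_mm: tuple[float, float, float],
) -> VolumetricFeatures:
    """Count regions, keep the largest, and compute the feature set."""
    n, largest = count_regions(lesion_mask)
    return compute_features(largest, n, fat_volume, breast_mask, spacing_mm)


def assemble_dixon_vector(
    features: VolumetricFeatures | None,
    metadata: dict,
    field_means: dict,
    metadata_fields: tuple[str, ...] = DIXON_METADATA_FIELDS,
) -> np.ndarray:
    """Ordered numeric vector: five volumetric features + clinical metadata.

    Missing entries (an absent/empty lesion's undefined intensity ratio, or a
    NaN metadata value) are imputed with ``field_means``, which must be
    computed on training-fold patients only. Unknown metadata fields raise.
    """
    values: dict[str, float] = (
        features.as_dict()
        if features is not None
        else {k: np.nan for k in DIXON_VECTOR_FIELDS[:5]}
    )
    if features is not None and not np.isfinite(values["intensity_ratio"]):
        values["intensity_ratio"] = np.nan
    for f in metadata_fields:
        if f not in metadata:
            raise KeyError(f"unknown metadata field {f!r}")
        values[f] = metadata[f]
    out = []
    for name in DIXON_VECTOR_FIELDS[:5] + tuple(metadata_fields):
        v = values[name]
        if v is None or not np.isfinite(v):
            v = field_means.get(name, 0.0)
        out.append(float(v))
    return np.asarray(out, dtype=np.float64)
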