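"""Preparation of DCE subtraction slices for the CNN branch.

From an annotated subtraction volume the CNN receives the significant slice
(the annotated slice where the tumor appears largest) and its three preceding
and three following slices — seven in total. Each slice is cropped to the
tumor-side half (axial acquisitions contain both breasts; the split is at the
mid-sagittal column), trimmed of non-breast margins, resized to a fixed
512 x 256 frame, oriented so the breast faces the same direction for every
study, and min–max normalized per stack.

Slices are 2D arrays ``(rows, cols)`` = (anterior–posterior, left–right).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

#: Fixed output frame (rows, cols) of a standardized slice.
PRODUCTION_SHAPE = (512, 256)

#: Fraction of the stack maximum below which a margin row/column counts as
#: non-breast and is trimmed.
BREAST_PRESENCE_FRAC = 0.05


class DegenerateInputError(ValueError):
    """A slice stack is empty after cropping (no breast signal)."""


@dataclass
class SliceStack:
    """Seven standardized single-channel slices plus provenance."""

    slices: np.ndarray  # (7, rows, cols)
    source_indices: tuple[int, ...]
    tumor_side: str
    orientation: str = "canonical"
    standardized: bool = False
    crop_box: tuple[int, int, int, int] | None = None  # rows0, rows1, cols0, cols1

    def __post_init__(self) -> None:
        if self.slices.shape[0] != 7:
            raise ValueError(f"a slice stack holds exactly 7 slices, got {self.slices.shape[0]}")


def extract_slices(volume: np.ndarray, significant_slice: int) -> tuple[np.ndarray, tuple[int, ...]]:
    """Pick the significant slice and its six neighbours from a volume.

    Indices are ``s-3 ... s+3`` in acquisition order. Near the volume edge the
    terminal slice is replicated so the 7-slice contract always holds.
    """
    n = volume.shape[0]
    if not 0 <= significant_slice < n:
        raise IndexError(f"significant slice {significant_slice} outside volume of {n} slices")
    idx = tuple(int(np.clip(significant_slice + d, 0, n - 1)) for d in range(-3, 4))
    return volume[list(idx)].astype(np.float64), idx


def extract_from_study(study) -> tuple[np.ndarray, tuple[int, ...]]:
    """Extract the 7 raw slices named by a study's annotations."""
    return extract_slices(study.selected_subtraction, study.annotations.significant_slice)


def _margin_crop_box(stack_max: np.ndarray, threshold: float) -> tuple[int, int, int, int]:
    """Contiguous below-threshold margins of the max-projection image."""
    rows = np.flatnonzero(stack_max.max(axis=1) >= threshold)
    cols = np.flatnonzero(stack_max.max(axis=0) >= threshold)
    if rows.size == 0 or cols.size == 0:
        raise DegenerateInputError("no breast signal above the presence threshold")
    return int(rows[0]), int(rows[-1] + 1), int(cols[0]), int(cols[-1] + 1)


def standardize_slices(
    raw: np.ndarray | SliceStack,
    tumor_side: str | None = None,
    target_shape: tuple[int, int] = PRODUCTION_SHAPE,
    threshold_frac: float = BREAST_PRESENCE_FRAC,
) -> SliceStack:
    """Crop, resize, orient and normalize 7 raw slices into a SliceStack.

    Steps: keep the tumor-side half (split at the mid-sagittal column); flip
    right-sided stacks so the breast faces the canonical direction; trim
    contiguous margin rows/columns whose maximum is below ``threshold_frac``
    of the stack maximum (one crop box shared by all 7 slices, from their max
    projection); resize bilinearly to ``target_shape``; min–max normalize the
    stack to [0, 1].

    A stack that is already standardized is returned unchanged (idempotence).
    """
    if isinstance(raw, SliceStack):
        if raw.standardized:
            return raw
        source = raw.slices
        tumor_side = tumor_side or raw.tumor_side
    else:
        source = np.asarray(raw, dtype=np.float64)
    if source.ndim != 3 or source.shape[0] != 7:
        raise ValueError("expected 7 raw slices of a common shape")
    if tumor_side not in ("left", "right"):
        raise ValueError(f"tumor side must be 'left' or 'right', got {tumor_side!r}")

    ncols = source.shape[2]
    half = source[:, :, : ncols // 2] if tumor_side == "left" else source[:, :, ncols // 2 :]
    if tumor_side == "right":
        half = half[:, :, ::-1]  # canonical orientation: breast faces as on the left

    projection = half.max(axis=0)
    peak = float(projection.max())
    if peak <= 0:
        raise DegenerateInputError("slice stack is empty after tumor-side crop")
    r0, r1, c0, c1 = _margin_crop_box(projection, threshold_frac * peak)
    cropped = half[:, r0:r1, c0:c1]

    out = np.stack(
        [
            resize(s, target_shape, order=1, preserve_range=True, anti_aliasing=False)
            for s in cropped
        ]
    )
    lo, hi = float(out.min()), float(out.max())
    out = (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)

    src = raw.source_indices if isinstance(raw, SliceStack) else tuple(range(7))
    return SliceStack(
        slices=out,
        source_indices=src,
        tumor_side=tumor_side,
        orientation="canonical",
        standardized=True,
        crop_box=(r0, r1, c0, c1),
    )


def undersample_overlap(n_slices: int, slice_spacing: float, slice_thickness: float) -> list[int]:
    """Indices of slices retained after removing through-plane overlap.

    When the slice thickness exceeds the slice spacing, adjacent slices image
    overlapping tissue; every ``k``-th slice with ``k = ceil(thickness /
    spacing)`` is kept. With no overlap all slices are kept.
    """
    if slice_spacing <= 0 or slice_thickness <= 0:
        raise ValueError("spacing and thickness must be positive")
    k = math.ceil(slice_thickness / slice_spacing) if slice_thickness > slice_spacing else 1
    return list(range(0, n_slices, k))


def prepare_stack(study, target_shape: tuple[int, int] = PRODUCTION_SHAPE) -> SliceStack:
    """End-to-end: extract the 7 annotated slices from a study and standardize."""
    raw, idx = extract_from_study(study)
    stack = standardize_slices(raw, study.annotations.tumor_side, target_shape=target_shape)
    stack.source_indices = idx
    return stack
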