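"""Reading and writing studies, masks and cohort tables.

Volumes are stored as NIfTI-1 (one file per volume type, voxel spacing in the
header zooms), truth and segmentation masks as NIfTI-1 with 0/1 voxels, the
cohort as CSV, and a JSON manifest linking patient ID -> volume files ->
annotations. Arrays keep the package's ``(z, y, x)`` order; the NIfTI affine
is a diagonal scaling by the spacing (phantoms carry no anatomical frame).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synth import Annotations, MriStudy, PhantomTruth


def _write_nifti(path: Path, vol: np.ndarray, spacing: tuple[float, float, float]) -> None:
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=np.float64), spacing


def write_study(
    out_dir: str | Path,
    study: MriStudy,
    truth: PhantomTruth | None = None,
) -> dict:
    """Write one study's volumes (and optional truth masks); return its manifest entry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pid = study.patient_id
    entry: dict = {
        "patient_id": pid,
        "spacing_mm": list(study.spacing_mm),
        "annotations": {
            "tumor_side": study.annotations.tumor_side,
            "selected_subtraction": study.annotations.selected_subtraction,
            "significant_slice": study.annotations.significant_slice,
            "orientation": study.annotations.orientation,
        },
        "volumes": {},
    }
    for i, vol in enumerate(study.subtraction):
        name = f"{pid}_subtraction_{i}.nii.gz"
        _write_nifti(out_dir / name, vol, study.spacing_mm)
        entry["volumes"].setdefault("subtraction", []).append(name)
    for vt in ("adc", "water", "fat"):
        vol = getattr(study, vt)
        if vol is None:
            continue
        name = f"{pid}_{vt}.nii.gz"
        _write_nifti(out_dir / name, vol, study.spacing_mm)
        entry["volumes"][vt] = name
    if truth is not None:
        entry["truth"] = {}
        for key, mask in [
            ("lesion", truth.lesion_mask),
            ("breast_left", truth.breast_masks["left"]),
            ("breast_right", truth.breast_masks["right"]),
        ]:
            name = f"{pid}_truth_{key}.nii.gz"
            _write_nifti(out_dir / name, mask.astype(np.uint8), study.spacing_mm)
            entry["truth"][key] = name
        entry["truth"]["analytic_volume_mm3"] = truth.analytic_volume_mm3
        entry["truth"]["lesion_count"] = truth.lesion_count
    return entry


def write_manifest(path: str | Path, entries: list[dict]) -> None:
    Path(path).write_text(json.dumps({"studies": entries}, indent=2))


def read_manifest(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())["studies"]


def read_study(data_dir: str | Path, entry: dict) -> MriStudy:
    """Load a study back from a manifest entry."""
    data_dir = Path(data_dir)
    sub, spacing = [], None
    for name in entry["volumes"]["subtraction"]:
        vol, spacing = _read_nifti(data_dir / name)
        sub.append(vol)
    adc = water = fat = None
    for vt in ("adc", "water", "fat"):
        if vt in entry["volumes"]:
            vol, spacing = _read_nifti(data_dir / entry["volumes"][vt])
            if vt == "adc":
                adc = vol
            elif vt == "water":
                water = vol
            else:
                fat = vol
    ann = entry["annotations"]
    return MriStudy(
        patient_id=entry["patient_id"],
        subtraction=sub,
        adc=adc,
        water=water,
        fat=fat,
        spacing_mm=tuple(entry["spacing_mm"]),
        annotations=Annotations(
            tumor_side=ann["tumor_side"],
            selected_subtraction=ann["selected_subtraction"],
            significant_slice=ann["significant_slice"],
            orientation=ann.get("orientation", "canonical"),
        ),
    )


def write_cohort(path: str | Path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
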