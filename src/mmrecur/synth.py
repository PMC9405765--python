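"""Synthetic mpMRI phantoms and synthetic clinical cohorts.

Every downstream stage of the pipeline is exercised on data produced here, so
the generators expose the ground truth they embed: phantom studies come with
analytic lesion geometry (:class:`PhantomTruth`) and cohorts carry the latent
outcome model that produced the labels.

Phantoms are axial acquisitions containing both breasts: two ellipsoidal
breasts on an empty background, breast tissue split into fat-dominant and
fibroglandular voxels, and ellipsoidal lesions that are bright on the
subtraction, water-only and ADC volumes (the lesion-selection rule downstream
keys on high intensity on ADC and water-only). Four co-registered volume
types are produced per study: DCE subtraction (two timepoints, one annotated
as the selected volume), ADC, Dixon water-only and Dixon fat-only.

Array convention: volumes are indexed ``(z, y, x)`` — slice axis first, then
the anterior–posterior image rows, then the left–right image columns; spacing
is given in the same order, in millimetres. The left breast occupies the low
``x`` half of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VOLUME_TYPES = ("subtraction", "adc", "water", "fat")
TISSUES = ("background", "fat", "fibroglandular", "lesion")

#: Default tissue intensity means per volume type (arbitrary units).
#: Lesions are bright on subtraction, ADC and water-only, and dark on
#: fat-only; gaps between class means are kept >= 3x the default noise SD so
#: fuzzy c-means clusters are recoverable by construction.
DEFAULT_INTENSITY_MEANS: dict[str, dict[str, float]] = {
    "subtraction": {"background": 0.0, "fat": 25.0, "fibroglandular": 55.0, "lesion": 160.0},
    "adc": {"background": 0.0, "fat": 40.0, "fibroglandular": 75.0, "lesion": 150.0},
    "water": {"background": 0.0, "fat": 20.0, "fibroglandular": 70.0, "lesion": 110.0},
    "fat": {"background": 0.0, "fat": 90.0, "fibroglandular": 32.0, "lesion": 15.0},
}

#: Default additive Gaussian noise SD per volume type, ~4% of the intensity
#: range of that volume type.
DEFAULT_NOISE_SD: dict[str, float] = {
    "subtraction": 6.0,
    "adc": 6.0,
    "water": 4.0,
    "fat": 3.5,
}


class SpecError(ValueError):
    """A generator spec violates its invariants."""


@dataclass(frozen=True)
class Lesion:
    """Ellipsoidal lesion: center and semi-axes in mm (z, y, x), plus side."""

    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]
    side: str  # "left" | "right"


@dataclass(frozen=True)
class Annotations:
    """Per-study manual annotations the real study relied on."""

    tumor_side: str
    selected_subtraction: int
    significant_slice: int
    #: image-space orientation marker; phantoms are generated canonical
    orientation: str = "canonical"


@dataclass
class MriStudy:
    """One patient's co-registered volumes plus spacing and annotations."""

    patient_id: str
    subtraction: list[np.ndarray]
    adc: np.ndarray | None
    water: np.ndarray
    fat: np.ndarray
    spacing_mm: tuple[float, float, float]
    annotations: Annotations

    @property
    def selected_subtraction(self) -> np.ndarray:
        return self.subtraction[self.annotations.selected_subtraction]


@dataclass
class PhantomTruth:
    """Ground truth embedded in a generated phantom."""

    lesion_mask: np.ndarray
    breast_masks: dict[str, np.ndarray]  # side -> binary mask
    analytic_volume_mm3: float
    bbox_extents_mm: tuple[float, float, float]
    lesion_count: int

    @property
    def bilateral_mask(self) -> np.ndarray:
        return self.breast_masks["left"] | self.breast_masks["right"]


@dataclass
class PhantomSpec:
    """Geometry, tissue intensities and noise for one phantom study.

    ``breast_centers_mm`` / ``breast_semiaxes_mm`` map side -> (z, y, x) mm.
    """

    shape: tuple[int, int, int] = (32, 48, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    breast_centers_mm: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    breast_semiaxes_mm: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    fat_fraction: float = 0.55
    lesions: list[Lesion] = field(default_factory=list)
    intensity_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INTENSITY_MEANS.items()}
    )
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    n_subtraction: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.breast_centers_mm:
            nz, ny, nx = self.shape
            dz, dy, dx = self.spacing_mm
            cz, cy = nz * dz / 2.0, ny * dy * 0.45
            self.breast_centers_mm = {
                "left": (cz, cy, nx * dx * 0.27),
                "right": (cz, cy, nx * dx * 0.73),
            }
        if not self.breast_semiaxes_mm:
            nz, ny, nx = self.shape
            dz, dy, dx = self.spacing_mm
            semi = (0.40 * nz * dz, 0.36 * ny * dy, 0.20 * nx * dx)
            self.breast_semiaxes_mm = {"left": semi, "right": semi}
        self.validate()

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise SpecError("voxel spacing must be positive on all axes")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise SpecError("fat fraction must lie in [0, 1]")
        for vt in VOLUME_TYPES:
            means = sorted(self.intensity_means[vt].values())
            sd = self.noise_sd[vt]
            gaps = np.diff(means)
            if sd > 0 and np.any(gaps < 3.0 * sd):
                raise SpecError(
                    f"{vt}: tissue intensity means closer than 3 noise SD "
                    f"(min gap {gaps.min():.1f}, 3*SD {3 * sd:.1f})"
                )
        for les in self.lesions:
            if les.side not in ("left", "right"):
                raise SpecError(f"unknown lesion side {les.side!r}")
            bc = np.asarray(self.breast_centers_mm[les.side], float)
            bs = np.asarray(self.breast_semiaxes_mm[les.side], float)
            lc = np.asarray(les.center_mm, float)
            ls = np.asarray(les.semiaxes_mm, float)
            # conservative containment: ellipsoid norm of the center plus the
            # worst-case reach of the lesion must stay inside the breast
            if np.sqrt(np.sum(((lc - bc) / bs) ** 2)) + ls.max() / bs.min() > 1.0:
                raise SpecError("lesion extends outside its breast ellipsoid")


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: tuple[float, float, float],
    semiaxes_mm: tuple[float, float, float],
) -> np.ndarray:
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    r2 = sum(
        ((g * sp - c) / ax) ** 2
        for g, sp, c, ax in zip(grids, spacing, center_mm, semiaxes_mm)
    )
    return r2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[MriStudy, PhantomTruth]:
    """Render a phantom study and its ground truth.

    Deterministic given ``spec.seed``. Lesion voxels are brighter than the
    surrounding breast tissue on the subtraction, water-only and ADC volumes;
    the second subtraction timepoint carries the full lesion enhancement and
    is annotated as the selected volume.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing_mm

    breast_masks = {
        side: _ellipsoid_mask(shape, spacing, spec.breast_centers_mm[side], spec.breast_semiaxes_mm[side])
        for side in ("left", "right")
    }
    bilateral = breast_masks["left"] | breast_masks["right"]

    lesion_mask = np.zeros(shape, dtype=bool)
    analytic = 0.0
    for les in spec.lesions:
        lesion_mask |= _ellipsoid_mask(shape, spacing, les.center_mm, les.semiaxes_mm)
        analytic += 4.0 / 3.0 * np.pi * float(np.prod(les.semiaxes_mm))
    lesion_mask &= bilateral

    # tissue map: 0 background, 1 fat, 2 fibroglandular, 3 lesion
    tissue = np.zeros(shape, dtype=np.int8)
    in_breast = bilateral & ~lesion_mask
    tissue[in_breast] = np.where(
        rng.random(int(in_breast.sum())) < spec.fat_fraction, 1, 2
    )
    tissue[lesion_mask] = 3

    def render(vt: str, lesion_scale: float = 1.0) -> np.ndarray:
        means = spec.intensity_means[vt]
        lut = np.array(
            [means["background"], means["fat"], means["fibroglandular"], means["lesion"] * lesion_scale],
            dtype=np.float64,
        )
        vol = lut[tissue]
        sd = spec.noise_sd[vt]
        if sd > 0:
            vol = vol + rng.normal(0.0, sd, size=shape)
        return vol

    # earlier subtraction timepoints enhance the lesion less; the last (full
    # enhancement) timepoint is the annotated "most important" volume
    scales = np.linspace(0.6, 1.0, max(spec.n_subtraction, 1))
    subtraction = [render("subtraction", s) for s in scales]
    adc = render("adc")
    water = render("water")
    fat = render("fat")

    if lesion_mask.any():
        per_slice = lesion_mask.sum(axis=(1, 2))
        significant = int(np.argmax(per_slice))
        sides = [les.side for les in spec.lesions]
        tumor_side = max(set(sides), key=sides.count)
    else:
        significant = shape[0] // 2
        tumor_side = "left"

    if lesion_mask.any():
        idx = np.nonzero(lesion_mask)
        extents = tuple(
            float((idx[a].max() - idx[a].min() + 1) * spacing[a]) for a in range(3)
        )
    else:
        extents = (0.0, 0.0, 0.0)

    study = MriStudy(
        patient_id="phantom",
        subtraction=subtraction,
        adc=adc,
        water=water,
        fat=fat,
        spacing_mm=spacing,
        annotations=Annotations(
            tumor_side=tumor_side,
            selected_subtraction=len(subtraction) - 1,
            significant_slice=significant,
        ),
    )
    truth = PhantomTruth(
        lesion_mask=lesion_mask,
        breast_masks=breast_masks,
        analytic_volume_mm3=analytic,
        bbox_extents_mm=extents,
        lesion_count=len(spec.lesions),
    )
    return study, truth


def spherical_lesion_spec(
    radius_mm: float,
    side: str = "left",
    seed: int = 0,
    **kwargs,
) -> PhantomSpec:
    """Convenience spec with one spherical lesion centered in the given breast."""
    spec = PhantomSpec(seed=seed, **kwargs)
    center = spec.breast_centers_mm[side]
    lesion = Lesion(center_mm=center, semiaxes_mm=(radius_mm,) * 3, side=side)
    return replace(spec, lesions=[lesion], seed=seed)


# ---------------------------------------------------------------------------
# clinical cohort
# ---------------------------------------------------------------------------

#: Clinical feature columns of a cohort table (order fixed).
CLINICAL_FEATURES = (
    "age",
    "bmi",
    "her2",
    "histological_type",
    "progesterone",
    "mitotic_index",
    "ki67",
    "tumor_grade",
    "cancer_subtype",
    "tumor_size_mm",
)

#: Default per-feature missingness rates (fractions), emulating a hospital
#: registry where proliferation markers and subtyping are incompletely coded.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "bmi": 0.03,
    "histological_type": 0.04,
    "progesterone": 0.05,
    "mitotic_index": 0.10,
    "ki67": 0.12,
    "tumor_grade": 0.05,
    "cancer_subtype": 0.06,
}

#: Default logistic risk coefficients on standardized drivers. BMI and age are
#: protective (inverse association with recurrence), HER2-positive status is
#: protective (targeted therapy era), and larger lesion volume raises risk.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "bmi": -0.8,
    "age": -0.6,
    "her2": -0.8,
    "log_volume": 1.0,
}


@dataclass
class CohortSpec:
    """Size, outcome structure and missingness of a synthetic cohort."""

    n: int = 800
    n_imaging: int = 200
    positive_rate: float = 0.16
    censoring_rate: float = 0.40
    missingness: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    coefficients: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 20:
            raise SpecError("cohort size must be at least 20")
        if not 0 <= self.n_imaging <= self.n:
            raise SpecError("imaging subset size must lie in [0, n]")
        for name, rate in [
            ("positive rate", self.positive_rate),
            ("censoring rate", self.censoring_rate),
            *self.missingness.items(),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise SpecError(f"{name} must lie in [0, 1], got {rate}")


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Bisection for the intercept putting mean sigmoid(eta + b0) at target."""
    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if np.mean(1.0 / (1.0 + np.exp(-(eta + mid)))) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    Columns: ``patient_id``, the clinical features in :data:`CLINICAL_FEATURES`,
    ``outcome`` (five-year recurrence, NaN for censored patients), ``censored``,
    ``has_imaging``, plus generator-truth columns ``outcome_true``,
    ``latent_volume_mm3`` and ``tumor_side`` that no real registry would carry
    (used only to build matching phantoms and to validate recovery).

    The outcome is Bernoulli under a logistic model on standardized BMI, age,
    HER2 status and log lesion volume with the spec's coefficients; the
    intercept is solved numerically to hit the target positive rate in
    expectation. Censoring is assigned independently of all features.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    age = np.clip(rng.normal(48.0, 10.0, n), 25.0, 82.0)
    bmi = np.clip(rng.normal(25.0, 4.5, n), 16.0, 45.0)
    her2 = (rng.random(n) < 0.20).astype(int)
    # subtype codes: 1 TNBC, 2 LuminalA, 3 LuminalB, 4 HER2+
    subtype = np.where(
        her2 == 1, 4, rng.choice([1, 2, 3], size=n, p=[0.25, 0.40, 0.35])
    )
    histological = rng.choice([1, 2, 3, 4], size=n, p=[0.75, 0.15, 0.03, 0.07])
    progesterone = (rng.random(n) < np.where(np.isin(subtype, (2, 3)), 0.8, 0.15)).astype(int)
    ki67 = np.clip(rng.lognormal(np.log(25.0), 0.6, n), 1.0, 95.0)
    mitotic = rng.poisson(np.clip(ki67 / 4.0, 1.0, None)).astype(int)
    grade = 1 + (ki67 > 14).astype(int) + (ki67 > 32).astype(int)

    radius = np.exp(rng.normal(np.log(8.0), 0.30, n))
    radius = np.clip(radius, 4.0, 13.0)
    volume = 4.0 / 3.0 * np.pi * radius**3
    tumor_size = 2.0 * radius + rng.normal(0.0, 1.5, n)
    side = rng.choice(["left", "right"], size=n)

    def z(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std()

    coef = spec.coefficients
    eta = (
        coef.get("bmi", 0.0) * z(bmi)
        + coef.get("age", 0.0) * z(age)
        + coef.get("her2", 0.0) * (her2 - her2.mean())
        + coef.get("log_volume", 0.0) * z(np.log(volume))
    )
    eta = eta + _solve_intercept(eta, spec.positive_rate)
    outcome_true = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    censored = (rng.random(n) < spec.censoring_rate).astype(int)

    has_imaging = np.zeros(n, dtype=int)
    has_imaging[rng.choice(n, size=spec.n_imaging, replace=False)] = 1

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age": age,
            "bmi": bmi,
            "her2": her2,
            "histological_type": histological.astype(float),
            "progesterone": progesterone.astype(float),
            "mitotic_index": mitotic.astype(float),
            "ki67": ki67,
            "tumor_grade": grade.astype(float),
            "cancer_subtype": subtype.astype(float),
            "tumor_size_mm": tumor_size,
            "outcome_true": outcome_true,
            "censored": censored,
            "has_imaging": has_imaging,
            "latent_volume_mm3": volume,
            "tumor_side": side,
        }
    )
    df["outcome"] = np.where(df["censored"] == 0, df["outcome_true"].astype(float), np.nan)

    for feat, rate in spec.missingness.items():
        if rate > 0:
            df.loc[rng.random(n) < rate, feat] = np.nan

    uncensored_pos = int(((df["censored"] == 0) & (df["outcome_true"] == 1)).sum())
    if uncensored_pos < 5:
        raise SpecError(
            f"cohort too small for stratified 5-fold CV: "
            f"{uncensored_pos} uncensored positives (< 5)"
        )
    return df


def phantom_spec_for_patient(
    row: pd.Series,
    base: PhantomSpec | None = None,
    seed: int = 0,
) -> PhantomSpec:
    """Phantom spec whose lesion volume matches the patient's latent volume."""
    base = base if base is not None else PhantomSpec()
    radius = float((3.0 * row["latent_volume_mm3"] / (4.0 * np.pi)) ** (1.0 / 3.0))
    side = str(row["tumor_side"])
    center = base.breast_centers_mm[side]
    lesion = Lesion(center_mm=center, semiaxes_mm=(radius,) * 3, side=side)
    return replace(base, lesions=[lesion], seed=seed)
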