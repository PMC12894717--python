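"""Synthetic pancreas study generator.

Generates a complete, fully reproducible desk-scale study: a clinical cohort
table, multi-staining slide rasters (brightfield IHC and 4-channel mIF) and
pixel-exact ground-truth region masks, with configurable planted T2D
effects on islet, adipocyte and connective-tissue morphology.

The default study layout mirrors a two-site, 100-patient design with 35 T2D
patients, 9 patients lacking a HOMA2B measurement, six IHC stainings and two
mIF staining sets per patient.  Planted T2D effects are multiplicative
factors on patient-level latent morphology parameters; the generator records
the rasterized ground truth of every planted structure (per-islet areas,
per-cluster areas, connective fraction, per-islet minimum adipocyte
distances) so downstream morphometry can be validated exactly.

Geometry is deliberately simple — islets are unions of perturbed ellipses,
adipocyte clusters are packed circles, connective tissue is an anisotropic
thresholded noise field, neuronal fibers are random-walk polylines — the
minimum needed to exercise component counting, area, intensity and distance
logic. Photorealism is a non-goal.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

IHC_STAININGS: tuple[str, ...] = (
    "insulin",
    "glucagon",
    "somatostatin",
    "PECAM1",
    "perilipin1",
    "tubulinB3",
)

#: mIF staining sets; channel order is (stain1, stain2, stain3, DAPI).
MIF_SETS: dict[str, tuple[str, str, str, str]] = {
    "set1": ("glucagon", "tubulinB3", "somatostatin", "DAPI"),
    "set2": ("insulin", "PECAM1", "perilipin1", "DAPI"),
}

#: Stainings whose signal is confined to the islets of Langerhans.
ISLET_STAININGS: frozenset[str] = frozenset({"insulin", "glucagon", "somatostatin"})

COHORT_COLUMNS = (
    "patient_id",
    "diabetic_status",
    "sex",
    "age",
    "bmi",
    "homa2b",
    "insulin_therapy",
    "malignant_tumor",
    "chronic_pancreatitis",
    "diabetes_duration",
    "cohort",
)

# IHC palette (uint8 RGB). Chosen so that a scripted color segmenter can
# recover the classes: background is near-white and unsaturated, acinar
# tissue pink, connective tissue blue-violet, adipocytes cream, and
# DAB-positive signal dark brown.
_BG = np.array([255, 255, 255], dtype=np.float32)
_TISSUE = np.array([214, 176, 199], dtype=np.float32)
_CONNECTIVE = np.array([183, 186, 224], dtype=np.float32)
_ADIPOCYTE = np.array([243, 236, 226], dtype=np.float32)
_DAB = np.array([138, 100, 62], dtype=np.float32)

DEFAULT_MICRONS_PER_PIXEL = 0.45
DEFAULT_SLIDE_SHAPE = (2048, 2048)


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


class ValidationError(ValueError):
    """Raised when generator inputs violate their contracts."""


@dataclass(frozen=True)
class EffectConfig:
    """Planted multiplicative T2D effects on latent morphology.

    Each factor multiplies the corresponding patient-level latent parameter
    when ``diabetic_status == 1``; non-diabetic patients use the base values.
    All factors must be strictly positive.  ``noise_sigma`` is the standard
    deviation of the lognormal patient-level heterogeneity; section-to-
    section (staining) variability arises separately from the per-section
    sampling of structure counts and sizes.
    """

    islet_area: float = 0.6
    islet_count: float = 0.7
    adipocyte_cluster_area: float = 1.5
    adipocyte_cluster_count: float = 0.8
    connective_fraction: float = 1.4
    islet_adipocyte_distance: float = 0.6
    noise_sigma: float = 0.28

    def __post_init__(self) -> None:
        for name in (
            "islet_area",
            "islet_count",
            "adipocyte_cluster_area",
            "adipocyte_cluster_count",
            "connective_fraction",
            "islet_adipocyte_distance",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"effect factor {name!r} must be > 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")

    @classmethod
    def null(cls) -> "EffectConfig":
        """An effect configuration with all planted factors equal to 1."""
        return cls(
            islet_area=1.0,
            islet_count=1.0,
            adipocyte_cluster_area=1.0,
            adipocyte_cluster_count=1.0,
            connective_fraction=1.0,
            islet_adipocyte_distance=1.0,
        )

    def with_factors(self, **kwargs: float) -> "EffectConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PatientLatents:
    """Patient-level latent morphology intensities (pixel units).

    These are expectations shared by all serial sections (stainings) of one
    patient; each section then draws its own counts and per-structure sizes
    around them, emulating section-to-section sampling variability.
    """

    islet_rate: float            # expected islets per section
    islet_area: float            # mean planted islet area, px^2
    adipocyte_rate: float        # expected adipocyte clusters per section
    adipocyte_cluster_area: float  # mean planted cluster area, px^2
    connective_fraction: float   # target fraction of tissue
    islet_adipocyte_distance: float  # mean satellite boundary gap, px


@dataclass
class SectionPlan:
    """Planted structures of one serial section, drawn from patient latents.

    Every islet is assigned at least one "satellite" adipocyte cluster with
    a planted boundary gap, so the minimum islet–adipocyte distance of the
    section tracks the latent distance parameter.
    """

    islet_areas: np.ndarray        # px^2 per planted islet
    cluster_areas: np.ndarray      # px^2 per planted cluster
    satellite_islet: np.ndarray    # cluster index -> islet index
    satellite_gap: np.ndarray      # planted boundary gap per cluster, px
    connective_fraction: float

    @property
    def n_islets(self) -> int:
        return len(self.islet_areas)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_areas)


def sample_section(latents: PatientLatents, rng: np.random.Generator) -> SectionPlan:
    """Draw one serial section's planted structures from patient latents.

    Counts are Poisson around the patient rates (with at least one islet
    and one cluster per islet); sizes are lognormal around the latent
    means; satellite gaps are lognormal around the latent distance.
    """
    n_isl = max(1, int(rng.poisson(latents.islet_rate)))
    extra_rate = max(0.2, latents.adipocyte_rate - latents.islet_rate)
    n_cl = n_isl + int(rng.poisson(extra_rate))
    # floor keeps every planted islet above the 5000 px artifact filter,
    # so the filter never censors planted structures
    islet_areas = np.maximum(
        6200.0, latents.islet_area * np.exp(rng.normal(0.0, 0.18, n_isl))
    )
    cluster_areas = latents.adipocyte_cluster_area * np.exp(rng.normal(0.0, 0.25, n_cl))
    satellite_islet = np.arange(n_cl) % n_isl
    satellite_gap = np.maximum(
        6.0, latents.islet_adipocyte_distance * np.exp(rng.normal(0.0, 0.25, n_cl))
    )
    connective = min(0.5, latents.connective_fraction * float(np.exp(rng.normal(0.0, 0.08))))
    return SectionPlan(
        islet_areas=islet_areas,
        cluster_areas=cluster_areas,
        satellite_islet=satellite_islet,
        satellite_gap=satellite_gap,
        connective_fraction=connective,
    )


def plan_biomarkers(
    plan: SectionPlan,
    tissue_area_px: float,
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL,
) -> dict[str, float]:
    """The section's biomarkers as planted (no rasterization).

    Mirrors exactly what the morphometry module measures on a rendered
    section, up to rasterization: tissue-standardized mean islet area and
    counts, adipocyte cluster area/count, connective fraction, and the mean
    over islets of the minimum satellite gap in microns.
    """
    min_gap = np.full(plan.n_islets, np.inf)
    np.minimum.at(min_gap, plan.satellite_islet, plan.satellite_gap)
    return {
        "islet_mean_area": float(plan.islet_areas.mean()) / tissue_area_px,
        "islet_count": plan.n_islets / tissue_area_px,
        "adipocyte_cluster_area": float(plan.cluster_areas.sum()) / tissue_area_px,
        "adipocyte_cluster_count": plan.n_clusters / tissue_area_px,
        "connective_area": plan.connective_fraction,
        "islet_adipocyte_distance": float(np.mean(min_gap[np.isfinite(min_gap)]))
        * microns_per_pixel,
    }


@dataclass
class MultiChannelSlide:
    """A raster slide: pixels, channel semantics and physical resolution.

    ``pixels`` is (H, W, 3) uint8 for IHC and (H, W, 4) uint16 for mIF.
    ``staining`` is an IHC staining label or an mIF set label.
    """

    pixels: np.ndarray
    channels: tuple[str, ...]
    modality: str  # "ihc" | "mif"
    staining: str
    microns_per_pixel: float

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValidationError("microns_per_pixel must be > 0")
        if self.modality not in ("ihc", "mif"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.pixels.ndim != 3 or self.pixels.shape[2] != len(self.channels):
            raise ValidationError("pixel array does not match channel semantics")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def is_mif(self) -> bool:
        return self.modality == "mif"


@dataclass
class SlideTruth:
    """Rasterized ground truth recorded while a slide was generated.

    Areas and counts are recorded by direct summation over each planted
    structure's local bounding box (independently of any labeling
    algorithm); distances are nearest-neighbour Euclidean distances between
    islet pixels and adipocyte pixels, in pixels.
    """

    latents: PatientLatents
    plan: "SectionPlan | None"
    islet_areas: np.ndarray          # px^2 per planted islet
    adipocyte_cluster_areas: np.ndarray  # px^2 per planted cluster
    connective_area: int
    tissue_area: int
    islet_min_distances: np.ndarray  # px, per planted islet (NaN if no adipocytes)


@dataclass
class ROIMaskSet:
    """Binary region masks aligned to one slide (tissue ⊇ all other classes)."""

    tissue: np.ndarray
    islet: np.ndarray
    adipocyte: np.ndarray
    connective: np.ndarray
    truth: SlideTruth | None = None

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.tissue, self.islet, self.adipocyte, self.connective)}
        if len(shapes) != 1:
            raise ValidationError("mask shapes differ")

    def check_nesting(self) -> bool:
        t = self.tissue
        return bool(
            (~self.islet | t).all() and (~self.adipocyte | t).all() and (~self.connective | t).all()
        )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    n_patients: int = 100,
    n_t2d: int = 35,
    n_missing_homa2b: int = 9,
    cohorts: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a synthetic two-site clinical cohort table.

    Covariates are drawn so that the null logistic model of diabetic status
    given (sex, age, BMI, tumor, pancreatitis) is correctly specified: binary
    covariates differ by status via their rates, continuous covariates are
    Gaussian with status-shifted means and *equal* spreads. Diabetes
    duration is positive only for T2D patients, insulin therapy occurs only
    in T2D, and HOMA2B is missing for exactly ``n_missing_homa2b`` patients
    chosen uniformly at random, independent of status.

    T2D patients are allocated so that the second cohort is approximately
    balanced while the first carries the remaining imbalance, mirroring a
    two-site design with one balanced site.
    """
    if cohorts is None:
        cohorts = {"A": 59, "B": 41}
    if n_patients <= 0:
        raise ValidationError("n_patients must be positive")
    if not (0 <= n_t2d <= n_patients):
        raise ValidationError("n_t2d must lie in [0, n_patients]")
    if not (0 <= n_missing_homa2b <= n_patients):
        raise ValidationError("n_missing_homa2b must lie in [0, n_patients]")
    if len(cohorts) != 2:
        raise ValidationError("exactly two cohorts are supported")
    if sum(cohorts.values()) != n_patients:
        raise ValidationError("cohort sizes must sum to n_patients")
    if any(v < 0 for v in cohorts.values()):
        raise ValidationError("cohort sizes must be non-negative")

    rng = np.random.default_rng(seed)
    (name_a, n_a), (name_b, n_b) = cohorts.items()
    cohort = np.array([name_a] * n_a + [name_b] * n_b)

    # Balanced second site, remainder in the first.
    n_t2d_b = min(n_b, n_t2d, int(round(n_b * 0.5)))
    n_t2d_a = n_t2d - n_t2d_b
    if n_t2d_a > n_a:  # overflow back into B
        n_t2d_b += n_t2d_a - n_a
        n_t2d_a = n_a
    status = np.zeros(n_patients, dtype=int)
    idx_a = np.arange(n_a)
    idx_b = n_a + np.arange(n_b)
    status[rng.choice(idx_a, size=n_t2d_a, replace=False)] = 1
    status[rng.choice(idx_b, size=n_t2d_b, replace=False)] = 1

    t2d = status == 1
    sex = (rng.random(n_patients) < np.where(t2d, 0.60, 0.48)).astype(int)
    age = np.clip(rng.normal(np.where(t2d, 64.0, 58.0), 11.0), 20.0, 88.0)
    bmi = np.clip(rng.normal(np.where(t2d, 29.0, 26.0), 4.0), 16.0, 45.0)
    malignant = (rng.random(n_patients) < np.where(t2d, 0.55, 0.45)).astype(int)
    pancreatitis = (rng.random(n_patients) < np.where(t2d, 0.25, 0.12)).astype(int)
    insulin_therapy = (t2d & (rng.random(n_patients) < 0.4)).astype(int)
    duration = np.where(t2d, np.clip(rng.gamma(2.2, 4.0, n_patients), 1.0, 35.0), 0.0)
    homa2b = np.clip(rng.normal(np.where(t2d, 62.0, 105.0), 24.0), 6.0, 220.0)
    missing = rng.choice(n_patients, size=n_missing_homa2b, replace=False)
    homa2b[missing] = np.nan

    table = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n_patients)],
            "diabetic_status": status,
            "sex": sex,
            "age": np.round(age, 1),
            "bmi": np.round(bmi, 1),
            "homa2b": np.round(homa2b, 1),
            "insulin_therapy": insulin_therapy,
            "malignant_tumor": malignant,
            "chronic_pancreatitis": pancreatitis,
            "diabetes_duration": np.round(duration, 1),
            "cohort": cohort,
        }
    )
    return table


# ---------------------------------------------------------------------------
# Patient latents
# ---------------------------------------------------------------------------

# Base (non-diabetic) latent morphology at 0.45 um/px on a 2048^2 slide.
# Adipocyte clusters outnumber islets so that every islet has a proximal
# ("satellite") cluster at the planted distance; otherwise the measured
# minimum distance would track the cluster count rather than the planted
# distance factor.
_BASE_N_ISLETS = 9.0
_BASE_ISLET_AREA = 13000.0        # px^2  (~2600 um^2)
_BASE_N_ADIP_CLUSTERS = 14.0
_BASE_ADIP_CLUSTER_AREA = 7000.0  # px^2
_BASE_CONNECTIVE_FRACTION = 0.10
_BASE_ISLET_ADIP_DISTANCE = 190.0  # px (~86 um)


def patient_latents(
    patient_row: pd.Series | dict,
    effects: EffectConfig | None = None,
    seed: int = 0,
) -> PatientLatents:
    """Draw the latent morphology intensities for one patient.

    Latents are lognormal around the base values, shifted multiplicatively by
    the planted effect factors when the patient is diabetic.  The draw is a
    pure function of ``(seed, patient_id)``, so all serial sections of a
    patient share the same underlying intensities while each section samples
    its own structures around them.
    """
    effects = effects or EffectConfig()
    pid = str(patient_row["patient_id"])
    t2d = int(patient_row["diabetic_status"]) == 1
    rng = np.random.default_rng([seed, _stable_hash(pid), 0x15E7])

    def draw(base: float, factor: float) -> float:
        value = base * float(np.exp(rng.normal(0.0, effects.noise_sigma)))
        return value * factor if t2d else value

    return PatientLatents(
        islet_rate=draw(_BASE_N_ISLETS, effects.islet_count),
        islet_area=draw(_BASE_ISLET_AREA, effects.islet_area),
        adipocyte_rate=draw(_BASE_N_ADIP_CLUSTERS, effects.adipocyte_cluster_count),
        adipocyte_cluster_area=draw(_BASE_ADIP_CLUSTER_AREA, effects.adipocyte_cluster_area),
        connective_fraction=min(0.5, draw(_BASE_CONNECTIVE_FRACTION, effects.connective_fraction)),
        islet_adipocyte_distance=draw(_BASE_ISLET_ADIP_DISTANCE, effects.islet_adipocyte_distance),
    )


# ---------------------------------------------------------------------------
# Geometry rendering
# ---------------------------------------------------------------------------

def _tissue_mask(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Wobbly-ellipse tissue section.

    The signed boundary field is evaluated on a coarse grid and linearly
    upsampled before thresholding — the boundary is smooth at that scale,
    and this keeps slide generation fast at full resolution.
    """
    from scipy.ndimage import zoom

    h, w = shape
    cy = h / 2 + rng.uniform(-0.02, 0.02) * h
    cx = w / 2 + rng.uniform(-0.02, 0.02) * w
    a = 0.46 * w * (1 + rng.uniform(-0.03, 0.03))
    b = 0.44 * h * (1 + rng.uniform(-0.03, 0.03))
    p1, p2 = rng.uniform(0, 2 * np.pi, 2)
    f = 8 if (h % 8 == 0 and w % 8 == 0) else 1
    yy = ((np.arange(h // f, dtype=np.float32) + 0.5) * f - 0.5 - cy)[:, None] / b
    xx = ((np.arange(w // f, dtype=np.float32) + 0.5) * f - 0.5 - cx)[None, :] / a
    r2 = xx * xx + yy * yy
    theta = np.arctan2(yy, xx)
    field = 1 + 0.06 * np.sin(3 * theta + p1) + 0.04 * np.sin(7 * theta + p2) - r2
    if f > 1:
        field = zoom(field, f, order=1, grid_mode=True, mode="nearest")
    return field >= 0.0


@dataclass
class _Geometry:
    tissue: np.ndarray
    islet: np.ndarray
    adipocyte: np.ndarray
    connective: np.ndarray
    islet_areas: list[int]
    islet_centers: list[tuple[float, float]]
    islet_radii: list[float]
    islet_pixel_lists: list[np.ndarray]  # (k,2) int coords per islet
    cluster_areas: list[int]
    cluster_circles: list[list[tuple[float, float, float]]]
    fiber_mask: np.ndarray | None
    vessel_mask: np.ndarray | None


def _blob_params(rng: np.random.Generator) -> list[tuple[float, float, float, float, float]]:
    """Shape parameters for a 3-ellipse blob, relative to a unit radius."""
    return [
        (
            rng.uniform(0, np.pi),
            rng.uniform(0.75, 1.3),
            rng.uniform(0.85, 1.1),
            rng.uniform(-0.25, 0.25),
            rng.uniform(-0.25, 0.25),
        )
        for _ in range(3)
    ]


def _islet_blob(r: float, params: list[tuple[float, float, float, float, float]]) -> np.ndarray:
    """Union of 3 oriented ellipses: a smooth irregular blob mask.

    All ellipse radii and offsets scale with ``r``, so the blob area scales
    as r^2 exactly (up to rasterization) — which makes a one-step radius
    rescale calibrate the rasterized area to a planned target.
    """
    size = int(np.ceil(3.4 * r))
    c = size / 2
    yy = np.arange(size, dtype=np.float32)[:, None] - c
    xx = np.arange(size, dtype=np.float32)[None, :] - c
    mask = np.zeros((size, size), dtype=bool)
    for ang, asp, ra_rel, off_y, off_x in params:
        ra = r * ra_rel
        dy = yy + off_y * r
        dx = xx + off_x * r
        u = np.cos(ang) * dx + np.sin(ang) * dy
        v = -np.sin(ang) * dx + np.cos(ang) * dy
        mask |= (u / (ra * asp)) ** 2 + (v / (ra / asp)) ** 2 <= 1.0
    return mask


def _layout_area(layout: list[tuple[float, float, float]]) -> int:
    """Rasterized union area of a circle layout on a scratch canvas."""
    pad = 2
    y0 = min(ly - r for (ly, _, r) in layout) - pad
    x0 = min(lx - r for (_, lx, r) in layout) - pad
    y1 = max(ly + r for (ly, _, r) in layout) + pad
    x1 = max(lx + r for (_, lx, r) in layout) + pad
    yy = np.arange(int(np.floor(y0)), int(np.ceil(y1)) + 1, dtype=np.float32)[:, None]
    xx = np.arange(int(np.floor(x0)), int(np.ceil(x1)) + 1, dtype=np.float32)[None, :]
    mask = np.zeros((yy.shape[0], xx.shape[1]), dtype=bool)
    for (ly, lx, r) in layout:
        mask |= (yy - ly) ** 2 + (xx - lx) ** 2 <= r * r
    return int(mask.sum())


def _paste(mask: np.ndarray, local: np.ndarray, y0: int, x0: int) -> tuple[slice, slice]:
    h, w = mask.shape
    lh, lw = local.shape
    ys, xs = slice(max(y0, 0), min(y0 + lh, h)), slice(max(x0, 0), min(x0 + lw, w))
    lys = slice(ys.start - y0, ys.stop - y0)
    lxs = slice(xs.start - x0, xs.stop - x0)
    mask[ys, xs] |= local[lys, lxs]
    return ys, xs


def _sample_geometry(
    plan: SectionPlan, shape: tuple[int, int], rng: np.random.Generator
) -> _Geometry:
    """Place and rasterize the planned structures of one section.

    Islet blobs are rescaled once so their rasterized area matches the
    planned area within a few percent; satellite clusters are anchored at
    their islet's boundary with the planted gap along a random direction,
    growing additional adipocyte circles away from the islet so the planted
    gap remains the cluster's closest approach.
    """
    from scipy.ndimage import binary_erosion

    h, w = shape
    tissue = _tissue_mask(shape, rng)
    islet = np.zeros(shape, dtype=bool)
    adipocyte = np.zeros(shape, dtype=bool)

    cy, cx = h / 2, w / 2
    safe_ry, safe_rx = 0.40 * h, 0.42 * w

    # --- islets ---------------------------------------------------------
    islet_centers: list[tuple[float, float]] = []
    islet_radii: list[float] = []
    islet_areas: list[int] = []
    islet_pixel_lists: list[np.ndarray] = []
    placed_index: list[int] = []  # plan islet index of each placed islet
    for i, area_i in enumerate(plan.islet_areas):
        r = float(np.sqrt(area_i / np.pi))
        placed = False
        for _try in range(120):
            u = np.sqrt(rng.uniform(0, 1))
            phi = rng.uniform(0, 2 * np.pi)
            yc = cy + u * safe_ry * np.sin(phi)
            xc = cx + u * safe_rx * np.cos(phi)
            ok = all(
                np.hypot(yc - yo, xc - xo) >= 2.0 * (r + ro)
                for (yo, xo), ro in zip(islet_centers, islet_radii)
            )
            if ok:
                placed = True
                break
        if not placed:
            continue
        params = _blob_params(rng)
        local = _islet_blob(r, params)
        # one-step area calibration toward the planned area (same shape)
        act = local.sum()
        if act > 0:
            local = _islet_blob(r * float(np.sqrt(area_i / act)), params)
        y0 = int(round(yc)) - local.shape[0] // 2
        x0 = int(round(xc)) - local.shape[1] // 2
        ys, xs = _paste(islet, local, y0, x0)
        # clip to tissue and record rasterized truth by direct summation
        region = islet[ys, xs] & tissue[ys, xs]
        islet[ys, xs] = region
        # boundary pixels suffice for exact minimum distances to outside sets
        boundary = region & ~binary_erosion(region)
        coords = np.argwhere(boundary)
        coords[:, 0] += ys.start
        coords[:, 1] += xs.start
        islet_areas.append(int(region.sum()))
        islet_pixel_lists.append(coords)
        islet_centers.append((yc, xc))
        islet_radii.append(r * 1.35)  # effective max extent of the blob
        placed_index.append(i)

    plan_to_placed = {pi: k for k, pi in enumerate(placed_index)}
    plan_min_gap = np.full(plan.n_islets, np.inf)
    np.minimum.at(plan_min_gap, plan.satellite_islet, plan.satellite_gap)

    # --- adipocyte clusters --------------------------------------------
    cluster_areas: list[int] = []
    cluster_circles_all: list[list[tuple[float, float, float]]] = []
    all_circles: list[tuple[float, float, float]] = []
    for j in range(plan.n_clusters):
        area_c = plan.cluster_areas[j]
        m = 1 + int(rng.poisson(2.0))
        r_cell = float(np.clip(np.sqrt(area_c / (m * np.pi)), 8.0, 90.0))
        gap = float(plan.satellite_gap[j])
        k = plan_to_placed.get(int(plan.satellite_islet[j]))

        # circle layout in a canonical frame: first circle at the origin,
        # extras growing into the +x half-plane (later rotated so +x points
        # away from the anchoring islet and the planted gap stays minimal)
        layout = [(0.0, 0.0, r_cell)]
        for _ in range(m - 1):
            for _grow in range(12):
                yb, xb, rb = layout[int(rng.integers(len(layout)))]
                rn = r_cell * rng.uniform(0.85, 1.1)
                ang = rng.uniform(-1.2, 1.2)
                cand = (yb + (rb + rn) * 0.88 * np.sin(ang), xb + (rb + rn) * 0.88 * np.cos(ang), rn)
                if cand[1] >= -0.2 * r_cell and np.hypot(cand[0], cand[1]) <= 2.6 * r_cell:
                    layout.append(cand)
                    break
        # calibrate the union area (circles overlap) to the planned area
        act0 = _layout_area(layout)
        if act0 > 0:
            s_cal = float(np.sqrt(area_c / act0))
            layout = [(ly * s_cal, lx * s_cal, r * s_cal) for (ly, lx, r) in layout]
            r_cell *= s_cal

        def try_placement(yc, xc, phi, protect_scale, anchored=True):
            """Exact per-circle clearance test; returns circles or None."""
            sin_p, cos_p = np.sin(phi), np.cos(phi)
            circles = [
                (yc + cos_p * ly + sin_p * lx, xc - sin_p * ly + cos_p * lx, r)
                for (ly, lx, r) in layout
            ]
            if not all(
                0.03 * h < yy_ < 0.97 * h and 0.03 * w < xx_ < 0.97 * w
                for (yy_, xx_, _) in circles
            ):
                return None
            # every circle center must lie on tissue, or the cluster would
            # be clipped away (or partially lost) at rasterization
            if not all(tissue[int(yy_), int(xx_)] for (yy_, xx_, _) in circles):
                return None
            # every other islet keeps (a scaled fraction of) its own planned
            # minimum gap, so foreign clusters cannot undercut its distance
            # biomarker; the anchoring islet keeps the planted gap itself
            for o, ((yo, xo), ro) in enumerate(zip(islet_centers, islet_radii)):
                if anchored and k is not None and o == k:
                    bc = islet_pixel_lists[o]
                    for (cyc, cxc, rc) in circles[1:]:
                        d_b = float(np.min(np.hypot(bc[:, 0] - cyc, bc[:, 1] - cxc))) - rc
                        if d_b < 0.85 * gap:
                            return None
                else:
                    protect = min(plan_min_gap[placed_index[o]], 400.0) * protect_scale
                    for (cyc, cxc, rc) in circles:
                        if np.hypot(cyc - yo, cxc - xo) < ro + rc + protect:
                            return None
            for (yo, xo, ro) in all_circles:
                for (cyc, cxc, rc) in circles:
                    if np.hypot(cyc - yo, cxc - xo) < ro + rc + 5:
                        return None
            return circles

        def anchor_at(phi):
            """Anchor the first circle at the islet boundary at the planted gap."""
            yc_i, xc_i = islet_centers[k]
            bcoords = islet_pixel_lists[k]
            ang = np.arctan2(bcoords[:, 0] - yc_i, bcoords[:, 1] - xc_i)
            bi = int(np.argmin(np.abs(np.angle(np.exp(1j * (ang - phi))))))
            by, bx = bcoords[bi]
            uy, ux = np.sin(phi), np.cos(phi)
            yc = by + uy * (gap + r_cell)
            xc = bx + ux * (gap + r_cell)
            # one curvature-correction step so the closest boundary pixel
            # sits at the planted gap
            d_act = float(np.min(np.hypot(bcoords[:, 0] - yc, bcoords[:, 1] - xc)) - r_cell)
            return yc + uy * (gap - d_act), xc + ux * (gap - d_act)

        circles = None
        if k is not None:
            # scan candidate directions, relaxing foreign protection in steps
            angles = rng.permutation(np.linspace(0, 2 * np.pi, 36, endpoint=False))
            for protect_scale in (0.9, 0.6, 0.3):
                for phi in angles:
                    yc, xc = anchor_at(phi + rng.uniform(-0.05, 0.05))
                    circles = try_placement(yc, xc, phi, protect_scale)
                    if circles is not None:
                        break
                if circles is not None:
                    break
        if circles is None:
            # uniform fallback with graded, finally zero, protection: a
            # mild distance bias is preferable to losing the cluster, which
            # would distort the count and area biomarkers asymmetrically
            for _try in range(140):
                u = np.sqrt(rng.uniform(0, 1))
                phi = rng.uniform(0, 2 * np.pi)
                yc = cy + u * safe_ry * np.sin(phi)
                xc = cx + u * safe_rx * np.cos(phi)
                scale = 0.9 if _try < 40 else (0.3 if _try < 90 else 0.0)
                circles = try_placement(yc, xc, phi, scale, anchored=False)
                if circles is not None:
                    break
        if circles is None:
            continue
        ys_min = int(min(c[0] - c[2] for c in circles)) - 2
        xs_min = int(min(c[1] - c[2] for c in circles)) - 2
        ys_max = int(max(c[0] + c[2] for c in circles)) + 3
        xs_max = int(max(c[1] + c[2] for c in circles)) + 3
        ys_min, xs_min = max(ys_min, 0), max(xs_min, 0)
        ys_max, xs_max = min(ys_max, h), min(xs_max, w)
        if ys_max <= ys_min or xs_max <= xs_min:
            continue
        ly = np.arange(ys_min, ys_max, dtype=np.float32)[:, None]
        lx = np.arange(xs_min, xs_max, dtype=np.float32)[None, :]
        local = np.zeros((ys_max - ys_min, xs_max - xs_min), dtype=bool)
        for (yc_c, xc_c, r_c) in circles:
            local |= (ly - yc_c) ** 2 + (lx - xc_c) ** 2 <= r_c**2
        local &= tissue[ys_min:ys_max, xs_min:xs_max]
        local &= ~islet[ys_min:ys_max, xs_min:xs_max]
        area = int(local.sum())
        if area == 0:
            continue
        adipocyte[ys_min:ys_max, xs_min:xs_max] |= local
        cluster_areas.append(area)
        cluster_circles_all.append(circles)
        all_circles.extend(circles)

    # --- connective tissue: anisotropic thresholded noise field ---------
    coarse = rng.normal(size=(h // 8, w // 8)).astype(np.float32)
    sig = (6.0, 1.5) if rng.random() < 0.5 else (1.5, 6.0)
    coarse = gaussian_filter(coarse, sigma=sig)
    field = np.repeat(np.repeat(coarse, 8, axis=0), 8, axis=1)
    avail = tissue & ~islet & ~adipocyte
    n_avail = int(avail.sum())
    target = plan.connective_fraction * int(tissue.sum())
    frac = min(0.9, target / max(n_avail, 1))
    thresh = np.quantile(field[avail], 1.0 - frac) if n_avail else np.inf
    connective = avail & (field >= thresh)

    # --- fibers and vessels (rendering-only structures) -----------------
    fiber = _random_walk_mask(shape, tissue, rng, n_walks=14, n_steps=2400)
    vessel = _random_walk_mask(shape, tissue, rng, n_walks=26, n_steps=700)

    return _Geometry(
        tissue=tissue,
        islet=islet,
        adipocyte=adipocyte,
        connective=connective,
        islet_areas=islet_areas,
        islet_centers=islet_centers,
        islet_radii=islet_radii,
        islet_pixel_lists=islet_pixel_lists,
        cluster_areas=cluster_areas,
        cluster_circles=cluster_circles_all,
        fiber_mask=fiber,
        vessel_mask=vessel,
    )


def _random_walk_mask(
    shape: tuple[int, int],
    tissue: np.ndarray,
    rng: np.random.Generator,
    n_walks: int,
    n_steps: int,
) -> np.ndarray:
    """Smooth random-walk polylines (neuronal fibers / vessel strands)."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_walks):
        y = rng.uniform(0.2 * h, 0.8 * h)
        x = rng.uniform(0.2 * w, 0.8 * w)
        ang = rng.uniform(0, 2 * np.pi)
        steps = rng.normal(0, 0.25, n_steps).cumsum() + ang
        ys = np.clip(y + np.cumsum(np.sin(steps)) * 1.6, 0, h - 1).astype(np.intp)
        xs = np.clip(x + np.cumsum(np.cos(steps)) * 1.6, 0, w - 1).astype(np.intp)
        mask[ys, xs] = True
        mask[np.minimum(ys + 1, h - 1), xs] = True
        mask[ys, np.minimum(xs + 1, w - 1)] = True
    mask &= tissue
    return mask


def _truth_distances(geom: _Geometry) -> np.ndarray:
    """Per-islet min Euclidean distance (px) to the nearest adipocyte pixel.

    Computed with a KD-tree over adipocyte pixels, independently of the
    distance-transform route used by the morphometry module.
    """
    if not geom.islet_pixel_lists:
        return np.array([])
    adip_pts = np.argwhere(geom.adipocyte)
    if len(adip_pts) == 0:
        return np.full(len(geom.islet_pixel_lists), np.nan)
    tree = cKDTree(adip_pts)
    out = []
    for coords in geom.islet_pixel_lists:
        if len(coords) == 0:
            out.append(np.nan)
            continue
        d, _ = tree.query(coords, k=1)
        out.append(float(np.min(d)))
    return np.array(out)


# ---------------------------------------------------------------------------
# Pixel rendering
# ---------------------------------------------------------------------------

def _render_ihc(geom: _Geometry, staining: str, rng: np.random.Generator) -> np.ndarray:
    """Palette rendering via a label image and a color lookup table.

    The same luminance noise is added to all three channels, so pixel
    saturation is noise-free and the scripted color segmenter sees crisp
    class boundaries (stylization, not photorealism).
    """
    h, w = geom.tissue.shape
    lab = np.zeros((h, w), dtype=np.uint8)
    lab[geom.tissue] = 1
    lab[geom.connective] = 2
    lab[geom.adipocyte] = 3

    dab_tint = (0.78 * _TISSUE + 0.22 * _DAB).round()
    palette = np.stack([_BG, _TISSUE, _CONNECTIVE, _ADIPOCYTE, _DAB, dab_tint]).astype(np.int16)

    if staining in ISLET_STAININGS:
        lab[geom.islet] = 4
    elif staining == "perilipin1":
        lab[_adipocyte_rims(geom)] = 4
    elif staining == "PECAM1":
        if geom.vessel_mask is not None:
            lab[geom.vessel_mask] = 4
    elif staining == "tubulinB3":
        lab[geom.islet] = 5
        if geom.fiber_mask is not None:
            lab[geom.fiber_mask] = 4
    else:
        raise ValidationError(f"unknown IHC staining {staining!r}")

    img = palette[lab]  # (h, w, 3) int16
    noise = rng.integers(-4, 5, size=(h, w), dtype=np.int16)
    img += noise[:, :, None]
    np.clip(img, 0, 255, out=img)
    return img.astype(np.uint8)


def _adipocyte_rims(geom: _Geometry) -> np.ndarray:
    """Thin rims of the adipocyte circles (perilipin stains droplet membranes)."""
    h, w = geom.adipocyte.shape
    rim = np.zeros((h, w), dtype=bool)
    for circles in geom.cluster_circles:
        for (yc, xc, r) in circles:
            y0, y1 = max(int(yc - r) - 2, 0), min(int(yc + r) + 3, h)
            x0, x1 = max(int(xc - r) - 2, 0), min(int(xc + r) + 3, w)
            ly = np.arange(y0, y1, dtype=np.float32)[:, None]
            lx = np.arange(x0, x1, dtype=np.float32)[None, :]
            d2 = (ly - yc) ** 2 + (lx - xc) ** 2
            rim[y0:y1, x0:x1] |= (d2 <= r**2) & (d2 >= (r - 3.0) ** 2)
    rim &= geom.adipocyte
    return rim


def _render_mif(geom: _Geometry, set_label: str, rng: np.random.Generator) -> np.ndarray:
    h, w = geom.tissue.shape
    channels = MIF_SETS[set_label]
    img = np.zeros((h, w, 4), dtype=np.float32)
    tissue = geom.tissue
    for c, label in enumerate(channels):
        plane = img[:, :, c]
        plane += rng.normal(90.0, 30.0, size=(h, w)).astype(np.float32)  # detector floor
        if label == "DAPI":
            plane[tissue] += rng.normal(3000.0, 500.0, size=int(tissue.sum()))
        elif label in ISLET_STAININGS:
            plane[tissue] += 120.0
            n = int(geom.islet.sum())
            plane[geom.islet] += rng.normal(18000.0, 2500.0, size=n)
        elif label == "perilipin1":
            # contract: intensity > 1000 only inside the adipocyte mask
            np.clip(plane, 0, 850.0, out=plane)
            n = int(geom.adipocyte.sum())
            plane[geom.adipocyte] = 1200.0 + np.abs(rng.normal(7000.0, 1800.0, size=n))
        elif label == "PECAM1":
            plane[tissue] += 150.0
            if geom.vessel_mask is not None:
                n = int(geom.vessel_mask.sum())
                plane[geom.vessel_mask] += rng.normal(9000.0, 1500.0, size=n)
        elif label == "tubulinB3":
            plane[tissue] += 150.0
            if geom.fiber_mask is not None:
                n = int(geom.fiber_mask.sum())
                plane[geom.fiber_mask] += rng.normal(9000.0, 1500.0, size=n)
            plane[geom.islet] += 2200.0
    return np.clip(img, 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# Public slide API
# ---------------------------------------------------------------------------

def generate_slide(
    patient_row: pd.Series | dict,
    staining: str,
    shape: tuple[int, int] = DEFAULT_SLIDE_SHAPE,
    effects: EffectConfig | None = None,
    seed: int = 0,
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL,
) -> tuple[MultiChannelSlide, ROIMaskSet]:
    """Render one synthetic slide and its exact ground-truth masks.

    ``staining`` is an IHC staining label or an mIF set label ("set1"/"set2").
    Each staining is a distinct serial section: all sections of one patient
    share the latent morphology intensities (a pure function of
    ``(seed, patient_id)``), while each section samples its own structure
    counts, sizes and positions — and its section plan is drawn from the
    same seeded stream that :func:`simulate_biomarker_table` uses, so
    rendered and simulated sections of the same (patient, staining) agree.
    The returned :class:`ROIMaskSet` carries a :class:`SlideTruth` record
    of the rasterized planted structures.
    """
    if shape[0] < 512 or shape[1] < 512:
        raise ValidationError("slide shape must be at least 512 x 512")
    effects = effects or EffectConfig()
    is_mif = staining in MIF_SETS
    if not is_mif and staining not in IHC_STAININGS:
        raise ValidationError(f"unknown staining label {staining!r}")

    pid = str(patient_row["patient_id"])
    latents = patient_latents(patient_row, effects, seed)
    plan = sample_section(latents, _section_rng(seed, pid, staining))
    geom_rng = np.random.default_rng([seed, _stable_hash(pid), _stable_hash(staining), 0x6E0])
    geom = _sample_geometry(plan, shape, geom_rng)

    render_rng = np.random.default_rng([seed, _stable_hash(pid), _stable_hash(staining), 0x9E])
    if is_mif:
        pixels = _render_mif(geom, staining, render_rng)
        slide = MultiChannelSlide(
            pixels=pixels,
            channels=MIF_SETS[staining],
            modality="mif",
            staining=staining,
            microns_per_pixel=microns_per_pixel,
        )
    else:
        pixels = _render_ihc(geom, staining, render_rng)
        slide = MultiChannelSlide(
            pixels=pixels,
            channels=("R", "G", "B"),
            modality="ihc",
            staining=staining,
            microns_per_pixel=microns_per_pixel,
        )

    truth = SlideTruth(
        latents=latents,
        plan=plan,
        islet_areas=np.array(geom.islet_areas, dtype=int),
        adipocyte_cluster_areas=np.array(geom.cluster_areas, dtype=int),
        connective_area=int(geom.connective.sum()),
        tissue_area=int(geom.tissue.sum()),
        islet_min_distances=_truth_distances(geom),
    )
    masks = ROIMaskSet(
        tissue=geom.tissue,
        islet=geom.islet,
        adipocyte=geom.adipocyte,
        connective=geom.connective,
        truth=truth,
    )
    return slide, masks


# ---------------------------------------------------------------------------
# Fast section-level biomarker simulation (no rasterization)
# ---------------------------------------------------------------------------

def _section_rng(seed: int, pid: str, staining: str) -> np.random.Generator:
    return np.random.default_rng([seed, _stable_hash(pid), _stable_hash(staining), 0x5EC])


def simulate_biomarker_table(
    cohort: pd.DataFrame,
    effects: EffectConfig | None = None,
    seed: int = 0,
    stainings: tuple[str, ...] = IHC_STAININGS,
    tissue_area_px: float = 2.5e6,
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL,
) -> pd.DataFrame:
    """Simulate a per-(patient, staining) biomarker table without rendering.

    Draws the same patient latents and per-section plans the slide renderer
    consumes (identical seeded streams), then reads the biomarkers directly
    off each plan.  A simulated row for (patient, staining) therefore
    matches the biomarkers measured on the rendered section up to
    rasterization, which makes this the fast path for large statistical
    simulations (null calibration, power) and for the non-rendered serial
    sections in the stacked association design.
    """
    effects = effects or EffectConfig()
    rows = []
    for _, row in cohort.iterrows():
        pid = str(row["patient_id"])
        lat = patient_latents(row, effects, seed)
        for staining in stainings:
            plan = sample_section(lat, _section_rng(seed, pid, staining))
            bm = plan_biomarkers(plan, tissue_area_px, microns_per_pixel)
            rows.append({"patient_id": row["patient_id"], "staining": staining, **bm})
    return pd.DataFrame(rows)
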