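"""Tissue-standardized attention quantification and histologic biomarkers.

Attention to a region of interest is measured as a density ratio: the mean
attention of patches overlapping the ROI divided by the mean attention of
all tissue patches, so a value of 1 means the ROI is attended exactly at
the tissue average (and is identically 1 for stainings whose signal is
confined to the ROI).

Histologic biomarkers follow the study's rules: connected components
(8-connectivity) count islets and adipocyte clusters — islet components
must exceed 5000 px to exclude segmentation artifacts, while a single
non-connected adipocyte already counts as one cluster — areas and counts
are standardized by total tissue size, islet–adipocyte proximity is the
mean over islets of the boundary-to-boundary minimum Euclidean distance,
and mIF channel intensity is averaged over tissue (perilipin 1 after
zeroing values at or below 1000 on the 16-bit scale).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops

from isletscope.synthetic import (
    ISLET_STAININGS,
    MIF_SETS,
    MultiChannelSlide,
    ROIMaskSet,
    ValidationError,
)
from isletscope.tiling import PatchGrid, patch_fractions

ISLET_MIN_AREA_PX = 5000
PERILIPIN_INTENSITY_THRESHOLD = 1000.0


# ---------------------------------------------------------------------------
# Attention quantification
# ---------------------------------------------------------------------------

def roi_attention(
    attention: np.ndarray,
    roi_mask: np.ndarray | None,
    grid: PatchGrid,
    overlap_fraction: float = 0.05,
    roi_fractions: np.ndarray | None = None,
) -> float:
    """Attention density ratio of an ROI relative to the tissue average.

    ``attention`` holds one score per tissue patch (grid order).  A patch
    overlaps the ROI when at least ``overlap_fraction`` of its pixels lie in
    the mask.  Returns NaN (missing) when no tissue patch overlaps the ROI —
    an absent ROI carries no information and must not fabricate a zero.
    Invariant to rescaling all attention scores by a positive constant.
    Instead of a pixel mask, precomputed per-patch ROI pixel fractions (all
    patches, grid order) may be supplied via ``roi_fractions``.
    """
    attention = np.asarray(attention, dtype=float)
    tissue_idx = grid.tissue_indices()
    if len(attention) != len(tissue_idx):
        raise ValidationError("attention must align with the tissue patches")
    if len(tissue_idx) == 0:
        return float("nan")
    if roi_fractions is None:
        roi_fractions = patch_fractions(roi_mask, grid)
    fracs = np.asarray(roi_fractions, dtype=float)[tissue_idx]
    overlapping = fracs >= max(overlap_fraction, np.finfo(float).tiny)
    if not overlapping.any():
        return float("nan")
    numerator = attention[overlapping].sum() / overlapping.sum()
    denominator = attention.sum() / len(attention)
    if denominator == 0:
        return float("nan")
    return float(numerator / denominator)


def mif_channel_attention(
    channel_attention: Mapping[str, np.ndarray],
    n_tissue_patches: int,
) -> pd.DataFrame:
    """Per-channel attention shares, with and without tissue normalization.

    ``share`` divides each channel's summed attention by the total over all
    channels (shares sum to 1); ``share_per_tissue_patch`` additionally
    standardizes by the tissue size so slides of different extents compare.
    """
    if n_tissue_patches <= 0:
        raise ValidationError("tissue patch count must be positive")
    sums = {c: float(np.asarray(a, dtype=float).sum()) for c, a in channel_attention.items()}
    total = sum(sums.values())
    if total == 0:
        raise ValidationError("all-zero attention cannot be normalized")
    rows = [
        {
            "channel": c,
            "share": s / total,
            "share_per_tissue_patch": s / total / n_tissue_patches,
        }
        for c, s in sums.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------

@dataclass
class Component:
    area: int
    centroid: tuple[float, float]
    coords: np.ndarray  # (k, 2) pixel coordinates


def _components(mask: np.ndarray, min_area: int) -> list[Component]:
    labeled = label(np.asarray(mask, dtype=bool), connectivity=2)
    out = []
    for region in regionprops(labeled):
        if region.area > min_area:
            out.append(
                Component(
                    area=int(region.area),
                    centroid=tuple(region.centroid),
                    coords=region.coords,
                )
            )
    return out


def islet_components(mask: np.ndarray, min_area: int = ISLET_MIN_AREA_PX) -> list[Component]:
    """8-connected islet components with area strictly above ``min_area``."""
    return _components(mask, min_area)


def adipocyte_clusters(mask: np.ndarray) -> list[Component]:
    """8-connected adipocyte clusters; a single adipocyte is one cluster."""
    return _components(mask, 0)


def relative_area(roi_mask: np.ndarray, tissue_mask: np.ndarray) -> float:
    """|roi ∩ tissue| / |tissue|; errors on empty tissue."""
    tissue = np.asarray(tissue_mask, dtype=bool)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValidationError("tissue mask is empty")
    return float((np.asarray(roi_mask, dtype=bool) & tissue).sum() / n_tissue)


def _mask_boundary(mask: np.ndarray) -> np.ndarray:
    """Pixels of ``mask`` with at least one of their 8 neighbours outside."""
    m = np.asarray(mask, dtype=bool)
    interior = m.copy()
    interior[0, :] = interior[-1, :] = interior[:, 0] = interior[:, -1] = False
    core = interior[1:-1, 1:-1]
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy or dx:
                core &= m[1 + dy : m.shape[0] - 1 + dy, 1 + dx : m.shape[1] - 1 + dx]
    return m & ~interior


def islet_adipocyte_distance(
    islets: Sequence[Component],
    adipocyte_mask: np.ndarray,
    microns_per_pixel: float = 1.0,
) -> float:
    """Mean over islets of the minimum distance to the nearest adipocyte (um).

    For each islet the minimum over its pixels of the Euclidean distance
    transform of the adipocyte mask is taken (boundary-to-boundary, not
    centroid-to-centroid).  The minimum of a distance transform over a
    pixel set is attained on the set's boundary, so it is computed exactly
    with a nearest-neighbour query between boundary pixels (overlapping
    masks yield distance 0).  Missing (NaN) when there are no islets or no
    adipocytes.
    """
    if not islets:
        return float("nan")
    adip = np.asarray(adipocyte_mask, dtype=bool)
    if not adip.any():
        return float("nan")
    from scipy.spatial import cKDTree

    tree = cKDTree(np.argwhere(_mask_boundary(adip)))
    dists = []
    for c in islets:
        if adip[c.coords[:, 0], c.coords[:, 1]].any():
            dists.append(0.0)
            continue
        boundary = c.coords[_component_boundary_selector(c)]
        d, _ = tree.query(boundary, k=1)
        dists.append(float(np.min(d)))
    return float(np.mean(dists) * microns_per_pixel)


def _component_boundary_selector(c: Component) -> np.ndarray:
    """Boolean selector of the component's boundary pixels within its coords."""
    y0, x0 = c.coords.min(axis=0)
    y1, x1 = c.coords.max(axis=0)
    local = np.zeros((y1 - y0 + 3, x1 - x0 + 3), dtype=bool)
    local[c.coords[:, 0] - y0 + 1, c.coords[:, 1] - x0 + 1] = True
    boundary = _mask_boundary(local)
    return boundary[c.coords[:, 0] - y0 + 1, c.coords[:, 1] - x0 + 1]


def mif_intensity_biomarker(
    channel: np.ndarray,
    tissue_mask: np.ndarray,
    channel_label: str,
    threshold: float = PERILIPIN_INTENSITY_THRESHOLD,
) -> float:
    """Mean channel intensity over tissue, the study's area proxy.

    For perilipin 1, intensities at or below ``threshold`` (16-bit scale)
    are zeroed first, removing non-specific background staining.
    """
    tissue = np.asarray(tissue_mask, dtype=bool)
    if not tissue.any():
        raise ValidationError("tissue mask is empty")
    vals = np.asarray(channel, dtype=float)[tissue]
    if channel_label == "perilipin1":
        vals = np.where(vals > threshold, vals, 0.0)
    return float(vals.mean())


def zscore_across_patients(values) -> np.ndarray | pd.Series:
    """Standardize to mean 0, sample SD 1 across patients; NaN propagated."""
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if len(finite) < 2:
        raise ValidationError("z-scoring needs at least two non-missing values")
    sd = finite.std(ddof=1)
    if sd == 0:
        raise ValidationError("z-scoring is undefined for constant values")
    z = (arr - finite.mean()) / sd
    if isinstance(values, pd.Series):
        return pd.Series(z, index=values.index, name=values.name)
    return z


# ---------------------------------------------------------------------------
# Rule-based segmentation of synthetic slides
# ---------------------------------------------------------------------------

def rule_based_segmenter(slide: MultiChannelSlide) -> ROIMaskSet:
    """Color/intensity-rule segmentation of synthetic slides.

    A scripted stand-in that recovers tissue, islet, adipocyte and
    connective masks from the generator's palette, so the pipeline can be
    exercised without ground-truth masks.  It presumes the synthetic
    palette and is documented as unsupported for real histology.  Islets
    are recoverable only where an islet-restricted staining provides
    signal; otherwise the islet mask stays empty.  For mIF slides the
    connective mask is always empty (no dedicated staining).
    """
    if slide.is_mif:
        px = slide.pixels.astype(np.float32)
        channels = dict(zip(slide.channels, np.moveaxis(px, -1, 0)))
        tissue = channels["DAPI"] > 1500
        islet = np.zeros_like(tissue)
        for name in ISLET_STAININGS:
            if name in channels:
                islet |= channels[name] > 6000
        adipocyte = (
            channels["perilipin1"] > PERILIPIN_INTENSITY_THRESHOLD
            if "perilipin1" in channels
            else np.zeros_like(tissue)
        )
        connective = np.zeros_like(tissue)
        tissue |= islet | adipocyte
    else:
        px = slide.pixels.astype(np.int16)
        r, g, b = px[:, :, 0], px[:, :, 1], px[:, :, 2]
        v = px.mean(axis=2)
        sat = px.max(axis=2) - px.min(axis=2)
        background = (v >= 247) & (sat <= 12)
        tissue = ~background
        dab = (r - b >= 30) & (v <= 190)
        islet = (
            dab if slide.staining in ISLET_STAININGS else np.zeros_like(tissue)
        )
        adipocyte = tissue & (v >= 226) & (sat <= 26) & ~dab
        connective = tissue & (b - r >= 8) & (v >= 150) & (v <= 235) & ~dab & ~adipocyte
    islet &= tissue
    adipocyte &= tissue & ~islet
    connective &= tissue & ~islet & ~adipocyte
    return ROIMaskSet(tissue=tissue, islet=islet, adipocyte=adipocyte, connective=connective)


# ---------------------------------------------------------------------------
# Per-slide biomarker records
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerRecord:
    """Tissue-standardized histologic biomarkers for one (patient, staining).

    Areas and counts are divided by the tissue pixel area; raw values are
    retained alongside.  ``islet_adipocyte_distance`` is in microns and may
    be missing (NaN).
    """

    patient_id: str
    staining: str
    islet_mean_area: float          # mean islet area / tissue area
    islet_count: float              # islets per tissue px
    adipocyte_cluster_area: float   # summed cluster area / tissue area
    adipocyte_cluster_count: float  # clusters per tissue px
    connective_area: float          # relative area
    islet_adipocyte_distance: float  # um, NaN if missing
    islet_count_raw: int
    adipocyte_cluster_count_raw: int
    tissue_area_px: int
    mif_intensity: dict | None = None  # channel label -> standardized mean


def compute_biomarkers(
    masks: ROIMaskSet,
    patient_id: str = "",
    staining: str = "",
    microns_per_pixel: float = 1.0,
    slide: MultiChannelSlide | None = None,
    min_islet_area: int = ISLET_MIN_AREA_PX,
) -> BiomarkerRecord:
    """Compute the full biomarker record from masks (and mIF intensities)."""
    tissue_area = int(np.asarray(masks.tissue, dtype=bool).sum())
    if tissue_area == 0:
        raise ValidationError("tissue mask is empty")
    islets = islet_components(masks.islet, min_islet_area)
    clusters = adipocyte_clusters(masks.adipocyte)
    mean_islet_area = float(np.mean([c.area for c in islets])) if islets else 0.0
    dist = islet_adipocyte_distance(islets, masks.adipocyte, microns_per_pixel)
    mif_intensity = None
    if slide is not None and slide.is_mif:
        mif_intensity = {
            name: mif_intensity_biomarker(slide.pixels[:, :, c], masks.tissue, name)
            for c, name in enumerate(slide.channels)
        }
    return BiomarkerRecord(
        patient_id=patient_id,
        staining=staining,
        islet_mean_area=mean_islet_area / tissue_area,
        islet_count=len(islets) / tissue_area,
        adipocyte_cluster_area=float(sum(c.area for c in clusters)) / tissue_area,
        adipocyte_cluster_count=len(clusters) / tissue_area,
        connective_area=relative_area(masks.connective, masks.tissue),
        islet_adipocyte_distance=dist,
        islet_count_raw=len(islets),
        adipocyte_cluster_count_raw=len(clusters),
        tissue_area_px=tissue_area,
        mif_intensity=mif_intensity,
    )


def biomarker_table(records: Sequence[BiomarkerRecord]) -> pd.DataFrame:
    """Tidy biomarker table keyed by (patient_id, staining)."""
    rows = []
    for rec in records:
        row = asdict(rec)
        mif = row.pop("mif_intensity")
        if mif:
            for k, v in mif.items():
                row[f"intensity_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
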