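"""Tissue detection, patch tiling, and mIF channel representations.

A slide is divided into a regular, row-major grid of fixed-size square
patches (0-based, half-open pixel boxes); trailing partial rows and columns
are dropped so every patch matches the encoder input size.  At the default
0.45 um/px a 256-px patch covers 115.2 um of tissue.

Tissue/background separation is a scripted rule, not a learned model: an
IHC pixel is foreground when its RGB saturation (max - min) exceeds a noise
band, an mIF pixel when any channel rises above the detector floor.  A
patch is a tissue patch when at least ``threshold`` of its pixels are
foreground.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from isletscope.synthetic import MultiChannelSlide, ValidationError


class RepresentationMode(str, enum.Enum):
    IHC_RGB = "ihc_rgb"
    MIF_RGB = "mif_rgb"
    MIF_CHANNELWISE = "mif_channelwise"
    MIF_CHANNELWISE_AVERAGE = "mif_channelwise_average"


@dataclass
class PatchGrid:
    """Row-major grid of half-open pixel boxes with per-patch tissue flags."""

    patch_size: int
    image_shape: tuple[int, int]
    boxes: np.ndarray  # (n, 4) int: y0, x0, y1, x1
    tissue: np.ndarray  # (n,) bool
    microns_per_pixel: float

    @property
    def n_patches(self) -> int:
        return len(self.boxes)

    @property
    def n_rows(self) -> int:
        return self.image_shape[0] // self.patch_size

    @property
    def n_cols(self) -> int:
        return self.image_shape[1] // self.patch_size

    @property
    def physical_extent_um(self) -> float:
        """Physical side length of one patch in microns."""
        return self.patch_size * self.microns_per_pixel

    def tissue_indices(self) -> np.ndarray:
        return np.flatnonzero(self.tissue)

    def to_frame(self):
        """Serializable table: patch index, pixel box, tissue flag."""
        import pandas as pd

        return pd.DataFrame(
            {
                "patch": np.arange(self.n_patches),
                "y0": self.boxes[:, 0],
                "x0": self.boxes[:, 1],
                "y1": self.boxes[:, 2],
                "x1": self.boxes[:, 3],
                "tissue": self.tissue,
            }
        )

    def extract(self, pixels: np.ndarray, index: int) -> np.ndarray:
        y0, x0, y1, x1 = self.boxes[index]
        return pixels[y0:y1, x0:x1]


def tile(slide: MultiChannelSlide, patch_size: int = 256) -> PatchGrid:
    """Tile a slide into a row-major grid; partial edge patches are dropped."""
    if patch_size < 32:
        raise ValidationError("patch_size must be >= 32")
    h, w = slide.shape
    if patch_size > h or patch_size > w:
        raise ValidationError("patch_size exceeds image size")
    rows, cols = h // patch_size, w // patch_size
    ys, xs = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    y0 = (ys * patch_size).ravel()
    x0 = (xs * patch_size).ravel()
    boxes = np.stack([y0, x0, y0 + patch_size, x0 + patch_size], axis=1)
    grid = PatchGrid(
        patch_size=patch_size,
        image_shape=(h, w),
        boxes=boxes,
        tissue=np.ones(len(boxes), dtype=bool),
        microns_per_pixel=slide.microns_per_pixel,
    )
    return grid


def foreground_mask(
    slide: MultiChannelSlide,
    ihc_saturation: float = 14.0,
    mif_noise_floor: float = 600.0,
) -> np.ndarray:
    """Per-pixel foreground (stained tissue) mask."""
    px = slide.pixels
    if slide.is_mif:
        return (px.astype(np.float32) > mif_noise_floor).any(axis=2)
    r, g, b = px[:, :, 0], px[:, :, 1], px[:, :, 2]
    hi = np.maximum(np.maximum(r, g), b)
    lo = np.minimum(np.minimum(r, g), b)
    sat = hi - lo  # uint8-safe since hi >= lo
    return (sat > ihc_saturation) | (hi < 240)


def detect_tissue(
    slide: MultiChannelSlide,
    grid: PatchGrid | None = None,
    threshold: float = 0.05,
    patch_size: int = 256,
    **fg_kwargs,
) -> PatchGrid:
    """Flag tissue patches: foreground-pixel fraction >= ``threshold``.

    With ``threshold=0`` any patch containing at least one foreground pixel
    is flagged.  Returns the grid with its ``tissue`` flags set.
    """
    if grid is None:
        grid = tile(slide, patch_size)
    fg = foreground_mask(slide, **fg_kwargs)
    if not fg.any():
        warnings.warn("slide contains no foreground; all patches are background")
    fracs = patch_fractions(fg, grid)
    if threshold <= 0:
        grid.tissue = fracs > 0
    else:
        grid.tissue = fracs >= threshold
    return grid


def patch_fractions(mask: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Fraction of True pixels of ``mask`` inside each patch box (vectorized)."""
    p = grid.patch_size
    rows, cols = grid.n_rows, grid.n_cols
    cropped = mask[: rows * p, : cols * p]
    sums = cropped.reshape(rows, p, cols, p).sum(axis=(1, 3))
    return (sums / (p * p)).ravel()


def compose_mif_rgb(patch: np.ndarray, dapi_weight: float = 0.5) -> np.ndarray:
    """Compose a 4-channel mIF patch into unit-range RGB.

    The three stainings become the R, G, B channels (scaled from the 16-bit
    range to [0, 1]) and the DAPI channel is overlaid on each as a grayscale
    image with weight ``dapi_weight``, then clipped to [0, 1].
    """
    if patch.ndim != 3 or patch.shape[2] != 4:
        raise ValidationError("compose_mif_rgb expects an (H, W, 4) patch")
    x = patch.astype(np.float32) / 65535.0
    rgb = x[:, :, :3] + dapi_weight * x[:, :, 3:4]
    return np.clip(rgb, 0.0, 1.0)


def split_channels(patch: np.ndarray) -> list[np.ndarray]:
    """Split a 4-channel patch into its four grayscale planes, order preserved."""
    if patch.ndim != 3 or patch.shape[2] != 4:
        raise ValidationError("split_channels expects an (H, W, 4) patch")
    return [patch[:, :, c] for c in range(4)]
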