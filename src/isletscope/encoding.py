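"""Patch encoders and per-slide embedding bags.

The MIL classifier consumes a *bag* of fixed-length feature vectors, one per
tissue patch.  The package ships a deterministic handcrafted encoder (the
"desk" encoder): per-channel intensity histograms, gradient-magnitude
statistics and simple texture proxies, projected to the target dimension by
a fixed seeded random projection.  It needs no training or downloads, and
its features respond to exactly the morphology the synthetic generator
plants (stain-positive area, texture, brightness).

Representation modes for 4-channel mIF slides follow the study design:

* ``mif_rgb``       — compose stains + DAPI into RGB, one vector per patch (d)
* ``mif_channelwise`` — encode each channel separately and append (4d)
* ``mif_channelwise_average`` — encode each channel separately and average (d)
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from isletscope.synthetic import MultiChannelSlide, ValidationError
from isletscope.tiling import PatchGrid, RepresentationMode, compose_mif_rgb

_N_HIST_BINS = 8
_FEATS_PER_CHANNEL = _N_HIST_BINS + 6  # hist + mean/std/gradmean/gradstd/hi/lo


@dataclass
class EmbeddingBag:
    """Per-patch feature vectors with aligned coordinates and provenance."""

    vectors: np.ndarray       # (n_patches, d)
    boxes: np.ndarray         # (n_patches, 4) pixel boxes
    patch_indices: np.ndarray  # indices into the source grid
    mode: str
    encoder_id: str
    microns_per_pixel: float

    def __post_init__(self) -> None:
        if len(self.vectors) != len(self.boxes):
            raise ValidationError("one vector per patch is required")
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("bag vectors must be finite")

    @property
    def n_patches(self) -> int:
        return len(self.vectors)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


class PatchEncoder:
    """Interface: maps a patch pixel array to a fixed-length vector."""

    dim: int
    deterministic: bool = True
    name: str = "encoder"

    def encode(self, patch: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def encode_many(self, patches: np.ndarray) -> np.ndarray:
        """Encode a stack of patches (n, H, W[, C]); default loops."""
        return np.stack([self.encode(p) for p in patches])


def _scale_to_unit(patch: np.ndarray) -> np.ndarray:
    if patch.dtype == np.uint8:
        return patch.astype(np.float32) / 255.0
    if patch.dtype == np.uint16:
        return patch.astype(np.float32) / 65535.0
    return np.clip(patch.astype(np.float32), 0.0, 1.0)


class DeskEncoder(PatchEncoder):
    """Deterministic handcrafted patch encoder with seeded random projection.

    Features per channel: an 8-bin intensity histogram, mean, standard
    deviation, gradient-magnitude mean and standard deviation, and the
    fractions of pixels above 0.7 and below 0.2 intensity.  The feature
    block is projected to dimension ``d`` with a fixed Gaussian matrix drawn
    once from ``seed`` (per input channel count), so the encoder is fully
    deterministic and encoders built with different seeds differ only in
    their projections.
    """

    def __init__(self, seed: int = 0, d: int = 128, pool_to: int = 64):
        if d < 16:
            raise ValidationError("encoder dimension must be >= 16")
        self.seed = int(seed)
        self.dim = int(d)
        self.pool_to = int(pool_to)
        self.name = f"desk-{seed}-{d}"
        self._projections: dict[int, np.ndarray] = {}

    def _projection(self, n_features: int) -> np.ndarray:
        if n_features not in self._projections:
            rng = np.random.default_rng([self.seed, n_features])
            self._projections[n_features] = rng.normal(
                0.0, 1.0 / np.sqrt(n_features), size=(n_features, self.dim)
            ).astype(np.float32)
        return self._projections[n_features]

    def _downsample(self, x: np.ndarray) -> np.ndarray:
        """Mean-pool to at most ``pool_to`` per side; the intensity statistics
        the features capture are robust to this, and it keeps encoding cheap."""
        h, w = x.shape[:2]
        fy, fx = h // self.pool_to, w // self.pool_to
        if fy > 1 and h % fy == 0 and fx > 1 and w % fx == 0:
            x = x.reshape(h // fy, fy, w // fx, fx, -1).mean(axis=(1, 3))
        return x

    def features(self, patch: np.ndarray) -> np.ndarray:
        """Raw handcrafted features before projection (concatenated channels)."""
        x = _scale_to_unit(patch)
        if x.ndim == 2:
            x = x[:, :, None]
        x = self._downsample(x)
        feats = []
        for c in range(x.shape[2]):
            plane = x[:, :, c]
            bins = np.minimum((plane * _N_HIST_BINS).astype(np.intp), _N_HIST_BINS - 1)
            hist = np.bincount(bins.ravel(), minlength=_N_HIST_BINS).astype(np.float32)
            hist /= plane.size
            grad = np.abs(np.diff(plane, axis=0)).mean() + np.abs(np.diff(plane, axis=1)).mean()
            grad_sd = np.abs(np.diff(plane, axis=0)).std() + np.abs(np.diff(plane, axis=1)).std()
            feats.append(
                np.concatenate(
                    [
                        hist,
                        [
                            plane.mean(),
                            plane.std(),
                            grad,
                            grad_sd,
                            float((plane > 0.7).mean()),
                            float((plane < 0.2).mean()),
                        ],
                    ]
                )
            )
        return np.concatenate(feats).astype(np.float32)

    def encode(self, patch: np.ndarray) -> np.ndarray:
        f = self.features(patch)
        return f @ self._projection(len(f))

    def encode_many(self, patches: np.ndarray) -> np.ndarray:
        feats = np.stack([self.features(p) for p in patches])
        return feats @ self._projection(feats.shape[1])


def encode_bag(
    grid: PatchGrid,
    slide: MultiChannelSlide,
    mode: RepresentationMode | str,
    encoder: PatchEncoder,
    dapi_weight: float = 0.5,
) -> EmbeddingBag:
    """Encode every tissue patch of a slide under a representation mode.

    Channel-wise modes encode each of the 4 channels separately; the
    appended variant concatenates the 4 vectors (dimension 4d), the
    averaged variant takes their elementwise mean (dimension d).
    """
    mode = RepresentationMode(mode)
    if mode is RepresentationMode.IHC_RGB:
        if slide.is_mif:
            raise ValidationError("ihc_rgb mode requires an IHC slide")
    elif not slide.is_mif or slide.pixels.shape[2] != 4:
        raise ValidationError(f"{mode.value} mode requires a 4-channel mIF slide")

    idx = grid.tissue_indices()
    vectors = []
    for i in idx:
        patch = grid.extract(slide.pixels, int(i))
        if mode is RepresentationMode.IHC_RGB:
            vectors.append(encoder.encode(patch))
        elif mode is RepresentationMode.MIF_RGB:
            vectors.append(encoder.encode(compose_mif_rgb(patch, dapi_weight)))
        else:
            per_channel = [encoder.encode(patch[:, :, c]) for c in range(4)]
            if mode is RepresentationMode.MIF_CHANNELWISE:
                vectors.append(np.concatenate(per_channel))
            else:
                vectors.append(np.mean(per_channel, axis=0))
    d = encoder.dim * (4 if mode is RepresentationMode.MIF_CHANNELWISE else 1)
    vecs = np.asarray(vectors, dtype=np.float32).reshape(len(idx), d)
    return EmbeddingBag(
        vectors=vecs,
        boxes=grid.boxes[idx],
        patch_indices=idx,
        mode=mode.value,
        encoder_id=encoder.name,
        microns_per_pixel=grid.microns_per_pixel,
    )


def save_bag(bag: EmbeddingBag, path: str | Path) -> None:
    """Save a bag as an .npz container with a JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        vectors=bag.vectors,
        boxes=bag.boxes,
        patch_indices=bag.patch_indices,
    )
    meta = {
        "mode": bag.mode,
        "encoder_id": bag.encoder_id,
        "dim": bag.dim,
        "n_patches": bag.n_patches,
        "microns_per_pixel": bag.microns_per_pixel,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_bag(path: str | Path) -> EmbeddingBag:
    """Load a bag; raises if the sidecar metadata disagrees with the arrays."""
    path = Path(path)
    try:
        with np.load(path.with_suffix(".npz")) as data:
            vectors = data["vectors"]
            boxes = data["boxes"]
            patch_indices = data["patch_indices"]
    except Exception as exc:
        raise ValidationError(f"cannot read bag container {path.with_suffix('.npz')}: {exc}")
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["dim"] != vectors.shape[1] or meta["n_patches"] != len(vectors):
        raise ValidationError(f"bag metadata mismatch for {path}")
    return EmbeddingBag(
        vectors=vectors,
        boxes=boxes,
        patch_indices=patch_indices,
        mode=meta["mode"],
        encoder_id=meta["encoder_id"],
        microns_per_pixel=meta["microns_per_pixel"],
    )
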