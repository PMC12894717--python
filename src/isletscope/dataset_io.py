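"""Writing and reading synthetic datasets on disk.

Slides are written losslessly: 8-bit RGB PNG for IHC, multi-channel 16-bit
TIFF for mIF.  Masks are single-channel 0/255 PNGs, the cohort table a CSV
with the canonical column names, and a JSON manifest records every file
with its SHA-256 checksum so a dataset can be verified after the fact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from isletscope.synthetic import MIF_SETS, MultiChannelSlide, ROIMaskSet

MASK_CLASSES = ("tissue", "islet", "adipocyte", "connective")
MANIFEST_NAME = "manifest.json"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_slide(slide: MultiChannelSlide, path: Path) -> Path:
    """Write one slide losslessly; returns the actual path written."""
    path = Path(path)
    if slide.is_mif:
        path = path.with_suffix(".tiff")
        # channel-first layout, one page per channel
        tifffile.imwrite(
            path, np.moveaxis(slide.pixels, -1, 0), photometric="minisblack"
        )
    else:
        path = path.with_suffix(".png")
        Image.fromarray(slide.pixels).save(path)
    return path


def read_slide(path: Path, staining: str, microns_per_pixel: float) -> MultiChannelSlide:
    path = Path(path)
    if path.suffix in (".tiff", ".tif"):
        pixels = np.moveaxis(tifffile.imread(path), 0, -1)
        return MultiChannelSlide(
            pixels=pixels,
            channels=MIF_SETS[staining],
            modality="mif",
            staining=staining,
            microns_per_pixel=microns_per_pixel,
        )
    pixels = np.asarray(Image.open(path))
    return MultiChannelSlide(
        pixels=pixels,
        channels=("R", "G", "B"),
        modality="ihc",
        staining=staining,
        microns_per_pixel=microns_per_pixel,
    )


def write_dataset(
    cohort: pd.DataFrame,
    slides: Iterable[tuple[str, str, MultiChannelSlide, ROIMaskSet]],
    out_dir: str | Path,
) -> dict:
    """Write a cohort, its slides and masks, and a checksummed manifest.

    ``slides`` yields ``(patient_id, staining, slide, masks)`` tuples.
    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []

    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    entries.append({"path": "cohort.csv", "kind": "cohort", "sha256": _sha256(cohort_path)})

    for pid, staining, slide, masks in slides:
        stem = f"{pid}_{staining}"
        spath = write_slide(slide, out / stem)
        entries.append(
            {
                "path": spath.name,
                "kind": "slide",
                "patient_id": pid,
                "staining": staining,
                "modality": slide.modality,
                "microns_per_pixel": slide.microns_per_pixel,
                "sha256": _sha256(spath),
            }
        )
        for cls in MASK_CLASSES:
            mpath = out / f"{stem}_mask_{cls}.png"
            arr = (getattr(masks, cls).astype(np.uint8)) * 255
            Image.fromarray(arr).save(mpath)
            entries.append(
                {
                    "path": mpath.name,
                    "kind": "mask",
                    "patient_id": pid,
                    "staining": staining,
                    "roi_class": cls,
                    "sha256": _sha256(mpath),
                }
            )

    manifest = {"n_files": len(entries), "files": entries}
    with open(out / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def verify_manifest(out_dir: str | Path) -> list[str]:
    """Re-checksum every manifest entry; returns a list of mismatched paths."""
    out = Path(out_dir)
    with open(out / MANIFEST_NAME) as fh:
        manifest = json.load(fh)
    bad = []
    for entry in manifest["files"]:
        p = out / entry["path"]
        if not p.exists() or _sha256(p) != entry["sha256"]:
            bad.append(entry["path"])
    return bad


def read_mask(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path)) > 127
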