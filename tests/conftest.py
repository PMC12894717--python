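import numpy as np
import pandas as pd
import pytest

import isletscope as isc


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return isc.generate_cohort(12, 5, 2, {"A": 7, "B": 5}, seed=11)


@pytest.fixture(scope="session")
def ihc_slide(small_cohort):
    """One small rendered IHC section with ground-truth masks."""
    slide, masks = isc.generate_slide(
        small_cohort.iloc[0], "insulin", shape=(1024, 1024), seed=11
    )
    return slide, masks


@pytest.fixture(scope="session")
def mif_slide(small_cohort):
    slide, masks = isc.generate_slide(
        small_cohort.iloc[1], "set2", shape=(1024, 1024), seed=11
    )
    return slide, masks


@pytest.fixture(scope="session")
def encoder():
    return isc.DeskEncoder(seed=5, d=32)


def make_gaussian_bags(n_bags, n_patches, dim, separation, seed):
    """Synthetic labelled bags: class-1 bags shift a subset of patch means."""
    rng = np.random.default_rng(seed)
    bags, labels = {}, {}
    for i in range(n_bags):
        y = i % 2
        vecs = rng.normal(0, 1, (n_patches, dim))
        if y:
            k = max(1, n_patches // 4)
            vecs[:k, : dim // 2] += separation
        boxes = np.array([[0, 256 * j, 256, 256 * (j + 1)] for j in range(n_patches)])
        bags[f"B{i:03d}"] = isc.EmbeddingBag(
            vectors=vecs.astype(np.float32),
            boxes=boxes,
            patch_indices=np.arange(n_patches),
            mode="ihc_rgb",
            encoder_id="test",
            microns_per_pixel=0.45,
        )
        labels[f"B{i:03d}"] = y
    return bags, labels
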