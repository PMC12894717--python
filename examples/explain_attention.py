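"""Explain a trained MIL model: attention heatmaps and pixel attributions.

Trains a small model on synthetic bags, derives class-specific patch
relevance (gradient-filtered attention), paints a slide-level heatmap, and
demonstrates the pixel-level attribution methods (saliency, integrated /
expected gradients, DeepLIFT with SmoothGrad) on a differentiable scorer.
"""

import numpy as np

import isletscope as isc
import isletscope.xai as xai
from isletscope.mil import Fold, TrainConfig
from isletscope.nnet import pooled_pixel_scorer

SEED = 5
cohort = isc.generate_cohort(16, 8, 0, {"A": 8, "B": 8}, seed=SEED)
encoder = isc.DeskEncoder(seed=SEED, d=64)
bags, labels, grids = {}, {}, {}
for _, row in cohort.iterrows():
    slide, _ = isc.generate_slide(row, "insulin", seed=SEED)
    grid = isc.detect_tissue(slide)
    bags[row["patient_id"]] = isc.encode_bag(grid, slide, "ihc_rgb", encoder)
    labels[row["patient_id"]] = int(row["diabetic_status"])
    grids[row["patient_id"]] = grid

model = isc.train_fold(
    bags, labels, Fold(train=list(bags), validation=[]),
    TrainConfig(subsample_fraction=0.5, epochs=40, seed=SEED),
)

pid = cohort.iloc[0]["patient_id"]
probs, attention = isc.predict(model, bags[pid])
relevance = xai.attention_lrp_mil(model, bags[pid], target=1)
heatmap = xai.assemble_heatmap(relevance, grids[pid])
print(f"{pid}: P(T2D) = {probs[1]:.3f}")
print(f"attention mass on top-3 patches: {np.sort(attention)[-3:].round(3)}")
print(f"relevance heatmap: shape {heatmap.shape}, nonzero in "
      f"{int((heatmap > 0).sum() / 256**2)} patches")

# pixel-level attributions on a differentiable patch scorer
scorer = pooled_pixel_scorer((64, 64), pool=8, seed=SEED)
patch = np.random.default_rng(SEED).random((64, 64))
ig = xai.integrated_gradients(scorer, patch, steps=64, target=1)
delta = scorer.predict(patch)[1] - scorer.predict(np.zeros((64, 64)))[1]
print(f"IG completeness: sum {ig.sum():.5f} vs f(x)-f(0) {delta:.5f}")
sg = xai.smoothgrad(lambda z: xai.saliency(scorer, z, 1), patch,
                    sigma=1.0, n=10, kernel_sigma=1.0, seed=SEED)
print(f"SmoothGrad saliency: min {sg.min():.4f} (non-negative), max {sg.max():.4f}")
# The IG sum matching f(x) - f(baseline) is the completeness identity; the
# SmoothGrad map is non-negative by construction (positive attributions only).
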