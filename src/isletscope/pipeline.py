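"""End-to-end orchestration of the synthetic desk-scale study.

One call runs the whole analysis for one random seed: generate the cohort
and slides, tile and encode, train the cross-validated attention-MIL
ensemble, evaluate held-out AUROC, quantify attention to the planted ROIs,
extract the histologic biomarkers from the ground-truth masks and fit the
diabetes-status GMLM.  Used by the examples, the test suite and the
acceptance script so that all of them exercise exactly the same pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from isletscope.biomarkers import biomarker_table, compute_biomarkers, roi_attention
from isletscope.encoding import DeskEncoder, EmbeddingBag, encode_bag
from isletscope.mil import (
    GatedAttentionMIL,
    SplitPlan,
    TrainConfig,
    auroc,
    ensemble_predict,
    make_splits,
    predict,
    train_ensemble,
)
from isletscope.stats import GMLMFit, ModelSpec, assemble_design, fit_gmlm
from isletscope.synthetic import (
    DEFAULT_SLIDE_SHAPE,
    EffectConfig,
    generate_cohort,
    generate_slide,
)
from isletscope.tiling import detect_tissue, patch_fractions


@dataclass
class StudyResult:
    """Everything the synthetic study computes for one seed."""

    cohort: pd.DataFrame
    plan: SplitPlan
    models: list[GatedAttentionMIL]
    ensemble_auroc: float
    fold_aurocs: list[float]
    biomarkers: pd.DataFrame
    gmlm: GMLMFit | None
    roi_attention_islet: float
    roi_attention_adipocyte: float
    roi_attention_planted: float  # islet ∪ adipocyte (the planted ROIs)
    test_scores: pd.DataFrame
    bags: dict[str, EmbeddingBag] = field(repr=False, default_factory=dict)


def run_synthetic_study(
    seed: int,
    n_patients: int = 100,
    n_t2d: int = 35,
    n_missing_homa2b: int = 9,
    cohorts: dict[str, int] | None = None,
    staining: str = "insulin",
    effects: EffectConfig | None = None,
    shape: tuple[int, int] = DEFAULT_SLIDE_SHAPE,
    d: int = 128,
    n_test: int = 25,
    k_folds: int = 15,
    n_val: int = 15,
    train_cfg: TrainConfig | None = None,
    fit_status_model: bool = True,
) -> StudyResult:
    """Run the full pipeline for one seed and return all study quantities.

    The status GMLM is fitted on the single-staining biomarker table with a
    cohort random intercept (a one-level staining factor would be
    confounded with the fixed intercept).
    """
    effects = effects or EffectConfig()
    cohort = generate_cohort(n_patients, n_t2d, n_missing_homa2b, cohorts, seed)
    encoder = DeskEncoder(seed=seed, d=d)

    bags: dict[str, EmbeddingBag] = {}
    labels: dict[str, int] = {}
    sites: dict[str, str] = {}
    records = []
    roi_fracs: dict[str, dict[str, np.ndarray]] = {}
    grids = {}
    for _, row in cohort.iterrows():
        pid = str(row["patient_id"])
        slide, masks = generate_slide(row, staining, shape=shape, effects=effects, seed=seed)
        grid = detect_tissue(slide)
        bags[pid] = encode_bag(grid, slide, "ihc_rgb", encoder)
        labels[pid] = int(row["diabetic_status"])
        sites[pid] = str(row["cohort"])
        records.append(
            compute_biomarkers(masks, pid, staining, slide.microns_per_pixel)
        )
        roi_fracs[pid] = {
            "islet": patch_fractions(masks.islet, grid),
            "adipocyte": patch_fractions(masks.adipocyte, grid),
        }
        grids[pid] = grid

    # Desk-scale bags hold ~50 patches, so the gigapixel-scale default of a
    # 5% patch subsample would show the model only 2-3 patches per view;
    # half-bag views are the comparable regime here.
    cfg = train_cfg or TrainConfig(
        subsample_fraction=0.5, seed=seed, balanced_cohorts=("A",)
    )
    plan = make_splits(cohort, n_test=n_test, k=k_folds, n_val=n_val, seed=seed)
    models = train_ensemble(bags, labels, plan, cfg, sites)

    test_rows = []
    for pid in plan.test:
        probs = ensemble_predict(models, bags[pid])
        test_rows.append({"patient_id": pid, "label": labels[pid], "score": probs[1]})
    test_scores = pd.DataFrame(test_rows)
    ens_auroc = auroc(test_scores["label"].to_numpy(), test_scores["score"].to_numpy())
    fold_aurocs = []
    for model in models:
        scores = [predict(model, bags[p])[0][1] for p in plan.test]
        fold_aurocs.append(auroc(test_scores["label"].to_numpy(), np.array(scores)))

    # attention concentration on the planted ROIs, averaged over test patients
    ratios = {"islet": [], "adipocyte": [], "planted": []}
    for pid in plan.test:
        attn = np.mean([predict(m, bags[pid])[1] for m in models], axis=0)
        fr = roi_fracs[pid]
        # islet and adipocyte masks are disjoint, so fractions add
        for cls, fracs in (
            ("islet", fr["islet"]),
            ("adipocyte", fr["adipocyte"]),
            ("planted", fr["islet"] + fr["adipocyte"]),
        ):
            r = roi_attention(attn, None, grids[pid], roi_fractions=fracs)
            if np.isfinite(r):
                ratios[cls].append(r)

    bio = biomarker_table(records)
    fit = None
    if fit_status_model:
        # Stacked six-staining design as in the study (one row per patient x
        # staining).  The rendered staining contributes its mask-measured
        # biomarkers; the five other serial sections come from the seeded
        # section-plan simulator, which draws from the same streams the
        # renderer would use (mask measurement equals the planted section
        # values up to rasterization, so rendering them too would be
        # redundant at this scale).
        from isletscope.synthetic import IHC_STAININGS, simulate_biomarker_table

        mean_tissue = float(bio["tissue_area_px"].mean())
        others = tuple(s for s in IHC_STAININGS if s != staining)
        sim = simulate_biomarker_table(
            cohort, effects, seed, stainings=others, tissue_area_px=mean_tissue
        )
        cols = ["patient_id", "staining"] + list(sim.columns.drop(["patient_id", "staining"]))
        stacked = pd.concat([bio[cols], sim[cols]], ignore_index=True)
        design = assemble_design(cohort, stacked, ModelSpec.diabetes_status())
        fit = fit_gmlm(design)

    return StudyResult(
        cohort=cohort,
        plan=plan,
        models=models,
        ensemble_auroc=float(ens_auroc),
        fold_aurocs=[float(a) for a in fold_aurocs],
        biomarkers=bio,
        gmlm=fit,
        roi_attention_islet=float(np.mean(ratios["islet"])) if ratios["islet"] else float("nan"),
        roi_attention_adipocyte=(
            float(np.mean(ratios["adipocyte"])) if ratios["adipocyte"] else float("nan")
        ),
        roi_attention_planted=(
            float(np.mean(ratios["planted"])) if ratios["planted"] else float("nan")
        ),
        test_scores=test_scores,
        bags=bags,
    )
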