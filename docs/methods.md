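# Methods

`isletscope` re-creates, at desk scale and on fully synthetic data, an
explainable-AI analysis of pancreas histology in type 2 diabetes (T2D):
whole-slide images are classified by an attention-based multiple-instance
learner, the attention and gradient structure of the trained models is
turned into spatial explanations, the highlighted regions are quantified as
histologic biomarkers, and the biomarkers are related to clinical outcomes
with generalized mixed linear models. This note records the models, the
parameters that matter, and the design decisions taken where the design was
genuinely open.

## Synthetic study generator

The generator is the package's ground truth and defines the study
conditions; everything downstream is validated against it.

**Cohort.** 100 patients across two sites (59/41), 35 with T2D, with sex,
age, BMI, malignant tumor, chronic pancreatitis, insulin therapy (T2D
only), diabetes duration (positive only in T2D) and HOMA2B (β-cell function
index, missing for exactly 9 patients, chosen at random independent of
status). Continuous covariates are Gaussian with status-shifted means and
*equal* spreads, and binary covariates differ via their rates; this makes
the null logistic model of status given the covariates correctly specified,
which the calibration suite relies on. The second site is generated
approximately balanced in T2D status while the first carries the remaining
imbalance, mirroring a two-site design in which only one site needs
balanced sampling during training.

**Morphology.** Each patient carries latent morphology *intensities*
(expected islet count and mean area, adipocyte-cluster count and mean area,
connective-tissue fraction, mean islet–adipocyte boundary distance), drawn
lognormally (σ = 0.28) around base values chosen for a 2048×2048 slide at
0.45 µm/px: 9 islets of ≈13 000 px² (≈2 600 µm²), 14 adipocyte clusters of
≈7 000 px², connective fraction 0.10, islet–adipocyte gap 190 px (≈86 µm).
Planted T2D effects multiply the latents (defaults: islet area ×0.6, islet
count ×0.7, adipocyte-cluster area ×1.5, cluster count ×0.8, connective
×1.4, distance ×0.6 — the directions of the morphological differences the
analysis is designed to detect).

The patient-heterogeneity scale σ = 0.28 was fixed during generator design
under two opposing constraints: much smaller values make the planted
factors correspond to ≳3 SD group separation, which completely separates
the logistic mixed model (divergent maximum-likelihood estimates, useless
z-tests); much larger values cap even an oracle classifier on the true
biomarkers below the AUROC regime the end-to-end suite probes. At 0.28 the
planted factors are ≈1.3–1.8 SD effects: the MLE stays finite and the
oracle ceiling is ≈0.97 AUROC.

**Serial sections.** Every staining of a patient is its own serial section:
it draws structure counts (Poisson around the patient rates, with at least
one islet), per-islet areas (lognormal, floored at 6 200 px² so the
downstream 5 000 px artifact filter never censors planted structures),
per-cluster areas and per-cluster "satellite" gaps from seeded streams
shared between the renderer and the fast biomarker simulator
(`simulate_biomarker_table`). A simulated biomarker row for a
(patient, staining) pair therefore equals the value measured on the
rendered section up to rasterization. Clusters outnumber islets by
construction and every islet is assigned at least one satellite cluster at
a planted boundary gap; this makes the measured minimum islet–adipocyte
distance track the planted distance factor rather than the cluster count
(which otherwise confounds it).

**Rendering.** Islets are unions of three oriented ellipses whose radius is
rescaled once so the rasterized area matches the planned area (all blob
dimensions scale with the radius, so the rescale is exact up to pixel
quantization — measured areas agree with the plan to ≈0.5%). Satellite
clusters are packed circles anchored at their islet's boundary with the
planted gap (one curvature-correction step); foreign clusters must respect
every other islet's planned minimum gap (relaxed gradually, finally to
zero, when a section is too crowded — losing a cluster would distort the
count and area biomarkers asymmetrically between groups, which is worse
than an occasional small distance bias). Connective tissue is an
anisotropically smoothed noise field thresholded to the planned fraction of
tissue; neuronal fibers and vessel strands are random-walk polylines used
only for rendering. IHC sections are 8-bit RGB palette renderings
(background white, acinar tissue pink, connective blue-violet, adipocytes
cream, stain-positive signal DAB brown) with shared-luminance noise so
pixel saturation stays noise-free; mIF sections are 4-channel 16-bit with a
DAPI channel marking tissue and the perilipin 1 channel exceeding 1000
counts only inside adipocytes. Photorealism is a non-goal; the geometry is
the minimum that exercises component counting, area, intensity and distance
logic.

**Ground truth.** The generator records per-structure rasterized areas (by
direct summation over local bounding boxes, independently of any labeling
algorithm) and per-islet minimum distances (KD-tree nearest-neighbour
between boundary pixel sets). The fidelity suite checks that the
morphometry module reproduces these records exactly.

## Tiling, representations, encoding

Slides are tiled into non-overlapping 256-px patches (115.2 µm at the
default resolution), row-major, partial edge patches dropped. A patch is
tissue when ≥5% of its pixels are foreground (RGB saturation above a noise
band for IHC; any channel above the detector floor for mIF) — a scripted
stand-in, since tissue selection is not otherwise specified. mIF patches
support three representations: RGB composition (stains as color channels
plus a 0.5-weighted DAPI overlay, clipped), channel-wise (each channel
encoded separately, vectors appended, 4× the dimension), and channel-wise
average (the four vectors averaged; identical dimension to RGB). The
channel ordering (stain1, stain2, stain3, DAPI) is fixed so appended
layouts are stable, and DAPI is encoded as a fourth channel in the
channel-wise modes.

The default encoder is deterministic and handcrafted: per-channel intensity
histograms (8 bins), mean/SD, gradient-magnitude statistics and
high/low-intensity fractions, computed on patches mean-pooled to ≤64 px per
side (the statistics are robust to pooling, and it keeps encoding cheap),
projected to the target dimension by a fixed seeded Gaussian matrix. It
needs no training or downloads and responds to exactly the morphology the
generator plants. A pretrained-ViT-style encoder can be substituted through
the same `PatchEncoder` interface.

## MIL classifier

Single-branch gated attention: patch i receives score
`a_i = w·(tanh(V h_i) ⊙ σ(U h_i))`, softmax-normalized over the bag; the
slide representation is the attention-weighted sum of patch features and a
linear head yields two class probabilities. Features are standardized with
training-fold statistics. Training is plain Adam under a cosine-annealed
learning rate with gradient accumulation (4 bags), per-epoch random patch
subsampling, and within-cohort minority oversampling for the unbalanced
site. An optional instance-level auxiliary loss on the top-/bottom-attended
patches exists with default weight 0. All gradients are hand-derived and
verified against finite differences.

`TrainConfig` defaults: subsample fraction 0.05 (the gigapixel-scale
convention), 60 epochs, base LR 0.05, hidden width 64, weight decay 1e-4.
The end-to-end study pipeline overrides the subsample fraction to 0.5: on a
desk-scale bag of ~50 patches a 5% subsample is 2–3 patches per view,
whereas 5% of a gigapixel slide is hundreds — half-bag views are the
comparable regime. Epoch count and learning rate were fixed from pilot runs
on the planted-effect generator.

Model development uses a 75/25 patient train/test split with 15 folds of 60
training / 15 validation patients inside the training set; the test split
is stratified by diabetes status so both classes are always present at
evaluation. Fold models are ensembled by averaging class probabilities.
AUROC uses the midrank Mann–Whitney convention (ties get half credit).

## Attribution methods

All methods operate on exact backpropagated gradients from the package's
own layer toolkit (`isletscope.nnet`) or the MIL model's backward pass.

* **Relevance propagation** through linear layers keeps only index pairs
  with non-negative contribution `x_j·W_ji ≥ 0`; each input receives the
  retained-contribution share of its downstream relevance, starting from a
  one-hot at the target class. Relevance stays non-negative and is
  conserved wherever every downstream unit retains a contribution.
* **Attention filtering**: per block, `Â = I + E_h(∇A ⊙ R)⁺` — identity
  plus the head-averaged positive part of the gradient×relevance product —
  and blocks are combined by matrix rollout (the ordered product), our
  documented reading of "weighted relevance across all blocks". For the
  MIL head, which has a single attention row rather than token-to-token
  matrices, the construction collapses to the attention weights gated by
  the positive part of the exact attention gradient for the target class.
* **Saliency** is the positive part of the input gradient; a
  central-difference fallback handles scorers without exact gradients.
* **Integrated gradients** integrate along the straight path from a black
  (zero) baseline with the trapezoid rule (default 32 steps); completeness
  holds to quadrature error, exactly for linear scorers.
* **Expected gradients** Monte-Carlo-average integrated gradients over a
  baseline distribution (seeded); with a point-mass baseline they converge
  to IG at the 1/√n rate.
* **DeepLIFT** uses the rescale rule with reference activations at the
  zero baseline and a 1e-9 near-zero-delta guard that falls back to the
  local derivative; summation-to-delta holds exactly for the supported
  layer family.
* **SmoothGrad** averages maps over n = 10 Gaussian perturbations
  (σ = 1.0), blurs with a Gaussian kernel (σ = 1.0, reflective borders) and
  keeps the positive part.

Patch-level scores are painted into their pixel boxes to form slide-level
heatmaps; values are preserved (no renormalization unless requested).

## Attention quantification and biomarkers

Attention to an ROI is a density ratio: mean attention of tissue patches
overlapping the ROI (≥5% pixel overlap) divided by mean attention over all
tissue patches. It is 1 for a uniform attention field, invariant to
rescaling the attention, 1 for a tissue-wide ROI under any attention (hence
identically 1 for stainings whose signal is confined to the islets), and
*missing* — never zero — when the ROI is absent. Channel-wise mIF attention
shares divide each channel's summed attention by the total over channels,
with an additional tissue-size standardization.

Biomarkers follow fixed rules: 8-connected components count islets
(area > 5000 px only, excluding segmentation artifacts) and adipocyte
clusters (no minimum; a single adipocyte is one cluster); areas and counts
are standardized by total tissue area; islet–adipocyte proximity is the
mean over islets of the boundary-to-boundary minimum Euclidean distance
(computed exactly via nearest-neighbour queries between boundary pixels,
which equals the minimum of the Euclidean distance transform over the
islet's pixels); mIF channel intensity is averaged over tissue, for
perilipin 1 after zeroing values ≤1000 on the 16-bit scale. The scripted
color/intensity segmenter recovers the synthetic palette's classes
(Dice ≈ 1 on clean renderings) and is documented as unsupported for real
histology; islets are only recoverable under islet-restricted stainings,
and mIF has no connective class.

## Association models

One biomarker row per (patient, staining) is joined to the clinical
covariates; continuous covariates are z-standardized on the analysis
sample (after missing-data removal), interactions are built after
standardization, and a Gaussian response is standardized too (a Gamma
response stays on its positive natural scale). The models: diabetes status
(binomial, logit), HOMA2B (Gaussian identity and Gamma, compared by AIC),
and diabetes duration (Gaussian, controlling for status) — each with
biomarkers, sex, age, BMI, malignant tumor and chronic pancreatitis as
fixed effects (plus insulin therapy and the adipocyte-area×BMI interaction
for HOMA2B), and random intercepts for staining and cohort. There is no
patient random effect: the response does not vary within a patient, so a
patient intercept would fit each patient perfectly.

Fitting is maximum likelihood with a Laplace approximation to the marginal
likelihood (exact for the Gaussian family), optimized by L-BFGS-B; the
inner latent mode is found by Newton iteration on standardized random
effects, which keeps the objective well-defined when a variance sits on its
zero bound (boundary estimates are reported as zero, not dropped). The
Gamma family uses a log link: the canonical inverse link does not keep the
mean positive over an unconstrained linear predictor, and the study's
reported results use the Gaussian family anyway (selected by AIC). Wald
z-tests (two-sided) use the observed information of the fixed effects at
the optimum with variance components held fixed, the convention of standard
mixed-model software; the test suite verifies coefficients, standard errors
and log-likelihoods against lme4 (`lmer`/`glmer`) to ≈1e-4. VIF screening
removes perfectly collinear effects deterministically (later-declared
first) and flags VIF > 10. Significance codes: * < 0.05, ** < 0.01,
*** < 0.001.

**Pseudo-replication caveat.** With six serial sections per patient the
stacked 600-row design repeats every patient-level covariate six times, and
the staining/cohort random intercepts do not absorb that dependence; the
z-tests of patient-level effects in the stacked design are therefore
anti-conservative (by up to √6 for a perfectly repeated covariate). The
calibration suite consequently validates the type-I error of the inference
machinery on a one-row-per-patient design, where the model is correctly
specified; the stacked design is used, as in the study layout, for the
power/sign-recovery analyses.

## End-to-end study and problem sizes

`isletscope.pipeline.run_synthetic_study` runs one seed of the full
analysis: 100 patients, one rendered insulin-stained 2048² section per
patient at 0.45 µm/px, desk encoder at d = 128, 15-fold gated-attention MIL
ensemble evaluated on the 25 held-out patients, attention ratios for the
planted ROIs on the test patients, mask-derived biomarkers, and the
binomial GMLM on the stacked six-staining design (the five non-rendered
serial sections come from the seeded section simulator, which draws from
the same streams the renderer would use; mask measurement equals the
planted section values up to rasterization, as the fidelity suite
verifies, so rendering them as pixels would add cost but no information).
These sizes are the package's desk-scale operating point; the acceptance
suite runs ten seeds of this pipeline.

## What the synthetic data does and does not show

The generator plants clean geometric structures with known labels, palette
colors without staining artifacts, and effects that act multiplicatively on
latent morphology. Passing tests therefore demonstrate that the pipeline's
machinery is correct (tiling, encoding, attention learning, attribution
identities, morphometry, mixed-model inference and their integration) and
that planted morphological signals of realistic size are recovered end to
end. They do not demonstrate performance on real histology: no
stain-variability, scanner noise, segmentation error, annotation ambiguity
or out-of-distribution morphology is modeled, and the handcrafted encoder
is not a learned histology representation.

## Known limitations

* The rule-based segmenter presumes the synthetic palette.
* Attention rollout is one documented reading of cross-block combination;
  the MIL adaptation collapses it to a single gated attention row.
* The Gamma family uses a log link (see above).
* Crowded sections relax foreign-islet distance protection rather than
  drop clusters, trading a small downward distance bias for unbiased
  counts.
* The stacked-design z-tests inherit the pseudo-replication
  anti-conservatism discussed above.
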