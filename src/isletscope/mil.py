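"""Gated-attention multiple-instance-learning classifier.

Each slide is a bag of patch embeddings with a single label (T2D / non-T2D).
A gated attention module scores every patch, the scores are softmax-
normalized, the bag representation is the attention-weighted sum of patch
features, and a linear head produces the two class probabilities.  Training
follows the study's adaptations: per-epoch random patch subsampling
(default 5% of a bag), Adam-style updates under a cosine-annealed learning
rate with gradient accumulation, and optional within-cohort minority
oversampling ("balanced sampling") for unbalanced sites.

Model development uses a fixed train/test patient split with K
cross-validation folds inside the training set; the K fold models are
ensembled at test time by averaging class probabilities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from isletscope.encoding import EmbeddingBag
from isletscope.synthetic import ValidationError


# ---------------------------------------------------------------------------
# Split plan
# ---------------------------------------------------------------------------

@dataclass
class Fold:
    train: list[str]
    validation: list[str]


@dataclass
class SplitPlan:
    """Held-out test patients plus K train/validation folds."""

    test: list[str]
    folds: list[Fold]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"test": self.test, "folds": [asdict(f) for f in self.folds]}, indent=1
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        data = json.loads(Path(path).read_text())
        return cls(test=data["test"], folds=[Fold(**f) for f in data["folds"]])


def make_splits(
    cohort: pd.DataFrame,
    n_test: int = 25,
    k: int = 15,
    n_val: int = 15,
    seed: int = 0,
) -> SplitPlan:
    """Deterministic patient-level split: test set plus K CV folds.

    The test set is stratified by diabetic status (so both classes are
    present for evaluation); each fold then draws ``n_val`` validation
    patients uniformly from the remaining training patients, leaving
    ``n_patients - n_test - n_val`` training patients per fold.
    """
    n_patients = len(cohort)
    if n_test + n_val > n_patients:
        raise ValidationError("n_test + n_val exceeds the cohort size")
    if k < 1 or n_test < 0 or n_val < 0:
        raise ValidationError("infeasible split sizes")
    rng = np.random.default_rng(seed)
    ids = cohort["patient_id"].to_numpy()
    status = cohort["diabetic_status"].to_numpy()

    test: list[str] = []
    if n_test > 0:
        for cls in (0, 1):
            cls_ids = ids[status == cls]
            n_cls = int(round(n_test * len(cls_ids) / n_patients))
            n_cls = min(n_cls, len(cls_ids))
            test.extend(rng.choice(cls_ids, size=n_cls, replace=False))
        while len(test) < n_test:  # rounding remainder
            extra = rng.choice(np.setdiff1d(ids, test), size=1)[0]
            test.append(extra)
        test = [str(t) for t in test[:n_test]]
    train_pool = np.array(sorted(set(ids) - set(test)))

    folds = []
    for _ in range(k):
        val = rng.choice(train_pool, size=n_val, replace=False) if n_val else np.array([])
        train = np.setdiff1d(train_pool, val)
        folds.append(Fold(train=[str(t) for t in train], validation=[str(v) for v in val]))
    return SplitPlan(test=test, folds=folds)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyper-parameters (defaults mirror the study's adaptations)."""

    subsample_fraction: float = 0.05
    epochs: int = 60
    lr: float = 0.05
    min_lr: float = 0.0
    accumulation: int = 4
    hidden: int = 64
    weight_decay: float = 1e-4
    instance_loss_weight: float = 0.0
    instance_top_k: int = 2
    balanced_cohorts: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValidationError("subsample_fraction must lie in (0, 1]")


def cosine_lr(step: int, total_steps: int, lr: float, min_lr: float = 0.0) -> float:
    """Cosine-annealed learning rate; strictly decreasing over the schedule."""
    if total_steps <= 1:
        return lr
    frac = step / (total_steps - 1)
    return min_lr + 0.5 * (lr - min_lr) * (1.0 + np.cos(np.pi * frac))


class GatedAttentionMIL:
    """Single-branch gated-attention MIL with a 2-class linear head.

    Attention for patch i: ``a_i = w . (tanh(V h_i + bv) * sigmoid(U h_i + bu))``
    normalized by softmax over the bag; the slide representation is
    ``z = sum_i alpha_i h_i``.
    """

    PARAM_NAMES = ("V", "bv", "U", "bu", "w", "Wc", "bc")

    def __init__(self, dim: int, hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        s = 1.0 / np.sqrt(dim)
        self.dim = dim
        self.hidden = hidden
        self.params = {
            "V": rng.normal(0, s, (dim, hidden)),
            "bv": np.zeros(hidden),
            "U": rng.normal(0, s, (dim, hidden)),
            "bu": np.zeros(hidden),
            "w": rng.normal(0, 1.0 / np.sqrt(hidden), hidden),
            "Wc": rng.normal(0, s, (dim, 2)),
            "bc": np.zeros(2),
        }
        # feature standardization fitted on the training fold
        self.feat_mean = np.zeros(dim)
        self.feat_std = np.ones(dim)
        self.train_log: list[dict] = []

    # -- forward -------------------------------------------------------

    def _standardize(self, H: np.ndarray) -> np.ndarray:
        return (H - self.feat_mean) / self.feat_std

    def forward(self, H_raw: np.ndarray) -> dict:
        if H_raw.shape[1] != self.dim:
            raise ValidationError(
                f"bag dimension {H_raw.shape[1]} does not match model dimension {self.dim}"
            )
        p = self.params
        H = self._standardize(H_raw)
        pre_v = H @ p["V"] + p["bv"]
        pre_u = H @ p["U"] + p["bu"]
        t = np.tanh(pre_v)
        s = 1.0 / (1.0 + np.exp(-pre_u))
        g = t * s
        e = g @ p["w"]
        e = e - e.max()
        alpha = np.exp(e)
        alpha /= alpha.sum()
        z = alpha @ H
        logits = z @ p["Wc"] + p["bc"]
        logits = logits - logits.max()
        probs = np.exp(logits)
        probs /= probs.sum()
        return {
            "H": H, "t": t, "s": s, "g": g, "e": e,
            "alpha": alpha, "z": z, "probs": probs,
        }

    def gradients(self, cache: dict, y: int, instance_cfg: tuple[float, int] | None = None) -> dict:
        """Cross-entropy gradients for one bag (hand-derived backprop)."""
        p = self.params
        H, t, s, g, alpha, z, probs = (
            cache["H"], cache["t"], cache["s"], cache["g"],
            cache["alpha"], cache["z"], cache["probs"],
        )
        dlogits = probs.copy()
        dlogits[y] -= 1.0
        grads = {
            "Wc": np.outer(z, dlogits),
            "bc": dlogits,
        }
        dz = p["Wc"] @ dlogits
        dalpha = H @ dz
        de = alpha * (dalpha - float(alpha @ dalpha))
        grads["w"] = g.T @ de
        dg = np.outer(de, p["w"])
        dt = dg * s
        ds = dg * t
        dpre_v = dt * (1.0 - t**2)
        dpre_u = ds * s * (1.0 - s)

        if instance_cfg is not None:
            # auxiliary instance loss on top-k / bottom-k attended patches
            weight, top_k = instance_cfg
            n = len(alpha)
            k = min(top_k, n // 2) or 1
            order = np.argsort(cache["e"])
            targets = {i: float(y) for i in order[-k:]}
            targets.update({i: 0.0 for i in order[:k]})
            for i, tgt in targets.items():
                q = 1.0 / (1.0 + np.exp(-cache["e"][i]))
                de_i = weight * (q - tgt) / (2 * k)
                grads["w"] += de_i * g[i]
                dgi = de_i * p["w"]
                dpre_v[i] += dgi * s[i] * (1.0 - t[i] ** 2)
                dpre_u[i] += dgi * t[i] * s[i] * (1.0 - s[i])

        grads["V"] = H.T @ dpre_v
        grads["bv"] = dpre_v.sum(axis=0)
        grads["U"] = H.T @ dpre_u
        grads["bu"] = dpre_u.sum(axis=0)
        return grads

    def attention_gradient(self, cache: dict, target: int) -> np.ndarray:
        """Exact gradient of the target logit w.r.t. the attention weights."""
        return cache["H"] @ self.params["Wc"][:, target]

    # -- persistence ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            feat_mean=self.feat_mean,
            feat_std=self.feat_std,
            **self.params,
        )
        path.with_suffix(".json").write_text(
            json.dumps({"dim": self.dim, "hidden": self.hidden})
        )

    @classmethod
    def load(cls, path: str | Path) -> "GatedAttentionMIL":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(meta["dim"], meta["hidden"])
        with np.load(path.with_suffix(".npz")) as data:
            for name in cls.PARAM_NAMES:
                model.params[name] = data[name]
            model.feat_mean = data["feat_mean"]
            model.feat_std = data["feat_std"]
        return model


def predict(model: GatedAttentionMIL, bag: EmbeddingBag) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and per-patch attention weights for one bag."""
    cache = model.forward(bag.vectors)
    return cache["probs"], cache["alpha"]


def ensemble_predict(
    models: Sequence[GatedAttentionMIL], bag: EmbeddingBag
) -> np.ndarray:
    """Arithmetic mean of the class-probability vectors of all fold models."""
    if not models:
        raise ValidationError("ensemble requires at least one model")
    return np.mean([predict(m, bag)[0] for m in models], axis=0)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _epoch_order(
    pids: list[str],
    labels: Mapping[str, int],
    cohorts: Mapping[str, str] | None,
    balanced: tuple[str, ...],
    rng: np.random.Generator,
) -> list[str]:
    """Bag visiting order with within-cohort minority oversampling."""
    order = list(pids)
    if cohorts is not None and balanced:
        for site in balanced:
            members = [p for p in pids if cohorts[p] == site]
            pos = [p for p in members if labels[p] == 1]
            neg = [p for p in members if labels[p] == 0]
            minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
            deficit = len(majority) - len(minority)
            if minority and deficit > 0:
                order.extend(rng.choice(minority, size=deficit, replace=True))
    rng.shuffle(order)
    return order


def train_fold(
    bags: Mapping[str, EmbeddingBag],
    labels: Mapping[str, int],
    fold: Fold,
    cfg: TrainConfig,
    cohorts: Mapping[str, str] | None = None,
) -> GatedAttentionMIL:
    """Fit one fold model on its training patients.

    Each epoch shows every training bag once (plus oversampled minority
    bags when balanced sampling is active), with a fresh random subsample
    of ``ceil(fraction * n_patches)`` patches per bag; Adam updates are
    applied every ``accumulation`` bags at the cosine-annealed rate.
    """
    train_ids = [p for p in fold.train if p in bags]
    classes = {labels[p] for p in train_ids}
    if classes != {0, 1}:
        raise ValidationError("each fold must contain both classes for training")

    dim = next(iter(bags.values())).dim
    rng = np.random.default_rng(cfg.seed)
    model = GatedAttentionMIL(dim, hidden=cfg.hidden, seed=cfg.seed)
    all_vecs = np.concatenate([bags[p].vectors for p in train_ids])
    model.feat_mean = all_vecs.mean(axis=0)
    model.feat_std = np.maximum(all_vecs.std(axis=0), 1e-6)

    # Adam state
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(val) for k, val in model.params.items()}
    acc = {k: np.zeros_like(val) for k, val in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t_adam = 0
    n_acc = 0

    order0 = _epoch_order(train_ids, labels, cohorts, cfg.balanced_cohorts, rng)
    steps_per_epoch = max(1, len(order0) // cfg.accumulation)
    total_steps = cfg.epochs * steps_per_epoch
    instance_cfg = (
        (cfg.instance_loss_weight, cfg.instance_top_k)
        if cfg.instance_loss_weight > 0
        else None
    )

    step = 0
    for epoch in range(cfg.epochs):
        order = _epoch_order(train_ids, labels, cohorts, cfg.balanced_cohorts, rng)
        epoch_loss = 0.0
        for pid in order:
            bag = bags[pid]
            n = bag.n_patches
            k = max(1, int(np.ceil(cfg.subsample_fraction * n)))
            idx = rng.choice(n, size=k, replace=False) if k < n else np.arange(n)
            cache = model.forward(bag.vectors[idx])
            y = labels[pid]
            epoch_loss -= float(np.log(cache["probs"][y] + 1e-12))
            grads = model.gradients(cache, y, instance_cfg)
            for key in acc:
                acc[key] += grads[key]
            n_acc += 1
            if n_acc >= cfg.accumulation:
                lr = cosine_lr(step, total_steps, cfg.lr, cfg.min_lr)
                t_adam += 1
                for key, g in acc.items():
                    g = g / n_acc + cfg.weight_decay * model.params[key]
                    m[key] = beta1 * m[key] + (1 - beta1) * g
                    v[key] = beta2 * v[key] + (1 - beta2) * g * g
                    mhat = m[key] / (1 - beta1**t_adam)
                    vhat = v[key] / (1 - beta2**t_adam)
                    model.params[key] -= lr * mhat / (np.sqrt(vhat) + eps)
                    acc[key][:] = 0.0
                n_acc = 0
                step += 1
        model.train_log.append({"epoch": epoch, "loss": epoch_loss / len(order)})
    return model


def train_ensemble(
    bags: Mapping[str, EmbeddingBag],
    labels: Mapping[str, int],
    plan: SplitPlan,
    cfg: TrainConfig,
    cohorts: Mapping[str, str] | None = None,
) -> list[GatedAttentionMIL]:
    """Train one model per CV fold (fold index folded into the seed)."""
    models = []
    for i, fold in enumerate(plan.folds):
        fold_cfg = TrainConfig(**{**asdict(cfg), "seed": cfg.seed * 1000 + i})
        models.append(train_fold(bags, labels, fold, fold_cfg, cohorts))
    return models


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the midrank Mann–Whitney statistic.

    Ties receive half credit.  Raises when only one class is present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUROC requires both classes")
    ranks = rankdata(scores)  # midranks
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
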