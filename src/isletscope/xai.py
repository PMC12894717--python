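"""Attention- and gradient-based attribution methods.

Implements the explanation toolbox used to interpret the MIL classifier:

* class-specific **layer-wise relevance propagation** through linear layers,
  restricted to the index set of non-negative contributions, and its
  attention extension — per-block relevance-filtered attention matrices
  combined across blocks by matrix rollout;
* **saliency** (positive gradient), **integrated gradients** along a
  straight path from a black (zero) baseline, **expected gradients**
  (integrated gradients averaged over a baseline distribution, Monte
  Carlo), and **DeepLIFT** with the rescale rule and summation-to-delta;
* a **SmoothGrad** wrapper: average attributions over Gaussian-perturbed
  inputs, blur with a Gaussian kernel, keep the positive part;
* heatmap assembly from patch-level scores onto the slide raster.

All gradients are exact backpropagated gradients from :mod:`isletscope.nnet`
or from the MIL model's hand-derived backward pass; a central-difference
fallback exists for scorers that cannot provide gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from isletscope import nnet
from isletscope.mil import GatedAttentionMIL
from isletscope.encoding import EmbeddingBag
from isletscope.nnet import Dense, Sequential, _ACTIVATIONS
from isletscope.synthetic import ValidationError
from isletscope.tiling import PatchGrid


@dataclass(frozen=True)
class AttributionConfig:
    """Shared attribution settings (defaults follow the study)."""

    ig_steps: int = 32
    eg_samples: int = 32
    smoothgrad_sigma: float = 1.0
    smoothgrad_n: int = 10
    kernel_sigma: float = 1.0
    positive_only: bool = True
    deeplift_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.ig_steps < 2:
            raise ValidationError("ig_steps must be >= 2")
        if self.smoothgrad_n < 1 or self.eg_samples < 1:
            raise ValidationError("sample counts must be >= 1")
        if self.smoothgrad_sigma < 0 or self.kernel_sigma < 0:
            raise ValidationError("sigmas must be >= 0")


def _gradient(net, x: np.ndarray, target: int) -> np.ndarray:
    try:
        return net.grad_input(x, target)
    except (AttributeError, NotImplementedError):
        warnings.warn("scorer provides no exact gradient; using central differences")
        return nnet.numerical_gradient(lambda z: float(net.predict(z)[..., target]), x)


# ---------------------------------------------------------------------------
# Gradient-based attributions
# ---------------------------------------------------------------------------

def saliency(net, x: np.ndarray, target: int = 1) -> np.ndarray:
    """Positive part of the gradient of the target score w.r.t. the input."""
    return np.maximum(_gradient(net, np.asarray(x, dtype=float), target), 0.0)


def integrated_gradients(
    net,
    x: np.ndarray,
    x0: np.ndarray | None = None,
    target: int = 1,
    steps: int = 32,
) -> np.ndarray:
    """Path-integrated gradients from baseline ``x0`` (default: black/zero).

    The path integral over alpha in [0, 1] is approximated with the
    trapezoid rule; the completeness property (attributions summing to
    ``f(x) - f(x0)``) holds up to the quadrature error, which shrinks as
    ``steps`` grows and vanishes for linear scorers.
    """
    x = np.asarray(x, dtype=float)
    x0 = np.zeros_like(x) if x0 is None else np.asarray(x0, dtype=float)
    if x0.shape != x.shape:
        raise ValidationError("baseline shape must match the input shape")
    if steps < 2:
        raise ValidationError("steps must be >= 2")
    alphas = np.linspace(0.0, 1.0, steps)
    weights = np.full(steps, 1.0 / (steps - 1))
    weights[0] = weights[-1] = 0.5 / (steps - 1)
    avg_grad = np.zeros_like(x)
    for a, w in zip(alphas, weights):
        avg_grad += w * _gradient(net, x0 + a * (x - x0), target)
    return (x - x0) * avg_grad


def expected_gradients(
    net,
    x: np.ndarray,
    baseline_sampler,
    n_samples: int = 32,
    target: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo integrated gradients over a baseline distribution.

    ``baseline_sampler(rng)`` must return baselines of the input's shape.
    With a point-mass sampler this converges to :func:`integrated_gradients`
    at Monte-Carlo rate 1/sqrt(n).  Seeded, hence reproducible.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(x)
    for _ in range(n_samples):
        x0 = np.asarray(baseline_sampler(rng), dtype=float)
        if x0.shape != x.shape:
            raise ValidationError("baseline sampler returned a mismatched shape")
        a = rng.uniform()
        acc += (x - x0) * _gradient(net, x0 + a * (x - x0), target)
    return acc / n_samples


def deeplift(
    net: Sequential,
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    target: int = 1,
    tol: float = 1e-9,
) -> np.ndarray:
    """DeepLIFT (rescale rule) input contributions for a layered network.

    Every neuron's activation is compared with its activation at the
    baseline input; contribution multipliers m = C/Delta are chained
    backwards.  For elementwise nonlinearities the multiplier is
    Delta-out / Delta-in, guarded by ``tol``: near-zero input deltas fall
    back to the local derivative.  The input contributions
    ``m * (x - baseline)`` satisfy summation-to-delta exactly for this
    layer family.
    """
    x = np.asarray(x, dtype=float)
    x0 = np.zeros_like(x) if baseline is None else np.asarray(baseline, dtype=float)
    if x0.shape != x.shape:
        raise ValidationError("baseline shape must match the input shape")
    acts_x = net.activations(x)
    acts_0 = net.activations(x0)

    m = np.zeros_like(acts_x[-1])
    m[..., target] = 1.0
    for layer, a_x, a_0 in zip(reversed(net.layers), reversed(acts_x[:-1]), reversed(acts_0[:-1])):
        if isinstance(layer, Dense):
            m = m @ layer.W.T
        elif isinstance(layer, _ACTIVATIONS):
            d_in = a_x - a_0
            d_out = layer.forward(a_x) - layer.forward(a_0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = d_out / d_in
            # near-zero delta: use the local derivative instead
            mid = 0.5 * (a_x + a_0)
            layer.forward(mid)
            deriv = layer.backward(np.ones_like(mid))
            ratio = np.where(np.abs(d_in) > tol, ratio, deriv)
            m = m * ratio
        else:
            raise ValidationError(f"deeplift does not support layer {type(layer).__name__}")
    return m * (x - x0)


def smoothgrad(
    method,
    x: np.ndarray,
    sigma: float = 1.0,
    n: int = 10,
    kernel_sigma: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """SmoothGrad wrapper around any attribution map ``method(x) -> map``.

    Averages ``n`` maps computed on inputs perturbed with N(0, sigma^2)
    noise, blurs the average with a Gaussian kernel (reflective borders)
    and keeps the positive part.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(x, dtype=float)
    for _ in range(n):
        noise = rng.normal(0.0, sigma, size=x.shape) if sigma > 0 else 0.0
        acc += method(x + noise)
    acc /= n
    if kernel_sigma > 0 and acc.ndim >= 2:
        acc = gaussian_filter(acc, sigma=kernel_sigma, mode="reflect")
    return np.maximum(acc, 0.0)


# ---------------------------------------------------------------------------
# Layer-wise relevance propagation and attention rollout
# ---------------------------------------------------------------------------

def lrp_relevance(net: Sequential, x: np.ndarray, target: int) -> np.ndarray:
    """Class-specific relevance propagated through the Dense layers.

    Relevance is initialized as a one-hot at the target class and pulled
    backwards layer by layer; at each linear layer only index pairs with a
    non-negative contribution ``x_j * W_ji >= 0`` are retained, each input
    receiving the retained-contribution share of its downstream relevance.
    Elementwise activations pass relevance through unchanged.  Relevance
    stays non-negative, and is conserved at every layer whose downstream
    units all retain at least one contribution.
    """
    x = np.asarray(x, dtype=float)
    acts = net.activations(x)
    r = np.zeros_like(acts[-1])
    r[..., target] = 1.0
    for layer, a_in in zip(reversed(net.layers), reversed(acts[:-1])):
        if isinstance(layer, Dense):
            contrib = a_in[..., :, None] * layer.W[None, ...] if a_in.ndim > 1 else a_in[:, None] * layer.W
            contrib = np.where(contrib >= 0.0, contrib, 0.0)
            denom = contrib.sum(axis=-2)
            with np.errstate(divide="ignore", invalid="ignore"):
                share = contrib / denom[..., None, :]
            share = np.nan_to_num(share, nan=0.0, posinf=0.0, neginf=0.0)
            r = (share * r[..., None, :]).sum(axis=-1)
        elif isinstance(layer, _ACTIVATIONS):
            pass  # identity for relevance
        else:
            raise ValidationError(f"lrp does not support layer {type(layer).__name__}")
    return r


def relevance_filtered_attention(
    grad_A: np.ndarray, relevance: np.ndarray
) -> np.ndarray:
    """Per-block relevance-filtered attention matrix.

    ``grad_A`` holds the gradients of the target score with respect to the
    attention entries, shaped (heads, n, n) or (n, n); ``relevance`` is the
    matching per-entry relevance.  Returns ``I + E_h (grad_A * relevance)^+``
    — the identity plus the head-averaged positive part of the
    gradient-relevance product.
    """
    grad_A = np.asarray(grad_A, dtype=float)
    relevance = np.asarray(relevance, dtype=float)
    prod = grad_A * relevance
    if prod.ndim == 3:
        prod = prod.mean(axis=0)
    if prod.ndim != 2 or prod.shape[0] != prod.shape[1]:
        raise ValidationError("attention matrices must be square")
    return np.eye(prod.shape[0]) + np.maximum(prod, 0.0)


def attention_rollout(a_hats: list[np.ndarray]) -> np.ndarray:
    """Ordered product of filtered attention matrices (empty list = identity)."""
    if not a_hats:
        raise ValidationError("rollout needs the token count; pass identity blocks")
    out = np.eye(a_hats[0].shape[0])
    for a in a_hats:
        out = a @ out
    return out


class FixedAttentionStack:
    """Toy transformer-like stack with scalar token features.

    Tokens carry scalar features x in R^n.  Block b mixes tokens with a
    fixed row-stochastic attention matrix per head and a scalar value
    weight: ``x_{b+1} = mean_h(A_bh) x_b * w_b``.  A readout matrix maps the
    final tokens to class scores.  Because every map is linear, attention
    gradients and Eq.-style relevance are exact, making the stack a precise
    fixture for the attention-attribution pipeline.
    """

    def __init__(self, attention: list[np.ndarray], value_weights: list[float], readout: np.ndarray):
        self.attention = [self._as_heads(a) for a in attention]
        self.value_weights = list(value_weights)
        self.readout = np.asarray(readout, dtype=float)
        if len(self.attention) != len(self.value_weights):
            raise ValidationError("one value weight per block is required")
        for a in self.attention:
            rows = a.sum(axis=-1)
            if not np.allclose(rows, 1.0, atol=1e-8):
                raise ValidationError("attention rows must sum to 1")

    @staticmethod
    def _as_heads(a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        return a[None, ...] if a.ndim == 2 else a

    @property
    def n_blocks(self) -> int:
        return len(self.attention)

    def forward(self, x: np.ndarray) -> dict:
        xs = [np.asarray(x, dtype=float)]
        for a, w in zip(self.attention, self.value_weights):
            xs.append(a.mean(axis=0) @ xs[-1] * w)
        scores = self.readout.T @ xs[-1]
        return {"xs": xs, "scores": scores}

    def grad_attention(self, cache: dict, target: int) -> list[np.ndarray]:
        """Exact gradient of the target score w.r.t. each head's attention."""
        xs = cache["xs"]
        g = self.readout[:, target].copy()  # d score / d x_B
        grads: list[np.ndarray] = [None] * self.n_blocks
        for b in range(self.n_blocks - 1, -1, -1):
            a, w = self.attention[b], self.value_weights[b]
            h = a.shape[0]
            grads[b] = np.stack([np.outer(g * w, xs[b]) for _ in range(h)]) / h
            g = a.mean(axis=0).T @ g * w
        return grads

    def relevance(self, cache: dict, target: int) -> list[np.ndarray]:
        """Per-block relevance of the attention entries (non-negative-share rule).

        The relevance of output token i at the final layer follows the
        linear-layer propagation rule from the one-hot class init through
        the readout; within block b, entry (i, j) receives the share of
        token i's relevance carried by its retained contribution
        ``A_ij x_j w``.
        """
        xs = cache["xs"]
        # relevance of final tokens from the readout (one-hot class init)
        contrib = xs[-1][:, None] * self.readout
        contrib = np.where(contrib >= 0, contrib, 0.0)
        denom = contrib[:, target].sum()
        r_tokens = contrib[:, target] / denom if denom > 0 else np.zeros_like(xs[-1])

        rel: list[np.ndarray] = [None] * self.n_blocks
        for b in range(self.n_blocks - 1, -1, -1):
            a, w = self.attention[b], self.value_weights[b]
            m = a.mean(axis=0) * w
            contrib = m * xs[b][None, :]
            contrib = np.where(contrib >= 0, contrib, 0.0)
            denom = contrib.sum(axis=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                share = contrib / denom
            share = np.nan_to_num(share)
            r_entries = share * r_tokens[:, None]
            rel[b] = np.broadcast_to(r_entries, a.shape).copy()
            r_tokens = r_entries.sum(axis=0)
        return rel


def attention_lrp(stack: FixedAttentionStack, x: np.ndarray, target: int = 1) -> np.ndarray:
    """Class-specific token relevance via relevance-filtered attention rollout.

    Computes the per-block filtered matrices ``A-hat = I + E_h(grad ⊙ R)^+``
    and combines them across all blocks by matrix rollout; with zero blocks
    the rollout is the identity and pure linear-layer relevance remains.
    Output: one non-negative relevance score per token.
    """
    cache = stack.forward(x)
    n = len(cache["xs"][0])
    if stack.n_blocks == 0:
        rollout = np.eye(n)
    else:
        grads = stack.grad_attention(cache, target)
        rels = stack.relevance(cache, target)
        a_hats = [relevance_filtered_attention(g, r) for g, r in zip(grads, rels)]
        rollout = attention_rollout(a_hats)
    # base token relevance at the input layer via the retained-share rule
    base = _input_token_relevance(stack, cache, target)
    scores = rollout.T @ base
    total = scores.sum()
    return scores / total if total > 0 else scores


def _input_token_relevance(stack: FixedAttentionStack, cache: dict, target: int) -> np.ndarray:
    xs = cache["xs"]
    contrib = xs[-1][:, None] * stack.readout
    contrib = np.where(contrib >= 0, contrib, 0.0)
    denom = contrib[:, target].sum()
    return contrib[:, target] / denom if denom > 0 else np.zeros_like(xs[-1])


def attention_lrp_mil(
    model: GatedAttentionMIL, bag: EmbeddingBag, target: int = 1
) -> np.ndarray:
    """Class-specific patch relevance for the gated-attention MIL model.

    The MIL head has a single attention row over patches; its relevance-
    filtered form reduces to the attention weights gated by the positive
    part of the exact attention gradient for the target class, normalized
    to sum to 1 (all-zero maps are returned as-is).
    """
    cache = model.forward(bag.vectors)
    grad = model.attention_gradient(cache, target)
    rel = cache["alpha"] * np.maximum(grad, 0.0)
    total = rel.sum()
    return rel / total if total > 0 else rel


# ---------------------------------------------------------------------------
# Heatmaps
# ---------------------------------------------------------------------------

def assemble_heatmap(
    scores: np.ndarray,
    grid: PatchGrid,
    background: float = 0.0,
    normalize: bool = False,
) -> np.ndarray:
    """Paint patch-level scores into their pixel boxes on the slide raster.

    ``scores`` may cover all patches or only the tissue patches (in grid
    order); non-tissue patches render as ``background``.  Values are
    preserved unless ``normalize`` is requested.
    """
    scores = np.asarray(scores, dtype=float)
    h, w = grid.image_shape
    raster = np.full((h, w), background, dtype=np.float32)
    if len(scores) == grid.n_patches:
        indices = np.arange(grid.n_patches)
    elif len(scores) == int(grid.tissue.sum()):
        indices = grid.tissue_indices()
    else:
        raise ValidationError("score vector does not align with the grid")
    if normalize and scores.max() > scores.min():
        scores = (scores - scores.min()) / (scores.max() - scores.min())
    for s, i in zip(scores, indices):
        if not grid.tissue[i]:
            continue
        y0, x0, y1, x1 = grid.boxes[i]
        raster[y0:y1, x0:x1] = s
    return raster


def save_heatmap(raster: np.ndarray, path) -> None:
    """Write a heatmap as 32-bit float TIFF plus an 8-bit PNG preview."""
    from pathlib import Path

    import tifffile
    from PIL import Image

    path = Path(path)
    tifffile.imwrite(path.with_suffix(".tiff"), raster.astype(np.float32))
    lo, hi = float(raster.min()), float(raster.max())
    preview = (raster - lo) / (hi - lo) if hi > lo else np.zeros_like(raster)
    Image.fromarray((preview * 255).astype(np.uint8)).save(path.with_suffix(".png"))
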