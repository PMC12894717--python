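"""Minimal differentiable feed-forward networks with exact backpropagation.

A tiny layer toolkit used in two places: as the differentiable scorer the
pixel-level attribution methods (saliency, integrated/expected gradients,
DeepLIFT) operate on, and as toy fixtures for the relevance-propagation
tests.  Layers cache their forward activations so input gradients and the
DeepLIFT rescale rule can be computed exactly, without any external
autodiff dependency.
"""

from __future__ import annotations

import numpy as np

from isletscope.synthetic import ValidationError


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map ``x @ W + b`` with ``W`` of shape (n_in, n_out)."""

    def __init__(self, W: np.ndarray, b: np.ndarray | None = None):
        self.W = np.asarray(W, dtype=float)
        self.b = np.zeros(self.W.shape[1]) if b is None else np.asarray(b, dtype=float)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out @ self.W.T


class ReLU(Layer):
    def forward(self, x):
        self._x = x
        return np.maximum(x, 0.0)

    def backward(self, grad_out):
        return grad_out * (self._x > 0)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad_out):
        return grad_out * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad_out):
        return grad_out * self._y * (1.0 - self._y)


class GELU(Layer):
    """Gaussian error linear unit (tanh approximation)."""

    _C = np.sqrt(2.0 / np.pi)

    def forward(self, x):
        self._x = x
        self._t = np.tanh(self._C * (x + 0.044715 * x**3))
        return 0.5 * x * (1.0 + self._t)

    def backward(self, grad_out):
        x, t = self._x, self._t
        dt = (1.0 - t**2) * self._C * (1.0 + 3 * 0.044715 * x**2)
        return grad_out * (0.5 * (1.0 + t) + 0.5 * x * dt)


_ACTIVATIONS = (ReLU, Tanh, Sigmoid, GELU)


class Sequential:
    """A feed-forward stack of layers mapping a flat input to class scores.

    Provides exact input gradients via backpropagation, which is all the
    attribution methods need.
    """

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    @property
    def n_inputs(self) -> int:
        for layer in self.layers:
            if isinstance(layer, Dense):
                return layer.W.shape[0]
        raise ValidationError("network has no Dense layer")

    def predict(self, x: np.ndarray) -> np.ndarray:
        h = np.asarray(x, dtype=float)
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def grad_input(self, x: np.ndarray, target: int) -> np.ndarray:
        """Exact gradient of output ``target`` with respect to the input."""
        out = self.predict(x)
        grad = np.zeros_like(out)
        grad[..., target] = 1.0
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def activations(self, x: np.ndarray) -> list[np.ndarray]:
        """Input plus the output of every layer, in order."""
        acts = [np.asarray(x, dtype=float)]
        for layer in self.layers:
            acts.append(layer.forward(acts[-1]))
        return acts


def random_mlp(
    sizes: tuple[int, ...],
    activation: type[Layer] = ReLU,
    seed: int = 0,
    final_activation: bool = False,
) -> Sequential:
    """A randomly initialized MLP, handy as a smooth test scorer."""
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    for i in range(len(sizes) - 1):
        W = rng.normal(0, 1.0 / np.sqrt(sizes[i]), size=(sizes[i], sizes[i + 1]))
        b = rng.normal(0, 0.1, size=sizes[i + 1])
        layers.append(Dense(W, b))
        if i < len(sizes) - 2 or final_activation:
            layers.append(activation())
    return Sequential(layers)


def pooled_pixel_scorer(
    patch_shape: tuple[int, int],
    pool: int = 8,
    hidden: int = 32,
    n_classes: int = 2,
    seed: int = 0,
) -> "PixelScorer":
    """Differentiable patch scorer: mean-pool then a small MLP.

    Used as the differentiable stand-in encoder+head when attribution maps
    are propagated down to pixels.
    """
    h, w = patch_shape
    if h % pool or w % pool:
        raise ValidationError("pool must divide the patch shape")
    mlp = random_mlp(((h // pool) * (w // pool), hidden, n_classes), seed=seed)
    return PixelScorer(mlp, patch_shape, pool)


class PixelScorer:
    """Wraps an MLP on mean-pooled pixels; exposes pixel-level gradients."""

    def __init__(self, mlp: Sequential, patch_shape: tuple[int, int], pool: int):
        self.mlp = mlp
        self.patch_shape = patch_shape
        self.pool = pool

    def _pool(self, x: np.ndarray) -> np.ndarray:
        h, w = self.patch_shape
        p = self.pool
        return x.reshape(h // p, p, w // p, p).mean(axis=(1, 3)).ravel()

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.mlp.predict(self._pool(x.reshape(self.patch_shape)))

    def grad_input(self, x: np.ndarray, target: int) -> np.ndarray:
        h, w = self.patch_shape
        p = self.pool
        g = self.mlp.grad_input(self._pool(x.reshape(self.patch_shape)), target)
        g = g.reshape(h // p, w // p) / (p * p)
        g = np.repeat(np.repeat(g, p, axis=0), p, axis=1)
        return g.reshape(x.shape)


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of a scalar function; test oracle."""
    x = np.asarray(x, dtype=float)
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        grad[i] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return grad
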