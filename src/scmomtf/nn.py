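"""Minimal feed-forward neural-network layers with reverse-mode gradients.

The model is small and shallow by design, so a compact numpy implementation
keeps the whole framework dependency-light and CPU-deterministic.  Each layer
caches its forward inputs; ``backward`` consumes the upstream gradient,
accumulates parameter gradients in ``grads`` and returns the gradient with
respect to its input.  ``Adam`` implements the standard adaptive-moment
update.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float64


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Linear(Layer):
    """Affine map with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout):
        self.gW += self._x.T @ gout
        self.gb += gout.sum(axis=0)
        return gout @ self.W.T


class Tanh(Layer):
    def __init__(self):
        self._y: np.ndarray | None = None

    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gout):
        return gout * (1.0 - self._y**2)


class Sigmoid(Layer):
    def __init__(self):
        self._y: np.ndarray | None = None

    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gout):
        return gout * self._y * (1.0 - self._y)


class LayerNorm(Layer):
    """Per-sample normalization (batch-independent, so inference is a pure
    row-wise function) with learnable scale and shift."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = np.ones(dim, dtype=DTYPE)
        self.beta = np.zeros(dim, dtype=DTYPE)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._inv_std: np.ndarray | None = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]

    def forward(self, x):
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        return self._xhat * self.gamma + self.beta

    def backward(self, gout):
        xhat, inv_std = self._xhat, self._inv_std
        self.ggamma += (gout * xhat).sum(axis=0)
        self.gbeta += gout.sum(axis=0)
        gx_hat = gout * self.gamma
        # standard layer-norm input gradient
        return (
            gx_hat
            - gx_hat.mean(axis=1, keepdims=True)
            - xhat * (gx_hat * xhat).mean(axis=1, keepdims=True)
        ) * inv_std


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, gout):
        for l in reversed(self.layers):
            gout = l.backward(gout)
        return gout

    def zero_grad(self):
        for g in self.grads():
            g.fill(0.0)


def mlp(
    dims: list[int],
    rng: np.random.Generator,
    final_sigmoid: bool = False,
) -> Sequential:
    """Stack of Linear->LayerNorm->Tanh blocks with a linear (or sigmoid) head."""
    layers: list[Layer] = []
    for i in range(len(dims) - 2):
        layers += [Linear(dims[i], dims[i + 1], rng), LayerNorm(dims[i + 1]), Tanh()]
    layers.append(Linear(dims[-2], dims[-1], rng))
    if final_sigmoid:
        layers.append(Sigmoid())
    return Sequential(*layers)


class Adam:
    """Adaptive-moment optimizer with optional decoupled weight decay.

    ``decay_mask`` selects which parameters the decay applies to (weight
    matrices only, by convention — never biases or normalization scales).
    """

    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0, decay_mask=None):
        self.params = list(params)
        self.grad_refs = list(grads)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.decay_mask = list(decay_mask) if decay_mask is not None else [False] * len(self.params)
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v, dec in zip(self.params, self.grad_refs, self.m, self.v, self.decay_mask):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if dec and self.weight_decay > 0.0:
                p -= self.lr * self.weight_decay * p


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
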