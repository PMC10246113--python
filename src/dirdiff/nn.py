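"""Minimal numpy neural-network layers with explicit backpropagation.

The score models in this package are small (tokenwise MLPs, dilated 1-D
convolutional stacks, and a relational transformer), so they are
implemented directly in numpy with hand-written forward/backward passes
and an Adam optimizer. Layers cache their forward activations
internally; a layer's ``backward`` must be called after its ``forward``
and before the next forward pass (single-stream training loops, which
is all this package does).

All random initialization flows through an explicit
``numpy.random.Generator`` so that training is reproducible bit-for-bit
from a seed.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

__all__ = [
    "Param",
    "Linear",
    "LayerNorm",
    "Conv1d",
    "gelu",
    "gelu_grad",
    "softmax",
    "time_features",
    "Adam",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
    pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
    return cdf + x * pdf


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(x: np.ndarray) -> np.ndarray:
    return (x > 0.0).astype(x.dtype)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def time_features(t: np.ndarray, dim: int, t_min: float = 1e-2,
                  t_max: float = 4.0) -> np.ndarray:
    """Sinusoidal embedding of log diffusion time, shape (..., dim).

    The log scale resolves the small-t regime where transition scores
    change fastest; times are mapped to [0, 1] via log(t/t_min).
    """
    t = np.clip(np.asarray(t, dtype=float)[..., None], t_min / 2, None)
    u = np.log(t / t_min) / math.log(t_max / t_min)
    half = dim // 2
    freqs = np.exp(np.linspace(0.0, math.log(30.0), half))
    ang = u * freqs
    out = np.concatenate([np.sin(ang), np.cos(ang)], axis=-1)
    if out.shape[-1] < dim:
        out = np.concatenate([out, u], axis=-1)
    return out


class Linear:
    """Affine map on the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        scale = math.sqrt(2.0 / (d_in + d_out)) if scale is None else scale
        self.W = Param(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self.W.value.shape[0])
        g2 = g.reshape(-1, self.W.value.shape[1])
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return g @ self.W.value.T


class LayerNorm:
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(d))
        self.beta = Param(np.zeros(d))
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (g * xhat).sum(axis=tuple(range(g.ndim - 1)))
        self.beta.grad += g.sum(axis=tuple(range(g.ndim - 1)))
        gh = g * self.gamma.value
        d = xhat.shape[-1]
        return inv * (
            gh
            - gh.mean(axis=-1, keepdims=True)
            - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
        )


class Conv1d:
    """Same-padded 1-D convolution over (B, L, C_in) with dilation."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dilation: int = 1):
        assert kernel % 2 == 1, "odd kernel sizes only (same padding)"
        scale = math.sqrt(2.0 / (c_in * kernel + c_out))
        self.W = Param(rng.normal(0.0, scale, size=(kernel, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.kernel = kernel
        self.dilation = dilation
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _gather(self, xp: np.ndarray, L: int) -> np.ndarray:
        K, d = self.kernel, self.dilation
        pad = (K // 2) * d
        idx = np.arange(L)[:, None] + np.arange(K)[None, :] * d  # into padded axis
        return xp[:, idx, :], idx, pad

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        pad = (self.kernel // 2) * self.dilation
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        cols, idx, _ = self._gather(xp, L)  # (B, L, K, C)
        self._cache = (cols, idx, x.shape, pad)
        return np.einsum("blkc,kco->blo", cols, self.W.value) + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, idx, xshape, pad = self._cache
        self.W.grad += np.einsum("blkc,blo->kco", cols, g)
        self.b.grad += g.sum(axis=(0, 1))
        gcols = np.einsum("blo,kco->blkc", g, self.W.value)
        B, L, C = xshape
        gxp = np.zeros((B, L + 2 * pad, C))
        np.add.at(gxp, (slice(None), idx), gcols)
        return gxp[:, pad:L + pad, :]


class Adam:
    """Adam optimizer over a flat list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1.0 - self.b1) * p.grad
            v[...] = self.b2 * v + (1.0 - self.b2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
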