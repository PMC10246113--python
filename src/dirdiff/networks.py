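"""Reference score-model architectures.

All networks implement the ``ScoreField`` interface: called with a
batch of simplex points ``x`` of shape (B, L, k), diffusion times ``t``
of shape (B,), and an optional per-position condition track, they
return scores in stick (v-) space, shape (B, L, k-1). Gradients flow
through ``backward``; parameters through ``params``. Evaluation is a
pure function of (x, t, condition) given fixed weights.

Three families are provided:

* :class:`MLPScoreNet` — a tokenwise MLP for i.i.d.-position toys;
* :class:`SequenceScoreNet` — a dilated residual 1-D convolutional
  stack for DNA-like sequences, with optional per-position
  conditioning (e.g. a transcription-initiation signal profile);
* :class:`SudokuScoreNet` — a transformer whose attention logits
  receive an additive bias projected from a binary relative positional
  encoding recording, for every cell pair, shared row / column / block
  membership (81 x 81 x 27 for standard Sudoku).
"""

from __future__ import annotations

import math
from typing import Protocol

import numpy as np

from .nn import (Adam, Conv1d, LayerNorm, Linear, Param, gelu, gelu_grad,
                 relu, relu_grad, softmax, time_features)

__all__ = [
    "ScoreField",
    "MLPScoreNet",
    "SequenceScoreNet",
    "SudokuScoreNet",
    "sudoku_rel_encoding",
    "TimeScaledScore",
    "build_sudoku_net",
    "build_sequence_net",
]

TIME_DIM = 16


class ScoreField(Protocol):
    """Callable score model s_theta(x, t[, condition]) in v-space."""

    def __call__(self, x: np.ndarray, t: np.ndarray,
                 condition: np.ndarray | None = None) -> np.ndarray: ...

    def backward(self, grad: np.ndarray) -> None: ...

    def params(self) -> list[Param]: ...


class MLPScoreNet:
    """Tokenwise MLP score model: positions are treated independently."""

    def __init__(self, k: int, hidden: int = 64, rng: np.random.Generator | None = None):
        rng = np.random.default_rng(0) if rng is None else rng
        self.k = k
        self.l1 = Linear(k + TIME_DIM, hidden, rng)
        self.l2 = Linear(hidden, hidden, rng)
        self.l3 = Linear(hidden, k - 1, rng, scale=1e-2)
        self._cache = None

    def params(self) -> list[Param]:
        return self.l1.params() + self.l2.params() + self.l3.params()

    def __call__(self, x, t, condition=None):
        x = np.asarray(x, dtype=float)
        tf = time_features(np.asarray(t, dtype=float), TIME_DIM)
        tf = np.broadcast_to(tf[:, None, :], x.shape[:-1] + (TIME_DIM,))
        h0 = np.concatenate([x, tf], axis=-1)
        a1 = self.l1.forward(h0)
        h1 = gelu(a1)
        a2 = self.l2.forward(h1)
        h2 = gelu(a2)
        out = self.l3.forward(h2)
        self._cache = (a1, a2)
        return out

    def backward(self, grad):
        a1, a2 = self._cache
        g = self.l3.backward(grad)
        g = self.l2.backward(g * gelu_grad(a2))
        self.l1.backward(g * gelu_grad(a1))


class _ConvBlock:
    """Residual block: conv(dilated) -> gelu -> conv(1) -> + input."""

    def __init__(self, width: int, kernel: int, dilation: int, rng):
        self.c1 = Conv1d(width, width, kernel, rng, dilation=dilation)
        self.c2 = Conv1d(width, width, 1, rng)
        self._a = None

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        a = self.c1.forward(x)
        self._a = a
        return x + self.c2.forward(relu(a))

    def backward(self, g):
        gb = self.c2.backward(g)
        return g + self.c1.backward(gb * relu_grad(self._a))


class SequenceScoreNet:
    """Dilated residual convolutional score model for sequences.

    The condition track (one extra channel) is concatenated to the
    simplex state per position; time enters through sinusoidal features
    broadcast along the sequence. Receptive field grows with the
    dilation schedule 1, 2, 4, ... per block.
    """

    def __init__(self, k: int, conditional: bool = False, width: int = 48,
                 n_blocks: int = 4, kernel: int = 5,
                 rng: np.random.Generator | None = None):
        rng = np.random.default_rng(0) if rng is None else rng
        self.k = k
        self.conditional = conditional
        c_in = k + TIME_DIM + (1 if conditional else 0)
        self.stem = Conv1d(c_in, width, kernel, rng)
        self.blocks = [
            _ConvBlock(width, kernel, 2 ** (i % 4), rng) for i in range(n_blocks)
        ]
        self.head = Conv1d(width, k - 1, 1, rng)
        self.head.W.value *= 1e-2
        self._a0 = None

    def params(self):
        out = self.stem.params() + self.head.params()
        for b in self.blocks:
            out += b.params()
        return out

    def __call__(self, x, t, condition=None):
        x = np.asarray(x, dtype=float)
        B, L, _ = x.shape
        feats = [x]
        if self.conditional:
            if condition is None:
                raise ValueError("conditional network requires a condition track")
            cond = np.asarray(condition, dtype=float).reshape(B, L, 1)
            feats.append(cond)
        tf = np.broadcast_to(
            time_features(np.asarray(t, dtype=float), TIME_DIM)[:, None, :],
            (B, L, TIME_DIM),
        )
        feats.append(tf)
        h = self.stem.forward(np.concatenate(feats, axis=-1))
        self._a0 = h
        h = relu(h)
        for b in self.blocks:
            h = b.forward(h)
        return self.head.forward(h)

    def backward(self, grad):
        g = self.head.backward(grad)
        for b in reversed(self.blocks):
            g = b.backward(g)
        self.stem.backward(g * relu_grad(self._a0))


def sudoku_rel_encoding(n: int = 3) -> np.ndarray:
    """Binary relative positional encoding for (n^2 x n^2) Sudoku.

    Shape (T, T, 3 n^2) with T = n^4 cells: feature block 0 marks joint
    membership in row r (n^2 bits), block 1 columns, block 2 the n x n
    boxes. Symmetric in the two cell axes; every cell shares exactly
    one row, one column and one box with itself.
    """
    N = n * n
    T = N * N
    rows = np.repeat(np.arange(N), N)
    cols = np.tile(np.arange(N), N)
    boxes = (rows // n) * n + cols // n
    enc = np.zeros((T, T, 3 * N))
    for f, lab in enumerate((rows, cols, boxes)):
        same = lab[:, None] == lab[None, :]
        for r in range(N):
            enc[..., f * N + r] = same & (lab[:, None] == r)
    return enc


class _TransformerBlock:
    def __init__(self, d: int, heads: int, rng, mlp_ratio: int = 2):
        assert d % heads == 0
        self.d, self.h, self.dh = d, heads, d // heads
        self.ln1 = LayerNorm(d)
        self.qkv = Linear(d, 3 * d, rng)
        self.proj = Linear(d, d, rng)
        self.ln2 = LayerNorm(d)
        self.fc1 = Linear(d, mlp_ratio * d, rng)
        self.fc2 = Linear(mlp_ratio * d, d, rng)
        self._cache = None

    def params(self):
        return (self.ln1.params() + self.qkv.params() + self.proj.params()
                + self.ln2.params() + self.fc1.params() + self.fc2.params())

    def forward(self, x: np.ndarray, bias: np.ndarray) -> np.ndarray:
        B, T, d = x.shape
        h1 = self.ln1.forward(x)
        qkv = self.qkv.forward(h1).reshape(B, T, 3, self.h, self.dh)
        q = qkv[:, :, 0].transpose(0, 2, 1, 3)  # (B, H, T, dh)
        k = qkv[:, :, 1].transpose(0, 2, 1, 3)
        v = qkv[:, :, 2].transpose(0, 2, 1, 3)
        logits = q @ k.swapaxes(-1, -2) / math.sqrt(self.dh) + bias[None]
        P = softmax(logits, axis=-1)
        o = (P @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
        x2 = x + self.proj.forward(o)
        h2 = self.ln2.forward(x2)
        a = self.fc1.forward(h2)
        x3 = x2 + self.fc2.forward(relu(a))
        self._cache = (q, k, v, P, a)
        return x3

    def backward(self, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (grad wrt input x, grad wrt attention bias)."""
        q, k, v, P, a = self._cache
        B, H, T, dh = q.shape
        gm = self.fc2.backward(g)
        gx2 = g + self.ln2.backward(self.fc1.backward(gm * relu_grad(a)))
        go = self.proj.backward(gx2).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        gP = go @ v.swapaxes(-1, -2)
        gv = P.swapaxes(-1, -2) @ go
        glogits = P * (gP - (gP * P).sum(axis=-1, keepdims=True))
        gbias = glogits.sum(axis=0)
        gq = glogits @ k / math.sqrt(dh)
        gk = glogits.swapaxes(-1, -2) @ q / math.sqrt(dh)
        gqkv = np.stack([gq, gk, gv], axis=2).transpose(0, 3, 2, 1, 4).reshape(B, T, 3 * H * dh)
        gx = gx2 + self.ln1.backward(self.qkv.backward(gqkv))
        return gx, gbias


class SudokuScoreNet:
    """Relational transformer score model for Sudoku grids.

    Each of the T = N^2 cells is a token carrying its k-dimensional
    simplex state; the binary relative positional encoding is projected
    by a linear layer to one bias per attention head and added to the
    attention logits before the softmax, so constraint structure enters
    every block. Digit identity enters only through the input embedding
    and the output head.
    """

    def __init__(self, n: int = 3, n_blocks: int = 20, d_model: int = 96,
                 heads: int = 4, rng: np.random.Generator | None = None):
        rng = np.random.default_rng(0) if rng is None else rng
        self.n = n
        self.k = n * n
        self.T = self.k * self.k
        self.rel = sudoku_rel_encoding(n)  # (T, T, 3k)
        self.embed = Linear(self.k, d_model, rng)
        self.time_proj = Linear(TIME_DIM, d_model, rng)
        self.rel_proj = Linear(3 * self.k, heads, rng)
        self.blocks = [_TransformerBlock(d_model, heads, rng) for _ in range(n_blocks)]
        self.ln_f = LayerNorm(d_model)
        self.head = Linear(d_model, self.k - 1, rng, scale=1e-2)
        self._cache = None

    def params(self):
        out = (self.embed.params() + self.time_proj.params() + self.rel_proj.params()
               + self.ln_f.params() + self.head.params())
        for b in self.blocks:
            out += b.params()
        return out

    def __call__(self, x, t, condition=None):
        x = np.asarray(x, dtype=float)
        B = x.shape[0]
        if x.shape[1:] != (self.T, self.k):
            raise ValueError(
                f"expected input shape (B, {self.T}, {self.k}), got {x.shape}"
            )
        tf = self.time_proj.forward(time_features(np.asarray(t, dtype=float), TIME_DIM))
        h = self.embed.forward(x) + tf[:, None, :]
        bias = self.rel_proj.forward(self.rel).transpose(2, 0, 1)  # (H, T, T)
        for b in self.blocks:
            h = b.forward(h, bias)
        hf = self.ln_f.forward(h)
        return self.head.forward(hf)

    def backward(self, grad):
        g = self.ln_f.backward(self.head.backward(grad))
        gbias = 0.0
        for b in reversed(self.blocks):
            g, gb = b.backward(g)
            gbias = gbias + gb
        self.rel_proj.backward(np.transpose(gbias, (1, 2, 0)))
        self.embed.backward(g)
        self.time_proj.backward(g.sum(axis=1))


class TimeScaledScore:
    """Multiply a network's output by a per-(time, stick-dim) scale.

    Transition scores grow like 1/t as t -> 0, spanning several orders
    of magnitude over the training time range; predicting the score in
    units of its typical magnitude (e.g. the cache's median |score| at
    each time) keeps the network's output O(1) and conditions the
    regression. Queried times snap to the nearest grid time.
    """

    def __init__(self, net, time_grid: np.ndarray, scale: np.ndarray):
        self.net = net
        self.time_grid = np.asarray(time_grid, dtype=float)
        self.scale = np.asarray(scale, dtype=float)  # (T, k-1)
        self._c: np.ndarray | None = None

    def params(self):
        return self.net.params()

    def __call__(self, x, t, condition=None):
        ti = np.abs(np.asarray(t, dtype=float)[:, None] - self.time_grid).argmin(1)
        c = self.scale[ti][:, None, :]
        self._c = c
        return self.net(x, t, condition) * c

    def backward(self, grad):
        self.net.backward(grad * self._c)


def build_sudoku_net(n: int = 3, n_blocks: int = 20, d_model: int = 96,
                     heads: int = 4, rng: np.random.Generator | None = None) -> SudokuScoreNet:
    """Relational transformer for (n^2 x n^2) Sudoku (default 20 blocks)."""
    return SudokuScoreNet(n=n, n_blocks=n_blocks, d_model=d_model, heads=heads, rng=rng)


def build_sequence_net(length: int, k: int = 4, conditional: bool = False,
                       width: int = 48, n_blocks: int = 4,
                       rng: np.random.Generator | None = None) -> SequenceScoreNet:
    """Convolutional sequence score net; ``length`` is informational."""
    del length  # fully convolutional: any length works
    return SequenceScoreNet(k=k, conditional=conditional, width=width,
                            n_blocks=n_blocks, rng=rng)
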