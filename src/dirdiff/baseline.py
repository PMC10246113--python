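"""Analytic position-factorized mixture score and residual score models.

For one-hot categorical data, the forward-diffusion marginal of a
*single* position is an exact, analytically computable mixture: with
prior category probabilities pi_c, the stick vector v of that position
has density

    p_t(v) = sum_c pi_c prod_j p_j(v_j | init_j(c), t) ,

where init_j(c) is 0, 1 or "stationary" according to the stick
structure of category c, and the factors are spectral Jacobi transition
densities or stationary Beta densities. The gradient of its log — the
*position-factorized mixture score* — is therefore available in closed
form; it is exact whenever positions are independent, and for
correlated data it is exact in the small-t limit (where a position's
own coordinates determine its category) and in the large-t limit
(stationarity). A score network then only needs to learn the
*cross-position* correction, which lives at intermediate diffusion
times; :class:`ResidualScoreModel` adds the network's output through a
smooth time window that is closed where the factorized score is already
exact. This decomposition is what makes CPU-scale training of strongly
constrained tasks (Sudoku) practical here.

Densities and scores are tabulated on a time grid x value grid at
construction and interpolated afterwards, so evaluation costs no
spectral sums.
"""

from __future__ import annotations

import numpy as np

from .jacobi import (
    stationary_log_density,
    stationary_score,
    transition_log_density,
    transition_score,
)
from .stick import StickBreakingSpec, sb_inverse

__all__ = ["FactorizedMixtureScore", "ResidualScoreModel", "time_window"]

#: Interior clamp for tabulated values (matches the cache's sample clamp).
TABLE_CLAMP = 1e-3


def _stick_code(k: int) -> np.ndarray:
    """code[c, j] in {0: init 0, 1: init 1, 2: stationary} per category."""
    code = np.empty((k, k - 1), dtype=int)
    for c in range(k):
        for j in range(k - 1):
            code[c, j] = 0 if j < c else (1 if j == c else 2)
    return code


class FactorizedMixtureScore:
    """Exact v-space score of the per-position forward mixture.

    Parameters
    ----------
    spec : StickBreakingSpec
    time_grid : array of times at which tables are built; queries snap
        to the nearest grid time.
    prior : (k,) category prior per position (default uniform). The
        empirical marginal of the training data is the natural choice.
    """

    def __init__(
        self,
        spec: StickBreakingSpec,
        time_grid: np.ndarray,
        prior: np.ndarray | None = None,
        n_v: int = 160,
    ):
        self.spec = spec
        self.time_grid = np.asarray(time_grid, dtype=float)
        k = spec.k
        prior = np.full(k, 1.0 / k) if prior is None else np.asarray(prior, float)
        if prior.shape != (k,) or np.any(prior < 0):
            raise ValueError("prior must be a length-k probability vector")
        self.log_prior = np.log(np.clip(prior / prior.sum(), 1e-300, None))
        self.code_onehot = np.eye(3)[_stick_code(k)]  # (k, k-1, 3)
        lo = TABLE_CLAMP / 2
        half = np.geomspace(lo, 0.5, n_v)
        self.v_grid = np.concatenate([half, 1.0 - half[::-1][1:]])
        T, J, V = len(self.time_grid), k - 1, len(self.v_grid)
        self._logd = np.empty((T, J, 3, V))
        self._score = np.empty((T, J, 3, V))
        for j, p in enumerate(spec.params):
            ls = stationary_log_density(p, self.v_grid)
            ss = stationary_score(p, self.v_grid)
            for ti, t in enumerate(self.time_grid):
                for init in (0, 1):
                    self._logd[ti, j, init] = transition_log_density(
                        p, float(init), self.v_grid, float(t)
                    )
                    self._score[ti, j, init] = transition_score(
                        p, float(init), self.v_grid, float(t)
                    )
                self._logd[ti, j, 2] = ls
                self._score[ti, j, 2] = ss

    def score_v(self, v: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Mixture score at stick points v (B, L, k-1), times t (B,)."""
        t_idx = np.abs(np.asarray(t, dtype=float)[:, None] - self.time_grid).argmin(1)
        out = np.empty_like(v)
        J = self.spec.k - 1
        for ti in np.unique(t_idx):
            sel = t_idx == ti
            vv = np.clip(v[sel], self.v_grid[0], self.v_grid[-1])
            ld = np.empty(vv.shape + (3,))
            sc = np.empty(vv.shape + (3,))
            for j in range(J):
                for c in range(3):
                    ld[..., j, c] = np.interp(vv[..., j], self.v_grid, self._logd[ti, j, c])
                    sc[..., j, c] = np.interp(vv[..., j], self.v_grid, self._score[ti, j, c])
            logw = np.einsum("bljc,kjc->blk", ld, self.code_onehot) + self.log_prior
            logw -= logw.max(-1, keepdims=True)
            w = np.exp(logw)
            w /= w.sum(-1, keepdims=True)
            out[sel] = np.einsum("blk,kjc,bljc->blj", w, self.code_onehot, sc)
        return out

    def __call__(self, x: np.ndarray, t: np.ndarray, condition=None) -> np.ndarray:
        v, _ = sb_inverse(np.asarray(x, dtype=float))
        v = np.clip(np.nan_to_num(v, nan=0.5), 1e-6, 1.0 - 1e-6)
        return self.score_v(v, t)

    # the baseline is parameter-free
    def params(self) -> list:
        return []

    def backward(self, grad) -> None:
        pass


def time_window(
    t: np.ndarray, lo: float = 0.12, hi: float = 3.0, ramp: float = 1.6
) -> np.ndarray:
    """Smooth gate in log time: 1 on [lo, hi], cosine ramp to 0 outside.

    ``ramp`` is the multiplicative width of each ramp (the gate reaches
    0 at lo/ramp and hi*ramp).
    """
    lt = np.log(np.clip(np.asarray(t, dtype=float), 1e-12, None))
    r = np.log(ramp)
    up = np.clip((lt - (np.log(lo) - r)) / r, 0.0, 1.0)
    dn = np.clip(((np.log(hi) + r) - lt) / r, 0.0, 1.0)
    return (0.5 - 0.5 * np.cos(np.pi * up)) * (0.5 - 0.5 * np.cos(np.pi * dn))


class ResidualScoreModel:
    """Factorized mixture baseline plus a time-gated learned residual.

    score(x, t) = baseline(x, t) + w(t) * net(x, t[, condition]),
    with w the smooth :func:`time_window`. Outside the window the model
    is exactly the analytic baseline, so the network trains (and acts)
    only at the intermediate times where cross-position structure
    matters.
    """

    def __init__(
        self,
        baseline: FactorizedMixtureScore,
        net,
        window: tuple[float, float] = (0.12, 3.0),
        ramp: float = 1.6,
    ):
        self.baseline = baseline
        self.net = net
        self.window = window
        self.ramp = ramp
        self._w: np.ndarray | None = None

    def params(self):
        return self.net.params()

    def __call__(self, x, t, condition=None):
        w = time_window(t, *self.window, self.ramp)[:, None, None]
        self._w = w
        return self.baseline(x, t) + w * self.net(x, t, condition)

    def backward(self, grad):
        self.net.backward(grad * self._w)
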