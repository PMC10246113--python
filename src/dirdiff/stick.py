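"""Stick-breaking coordinates for diffusion on the probability simplex.

A point ``x`` on the k-simplex is represented by k-1 stick coordinates
``v`` in [0, 1]^{k-1} through the classical stick-breaking construction

    x_1 = v_1,  x_2 = (1 - v_1) v_2,  ...,  x_k = prod_i (1 - v_i).

Running k-1 *independent* univariate Jacobi diffusions on the sticks
yields a multivariate diffusion on the simplex; choosing stationary laws
Beta(1, k-1), Beta(1, k-2), ..., Beta(1, 1) makes the stationary law of
``x`` the flat Dirichlet Dir(1, ..., 1). One-hot initial data occupy
simplex vertices: the inverse transform determines the leading sticks
(zeros then a single one) and leaves the remaining dimensions
*undetermined* — those stay at their stationary Beta law for all time
and never need to be simulated explicitly.

Score conventions. v-space scores are gradients of log-densities with
respect to ``v``. x-space scores are gradients with respect to the free
coordinates x_1 .. x_{k-1} (x_k is determined by the simplex
constraint). The two are related through the stick-breaking Jacobian
and the gradient of its log-determinant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .jacobi import (
    EPS_INTERIOR,
    JacobiParams,
    forward_sample_em,
    stationary_score,
    transition_score,
)

__all__ = [
    "StickBreakingSpec",
    "flat_spec",
    "sb_transform",
    "sb_inverse",
    "onehot_to_stick",
    "stick_jacobian",
    "log_det_jacobian",
    "score_v_to_x",
    "score_x_to_v",
    "sample_stationary_v",
    "forward_sample_multivariate",
]


@dataclass(frozen=True)
class StickBreakingSpec:
    """k categories and the k-1 Jacobi processes driving the sticks."""

    k: int
    params: tuple[JacobiParams, ...]

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 categories")
        if len(self.params) != self.k - 1:
            raise ValueError(
                f"expected {self.k - 1} Jacobi parameter sets for k={self.k}, "
                f"got {len(self.params)}"
            )

    @property
    def a(self) -> np.ndarray:
        return np.array([p.a for p in self.params])

    @property
    def b(self) -> np.ndarray:
        return np.array([p.b for p in self.params])

    @property
    def s(self) -> np.ndarray:
        return np.array([p.s for p in self.params])


def flat_spec(k: int, s: float = 1.0) -> StickBreakingSpec:
    """Spec whose stationary law on the simplex is Dir(1, ..., 1).

    Stick i (1-indexed) gets stationary Beta(1, k - i).
    """
    if k < 2:
        raise ValueError("need at least 2 categories")
    return StickBreakingSpec(
        k=k, params=tuple(JacobiParams(1.0, float(k - 1 - i), s) for i in range(k - 1))
    )


def sb_transform(v: np.ndarray) -> np.ndarray:
    """Stick coordinates (..., k-1) -> simplex point (..., k)."""
    v = np.asarray(v, dtype=float)
    one_minus = 1.0 - v
    # remaining stick length before each break, and after all breaks
    rem = np.concatenate(
        [np.ones_like(v[..., :1]), np.cumprod(one_minus, axis=-1)], axis=-1
    )
    x = np.concatenate([v * rem[..., :-1], rem[..., -1:]], axis=-1)
    return x


def sb_inverse(x: np.ndarray, tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Simplex point (..., k) -> (v, determined_mask), each (..., k-1).

    v_i = x_i / (remaining stick length). Once the stick is exhausted
    (remaining length <= tol, which happens right after a coordinate
    equal to the whole remainder, e.g. past the 1 of a one-hot vector),
    later dimensions are undetermined: their mask entry is False and
    their value is reported as NaN.
    """
    x = np.asarray(x, dtype=float)
    k = x.shape[-1]
    v = np.empty(x.shape[:-1] + (k - 1,))
    determined = np.empty(x.shape[:-1] + (k - 1,), dtype=bool)
    rem = np.ones(x.shape[:-1])
    for i in range(k - 1):
        ok = rem > tol
        determined[..., i] = ok
        with np.errstate(divide="ignore", invalid="ignore"):
            vi = np.where(ok, x[..., i] / np.where(ok, rem, 1.0), np.nan)
        v[..., i] = np.clip(vi, 0.0, 1.0) if np.all(ok) else vi
        rem = rem - x[..., i]
    np.clip(v, 0.0, 1.0, out=v, where=determined)
    return v, determined


def onehot_to_stick(categories: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Stick structure of one-hot data given category indices.

    For category c (0-based): v_j = 0 for j < c, v_c = 1 (when c < k-1),
    and dimensions j > c are undetermined. Returns (init_values,
    determined_mask), shapes (..., k-1); init_values is 0 where
    undetermined (unused there).
    """
    categories = np.asarray(categories)
    if np.any((categories < 0) | (categories >= k)):
        raise ValueError("category index out of range")
    j = np.arange(k - 1)
    c = categories[..., None]
    init = (j == c).astype(float)
    determined = j <= c
    return init, determined


def _check_interior_v(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any((v <= 0.0) | (v >= 1.0)):
        raise ValueError("stick coordinates must be strictly interior")
    return v


def stick_jacobian(v: np.ndarray) -> np.ndarray:
    """J = d x_{1..k-1} / d v, lower-triangular, shape (..., k-1, k-1)."""
    v = _check_interior_v(v)
    km1 = v.shape[-1]
    one_minus = 1.0 - v
    rem = np.concatenate(
        [np.ones_like(v[..., :1]), np.cumprod(one_minus, axis=-1)[..., :-1]], axis=-1
    )  # rem_i = prod_{j<i} (1 - v_j)
    J = np.zeros(v.shape[:-1] + (km1, km1))
    idx = np.arange(km1)
    J[..., idx, idx] = rem
    for i in range(km1):
        for j in range(i):
            J[..., i, j] = -v[..., i] * rem[..., i] / one_minus[..., j]
    return J


def log_det_jacobian(v: np.ndarray) -> np.ndarray:
    """log |det dx/dv| = sum_j (k-2-j) log(1 - v_j) (0-based j)."""
    v = _check_interior_v(v)
    km1 = v.shape[-1]
    expo = (km1 - 1) - np.arange(km1)  # = k-2-j for 0-based j
    return np.sum(expo * np.log1p(-v), axis=-1)


def _grad_log_det_inv(v: np.ndarray) -> np.ndarray:
    """d/dv log |det dv/dx| = + (k-2-j) / (1 - v_j) per dimension."""
    km1 = v.shape[-1]
    expo = (km1 - 1) - np.arange(km1)
    return expo / (1.0 - v)


def score_v_to_x(v: np.ndarray, score_v: np.ndarray) -> np.ndarray:
    """Convert a v-space score to the x-space score at x = sb_transform(v).

    Implements d log p_x / dx = (d log p_v / dv + d log|det dv/dx| / dv)
    (dv/dx), as a row vector times the inverse stick-breaking Jacobian.
    """
    v = _check_interior_v(v)
    score_v = np.asarray(score_v, dtype=float)
    J = stick_jacobian(v)
    rhs = score_v + _grad_log_det_inv(v)
    # row-vector solve: s_x J = rhs  <=>  J^T s_x^T = rhs^T
    return np.linalg.solve(np.swapaxes(J, -1, -2), rhs[..., None])[..., 0]


def score_x_to_v(v: np.ndarray, score_x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`score_v_to_x` (v identifies the point)."""
    v = _check_interior_v(v)
    score_x = np.asarray(score_x, dtype=float)
    J = stick_jacobian(v)
    sv = (score_x[..., None, :] @ J)[..., 0, :]
    return sv - _grad_log_det_inv(v)


def sample_stationary_v(
    spec: StickBreakingSpec, shape: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    """Independent stationary Beta draws for every stick, shape (*shape, k-1)."""
    out = np.empty(tuple(shape) + (spec.k - 1,))
    for j, p in enumerate(spec.params):
        out[..., j] = rng.beta(p.a, p.b, size=shape)
    return np.clip(out, EPS_INTERIOR, 1.0 - EPS_INTERIOR)


def forward_sample_multivariate(
    spec: StickBreakingSpec,
    x0: np.ndarray,
    t: float,
    rng: np.random.Generator,
    steps_per_unit: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Diffuse one-hot data to time ``t``; return (v_t, score_v).

    ``x0``: one-hot array (..., k). Determined stick dimensions are
    integrated by Euler-Maruyama from their 0/1 initial values and
    scored with the spectral transition score; undetermined dimensions
    are stationary for all time, so they are drawn from their Beta law
    and scored with the stationary Beta score.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape[-1] != spec.k:
        raise ValueError("x0 last axis must have length k")
    is_onehot = np.all(np.isin(x0, (0.0, 1.0))) and np.all(x0.sum(axis=-1) == 1.0)
    if not is_onehot:
        raise ValueError("forward diffusion for training starts from one-hot data only")
    cats = np.argmax(x0, axis=-1)
    init, determined = onehot_to_stick(cats, spec.k)
    v = np.empty(x0.shape[:-1] + (spec.k - 1,))
    score = np.empty_like(v)
    for j, p in enumerate(spec.params):
        det_j = determined[..., j]
        for x_init in (0.0, 1.0):
            sel = det_j & (init[..., j] == x_init)
            if not np.any(sel):
                continue
            draws = forward_sample_em(
                p, np.full(int(sel.sum()), x_init), t, rng=rng,
                steps_per_unit=steps_per_unit,
            )
            draws = np.clip(draws, EPS_INTERIOR, 1.0 - EPS_INTERIOR)
            v[..., j][sel] = draws
            score[..., j][sel] = transition_score(p, x_init, draws, t)
        und = ~det_j
        if np.any(und):
            draws = np.clip(
                rng.beta(p.a, p.b, size=int(und.sum())),
                EPS_INTERIOR, 1.0 - EPS_INTERIOR,
            )
            v[..., j][und] = draws
            score[..., j][und] = stationary_score(p, draws)
    return v, score
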