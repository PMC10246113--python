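"""Shared fixtures: small caches, exact-score oracles, and the two
trained models (Bernoulli toy and mini-Sudoku) reused across tests.

The exact-score oracles are built directly from the spectral transition
densities and play the role of ground truth for sampler and likelihood
tests; they are independent of the training pipeline they are used to
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from dirdiff.cache import build_cache
from dirdiff.jacobi import (
    stationary_log_density,
    stationary_score,
    transition_log_density,
    transition_score,
)
from dirdiff.stick import flat_spec, onehot_to_stick, sb_inverse


# ---------------------------------------------------------------------------
# oracles


class TwoCategoryMixtureScore:
    """Exact v-space score for i.i.d. 2-category data, P(category 1) = p1.

    Category 1 maps to stick init 0 and category 0 to init 1; the
    marginal density at time t is the corresponding two-component
    mixture of spectral transition densities, so its score is the
    posterior-weighted mix of the component scores. Serves as the
    ground-truth score field in sampler/likelihood tests.
    """

    def __init__(self, p1: float = 0.7, params=None):
        from dirdiff.jacobi import JacobiParams

        self.w0 = p1  # weight of init 0 (category 1)
        self.p = params or JacobiParams(1.0, 1.0, 1.0)

    def __call__(self, x, t, condition=None):
        v = np.clip(np.asarray(x)[..., 0], 1e-9, 1 - 1e-9)
        out = np.empty_like(v)
        for ti in np.unique(np.asarray(t, dtype=float)):
            sel = np.asarray(t) == ti
            vv = v[sel].ravel()
            l0 = transition_log_density(self.p, 0.0, vv, float(ti))
            l1 = transition_log_density(self.p, 1.0, vv, float(ti))
            s0 = transition_score(self.p, 0.0, vv, float(ti))
            s1 = transition_score(self.p, 1.0, vv, float(ti))
            d0 = self.w0 * np.exp(l0)
            d1 = (1.0 - self.w0) * np.exp(l1)
            out[sel] = ((d0 * s0 + d1 * s1) / (d0 + d1)).reshape(v[sel].shape)
        return out[..., None]

    def params(self):
        return []

    def backward(self, grad):
        pass


class GridMixtureScore:
    """Exact v-space score of a uniform mixture over a finite grid set.

    The data distribution is uniform over ``grids`` (B category arrays
    of shape (L,)); the diffused density factorizes per component over
    positions and stick dimensions, so the exact score is the
    posterior-weighted mixture of per-component transition /
    stationary scores.
    """

    def __init__(self, spec, category_arrays: np.ndarray):
        self.spec = spec
        cats = np.asarray(category_arrays)
        init, det = onehot_to_stick(cats, spec.k)
        code = np.where(det, init.astype(int), 2)
        self.C = np.eye(3)[code]  # (G, L, k-1, 3)

    def __call__(self, x, t, condition=None):
        v, _ = sb_inverse(np.asarray(x, dtype=float))
        v = np.clip(np.nan_to_num(v, nan=0.5), 1e-6, 1 - 1e-6)
        ti = float(np.asarray(t).ravel()[0])
        B, L, J = v.shape
        ld = np.empty(v.shape + (3,))
        sc = np.empty(v.shape + (3,))
        for j, p in enumerate(self.spec.params):
            vj = v[..., j].ravel()
            for c, x0 in enumerate((0.0, 1.0)):
                ld[..., j, c] = transition_log_density(p, x0, vj, ti).reshape(B, L)
                sc[..., j, c] = transition_score(p, x0, vj, ti).reshape(B, L)
            ld[..., j, 2] = stationary_log_density(p, vj).reshape(B, L)
            sc[..., j, 2] = stationary_score(p, vj).reshape(B, L)
        logw = np.einsum("bljc,gljc->bg", ld, self.C)
        logw -= logw.max(1, keepdims=True)
        w = np.exp(logw)
        w /= w.sum(1, keepdims=True)
        return np.einsum("bg,gljc,bljc->blj", w, self.C, sc)

    def params(self):
        return []

    def backward(self, grad):
        pass


def enumerate_mini_grids() -> np.ndarray:
    """All 288 valid 4x4 Sudoku grids, by exhaustive backtracking."""
    grids = []
    g = np.zeros((4, 4), dtype=int)

    def rec(i: int) -> None:
        if i == 16:
            grids.append(g.copy())
            return
        r, c = divmod(i, 4)
        used = (
            set(g[r, :c])
            | set(g[:r, c])
            | set(g[(r // 2) * 2:(r // 2) * 2 + 2, (c // 2) * 2:(c // 2) * 2 + 2].ravel())
        )
        for d in range(1, 5):
            if d not in used:
                g[r, c] = d
                rec(i + 1)
                g[r, c] = 0

    rec(0)
    return np.stack(grids)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def mini_grids():
    return enumerate_mini_grids()


@pytest.fixture(scope="session")
def toy_cache():
    """Small k=2 flat-spec cache shared by toy training tests."""
    spec = flat_spec(2)
    grid = np.geomspace(1e-2, 4.0, 40)
    return build_cache(spec, grid, n_per_cell=500, rng=1, steps_per_unit=400)


@pytest.fixture(scope="session")
def toy_model(toy_cache):
    """MLP score model trained on i.i.d. Bernoulli(0.7) positions.

    Used for end-to-end recovery and ELBO checks; ~2500 DSM steps.
    """
    from dirdiff.api import DirichletDiffusion
    from dirdiff.tasks import iid_categorical_batches

    rng = np.random.default_rng(2)
    data = iid_categorical_batches([0.3, 0.7], length=8, batch_size=64, rng=rng)
    model = DirichletDiffusion(
        data, k=2, length=8, seed=7, time_grid=toy_cache.time_grid
    )
    return model.fit(cache=toy_cache, n_steps=2500, lr=2e-3, batch_size=64)


@pytest.fixture(scope="session")
def sudoku_model(mini_grids):
    """Relational-transformer residual model trained on 4x4 Sudoku.

    The heavyweight fixture behind the generation/solving checks:
    k=4 flat-spec cache, factorized mixture baseline, 8000 DSM steps
    restricted to the time window where the baseline is inexact.
    """
    from dirdiff.api import DirichletDiffusion
    from dirdiff.tasks import grids_to_onehot

    spec_grid = np.geomspace(1e-2, 4.0, 50)
    cache = build_cache(
        flat_spec(4), spec_grid, n_per_cell=800, rng=3, steps_per_unit=400
    )
    onehot = grids_to_onehot(mini_grids)
    rng = np.random.default_rng(0)

    def batches():
        while True:
            yield onehot[rng.integers(len(onehot), size=96)]

    model = DirichletDiffusion(
        batches(), k=4, length=16, network="sudoku",
        factorized_baseline=True, seed=11, time_grid=spec_grid,
        net_options={"n_blocks": 3, "d_model": 48, "heads": 4},
    )
    window = tuple(np.nonzero((spec_grid >= 0.12) & (spec_grid <= 3.0))[0].tolist())
    return model.fit(
        cache=cache, n_steps=8000, lr=2.5e-3, batch_size=96,
        time_indices=window,
    )
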