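"""Pre-sampled dictionary of forward-diffusion samples and scores.

Training by denoising score matching needs, for every minibatch, draws
x_t ~ p(x_t | x_0) and the matching transition scores. Because one-hot
data place every stick coordinate at 0 or 1 (or at its stationary law),
only *two* starting points per univariate process ever occur, so the
forward simulation can be amortized: we pre-sample Euler-Maruyama
trajectories from 0 and 1 on a fixed time grid, score them once with
the spectral transition density, and draw from this dictionary during
training.

Storage is one HDF5 file per spec with layout

    /meta                       attrs: k, seed, steps_per_unit, created
    /params/a, /params/b, /params/s    (k-1,) process parameters
    /time_grid                  (T,) increasing times
    /proc_{j}/init_{0|1}/samples   (T, n_per_cell)
    /proc_{j}/init_{0|1}/scores    (T, n_per_cell)
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import h5py
import numpy as np

from .jacobi import (
    DEFAULT_T_MIN,
    EPS_INTERIOR,
    JacobiParams,
    forward_trajectory_em,
    stationary_score,
    transition_score,
)
from .stick import StickBreakingSpec, onehot_to_stick

__all__ = [
    "DiffusedSampleCache",
    "default_time_grid",
    "build_cache",
    "draw_minibatch",
    "DEFAULT_T_MAX",
]

#: Default diffusion horizon for unit-speed processes: the n=1 spectral
#: term of the slowest flat-spec process (a=1, b=1) decays as
#: exp(-t) and is below 2e-2 at t = 4.
DEFAULT_T_MAX = 4.0


def default_time_grid(
    t_min: float = DEFAULT_T_MIN, t_max: float = DEFAULT_T_MAX, n: int = 100
) -> np.ndarray:
    """Log-spaced grid of n training times in [t_min, t_max]."""
    return np.geomspace(t_min, t_max, n)


@dataclass
class DiffusedSampleCache:
    """In-memory dictionary of forward samples/scores from inits 0 and 1.

    ``samples[j][init]`` and ``scores[j][init]`` are (n_times,
    n_per_cell) arrays for stick process j.
    """

    spec: StickBreakingSpec
    time_grid: np.ndarray
    samples: list[dict[int, np.ndarray]]
    scores: list[dict[int, np.ndarray]]
    seed: int
    steps_per_unit: int

    @property
    def n_per_cell(self) -> int:
        return self.samples[0][0].shape[1]

    def score_scale(self) -> np.ndarray:
        """Median |transition score| per (time, stick dim), inits pooled.

        A robust magnitude profile of the regression targets (the
        scores grow like 1/t as t -> 0); used to normalize network
        outputs so the learned function stays O(1) across times.
        """
        T = len(self.time_grid)
        J = self.spec.k - 1
        out = np.empty((T, J))
        for j in range(J):
            pooled = np.concatenate([self.scores[j][0], self.scores[j][1]], axis=1)
            out[:, j] = np.median(np.abs(pooled), axis=1)
        return np.maximum(out, 1e-3)

    def time_index(self, t: np.ndarray) -> np.ndarray:
        """Snap times to nearest grid index."""
        return np.abs(np.asarray(t)[..., None] - self.time_grid).argmin(axis=-1)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["k"] = self.spec.k
            f.attrs["seed"] = self.seed
            f.attrs["steps_per_unit"] = self.steps_per_unit
            f.attrs["created"] = datetime.datetime.now(datetime.UTC).isoformat()
            g = f.create_group("params")
            g.create_dataset("a", data=self.spec.a)
            g.create_dataset("b", data=self.spec.b)
            g.create_dataset("s", data=self.spec.s)
            f.create_dataset("time_grid", data=self.time_grid)
            for j in range(self.spec.k - 1):
                for init in (0, 1):
                    gj = f.create_group(f"proc_{j}/init_{init}")
                    gj.create_dataset("samples", data=self.samples[j][init])
                    gj.create_dataset("scores", data=self.scores[j][init])

    @classmethod
    def load(cls, path) -> "DiffusedSampleCache":
        with h5py.File(path, "r") as f:
            k = int(f.attrs["k"])
            a, b, s = (np.asarray(f["params"][key]) for key in ("a", "b", "s"))
            spec = StickBreakingSpec(
                k=k,
                params=tuple(
                    JacobiParams(float(ai), float(bi), float(si))
                    for ai, bi, si in zip(a, b, s)
                ),
            )
            time_grid = np.asarray(f["time_grid"])
            samples, scores = [], []
            for j in range(k - 1):
                samples.append(
                    {init: np.asarray(f[f"proc_{j}/init_{init}/samples"]) for init in (0, 1)}
                )
                scores.append(
                    {init: np.asarray(f[f"proc_{j}/init_{init}/scores"]) for init in (0, 1)}
                )
            return cls(
                spec=spec,
                time_grid=time_grid,
                samples=samples,
                scores=scores,
                seed=int(f.attrs["seed"]),
                steps_per_unit=int(f.attrs["steps_per_unit"]),
            )


def build_cache(
    spec: StickBreakingSpec,
    time_grid: np.ndarray | None = None,
    n_per_cell: int = 1000,
    rng: np.random.Generator | int | None = None,
    steps_per_unit: int = 1000,
    interior: float = 1e-3,
) -> DiffusedSampleCache:
    """Simulate and score the forward dictionary.

    One EM pass per (process, init) produces jointly consistent
    snapshots at every grid time; scores come from the analytic
    spectral transition score at each snapshot. Stored samples are
    projected to the ``interior``-clamped interval before scoring: at
    small times the integrator can park samples essentially on the
    boundary, where the transition score blows up like 1/interior and
    would dominate every training batch; the projection caps target
    magnitudes at the cost of a negligible density distortion.
    Deterministic given the seed.
    """
    if time_grid is None:
        time_grid = default_time_grid()
    time_grid = np.asarray(time_grid, dtype=float)
    if np.any(time_grid < DEFAULT_T_MIN):
        raise ValueError(
            f"grid times below the spectral-validity floor {DEFAULT_T_MIN}"
        )
    if isinstance(rng, (int, np.integer)) or rng is None:
        seed = int(rng if rng is not None else np.random.SeedSequence().entropy % 2**31)
        rng = np.random.default_rng(seed)
    else:
        seed = -1
    samples: list[dict[int, np.ndarray]] = []
    scores: list[dict[int, np.ndarray]] = []
    for p in spec.params:
        s_j, sc_j = {}, {}
        for init in (0, 1):
            traj = forward_trajectory_em(
                p, np.full(n_per_cell, float(init)), time_grid, rng,
                steps_per_unit=steps_per_unit,
            )
            traj = np.clip(traj, interior, 1.0 - interior)
            sc = np.stack(
                [
                    transition_score(p, float(init), traj[i], float(t))
                    for i, t in enumerate(time_grid)
                ]
            )
            s_j[init], sc_j[init] = traj, sc
        samples.append(s_j)
        scores.append(sc_j)
    return DiffusedSampleCache(
        spec=spec,
        time_grid=time_grid,
        samples=samples,
        scores=scores,
        seed=seed,
        steps_per_unit=steps_per_unit,
    )


def draw_minibatch(
    cache: DiffusedSampleCache,
    data_batch: np.ndarray,
    t_batch: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble diffused v-samples and target scores for a data batch.

    ``data_batch``: one-hot array (B, L, k) (or (B, k)); ``t_batch``:
    (B,) times, snapped to the nearest grid point. Determined stick
    dimensions draw uniformly without replacement from the matching
    cache cell; undetermined dimensions draw fresh stationary Beta
    samples with the stationary score. Returns (v, score_v) of shape
    (B, L, k-1).
    """
    x = np.asarray(data_batch, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[:, None, :]
    B, L, k = x.shape
    if k != cache.spec.k:
        raise ValueError("data category count does not match cache spec")
    cats = np.argmax(x, axis=-1)
    init, determined = onehot_to_stick(cats, k)
    t_idx = cache.time_index(t_batch)
    v = np.empty((B, L, k - 1))
    score = np.empty((B, L, k - 1))
    n_cell = cache.n_per_cell
    for j, p in enumerate(cache.spec.params):
        und = ~determined[..., j]
        if np.any(und):
            draws = np.clip(
                rng.beta(p.a, p.b, size=int(und.sum())),
                EPS_INTERIOR, 1.0 - EPS_INTERIOR,
            )
            v[..., j][und] = draws
            score[..., j][und] = stationary_score(p, draws)
        for init_val in (0, 1):
            for ti in np.unique(t_idx):
                sel = determined[..., j] & (init[..., j] == init_val) & (t_idx[:, None] == ti)
                m = int(sel.sum())
                if m == 0:
                    continue
                if m > n_cell:
                    raise ValueError(
                        f"cache cell holds {n_cell} samples but {m} were requested"
                    )
                cols = rng.choice(n_cell, size=m, replace=False)
                v[..., j][sel] = cache.samples[j][init_val][ti, cols]
                score[..., j][sel] = cache.scores[j][init_val][ti, cols]
    if squeeze:
        v, score = v[:, 0], score[:, 0]
    return v, score
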