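"""Model / Results interface for simplex-diffusion generative modeling.

:class:`DirichletDiffusion` is constructed from one-hot categorical
sequence data (an array of examples or an iterator of batches), holds
the forward-diffusion specification, and :meth:`~DirichletDiffusion.fit`
runs denoising score matching to produce a
:class:`DiffusionResults`. The results object owns the trained score
field and exposes sampling (unconditional, time-dilated, inpainting),
likelihood estimation (probability-flow ODE and the discrete ELBO) and
a text summary.

Example
-------
>>> import numpy as np
>>> from dirdiff import DirichletDiffusion
>>> from dirdiff.tasks import iid_categorical_batches
>>> data = iid_categorical_batches([0.3, 0.7], length=8, batch_size=64,
...                                rng=np.random.default_rng(0))
>>> model = DirichletDiffusion(data, k=2, length=8, seed=0)
>>> res = model.fit(n_steps=500)
>>> cats = res.sample(100)[1]
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterator

import numpy as np

from .baseline import FactorizedMixtureScore, ResidualScoreModel
from .cache import DiffusedSampleCache, build_cache, default_time_grid
from .likelihood import LikelihoodConfig, discrete_elbo, ode_log_likelihood
from .networks import MLPScoreNet, SequenceScoreNet, SudokuScoreNet, TimeScaledScore
from .sampler import SamplerConfig, inpaint, sample
from .stick import StickBreakingSpec, flat_spec
from .training import TrainingConfig, load_params, save_params, train

__all__ = ["DirichletDiffusion", "DiffusionResults"]


def _as_batch_iterator(
    data, batch_size: int, rng: np.random.Generator
) -> Iterator:
    """Accept an (N, L, k) one-hot array or a batch iterator."""
    if hasattr(data, "__next__"):
        return data
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 3:
        raise ValueError("array data must be one-hot of shape (N, L, k)")

    def gen():
        while True:
            yield arr[rng.integers(len(arr), size=batch_size)]

    return gen()


class DirichletDiffusion:
    """Score-based diffusion generative model for k-category sequences.

    Parameters
    ----------
    data : (N, L, k) one-hot array, or an iterator yielding batches
        (optionally (batch, condition) tuples for conditional models).
    k : number of categories.
    length : sequence length (inferred from array data).
    network : "mlp" | "conv" | "sudoku" | a ScoreField instance.
        "mlp" treats positions independently (i.i.d. toys); "conv" is
        the dilated convolutional sequence net; "sudoku" the relational
        transformer (requires length == n**4 for some n).
    factorized_baseline : if True, wrap the network in a
        :class:`ResidualScoreModel` around the analytic
        position-factorized mixture score (recommended for strongly
        constrained tasks at CPU scale).
    spec : stick-breaking specification; defaults to the flat-Dirichlet
        preset for k categories.
    conditional : whether the network receives a per-position condition
        track.
    """

    def __init__(
        self,
        data,
        k: int,
        length: int | None = None,
        network: str | object = "mlp",
        factorized_baseline: bool = False,
        baseline_prior: np.ndarray | None = None,
        spec: StickBreakingSpec | None = None,
        conditional: bool = False,
        time_grid: np.ndarray | None = None,
        seed: int = 0,
        net_options: dict | None = None,
    ):
        self.k = int(k)
        if not hasattr(data, "__next__"):
            arr = np.asarray(data)
            if length is None and arr.ndim == 3:
                length = arr.shape[1]
            if arr.ndim == 3 and arr.shape[2] != self.k:
                raise ValueError("data last axis must have length k")
        if length is None:
            raise ValueError("length is required with iterator data")
        self.length = int(length)
        self.data = data
        self.spec = spec if spec is not None else flat_spec(self.k)
        if self.spec.k != self.k:
            raise ValueError("spec.k does not match k")
        self.conditional = conditional
        self.time_grid = (
            np.asarray(time_grid, float) if time_grid is not None else default_time_grid()
        )
        self.seed = int(seed)
        self.factorized_baseline = factorized_baseline
        self.baseline_prior = baseline_prior
        self._net_spec = network
        self.net_options = dict(net_options or {})

    # -- construction helpers -------------------------------------------------

    def _build_network(self, rng: np.random.Generator):
        if not isinstance(self._net_spec, str):
            return self._net_spec
        opts = self.net_options
        if self._net_spec == "mlp":
            return MLPScoreNet(self.k, hidden=opts.get("hidden", 64), rng=rng)
        if self._net_spec == "conv":
            return SequenceScoreNet(
                self.k,
                conditional=self.conditional,
                width=opts.get("width", 48),
                n_blocks=opts.get("n_blocks", 4),
                rng=rng,
            )
        if self._net_spec == "sudoku":
            n = int(round(self.length ** 0.25))
            if n ** 4 != self.length or n * n != self.k:
                raise ValueError(
                    "sudoku network requires length == n**4 and k == n**2"
                )
            return SudokuScoreNet(
                n=n,
                n_blocks=opts.get("n_blocks", 3),
                d_model=opts.get("d_model", 48),
                heads=opts.get("heads", 4),
                rng=rng,
            )
        raise ValueError(f"unknown network kind {self._net_spec!r}")

    def build_score_model(
        self,
        rng: np.random.Generator | None = None,
        cache: DiffusedSampleCache | None = None,
    ):
        """Network, wrapped with the factorized baseline or, for the
        convolutional sequence net, with per-time output scaling."""
        rng = rng or np.random.default_rng(self.seed + 1)
        net = self._build_network(rng)
        if self.factorized_baseline:
            base = FactorizedMixtureScore(
                self.spec, self.time_grid, prior=self.baseline_prior
            )
            return ResidualScoreModel(base, net)
        if self._net_spec == "conv" and cache is not None:
            return TimeScaledScore(net, cache.time_grid, cache.score_scale())
        return net

    # -- fitting --------------------------------------------------------------

    def fit(
        self,
        config: TrainingConfig | None = None,
        cache: DiffusedSampleCache | None = None,
        cache_n_per_cell: int = 800,
        cache_steps_per_unit: int = 400,
        **overrides,
    ) -> "DiffusionResults":
        """Train the score model by denoising score matching."""
        config = config or TrainingConfig(seed=self.seed)
        if overrides:
            config = replace(config, **overrides)
        if cache is None:
            cache = build_cache(
                self.spec,
                self.time_grid,
                n_per_cell=cache_n_per_cell,
                rng=self.seed + 17,
                steps_per_unit=cache_steps_per_unit,
            )
        rng = np.random.default_rng(self.seed)
        dataset = _as_batch_iterator(self.data, config.batch_size, rng)
        if self.factorized_baseline and self.baseline_prior is None:
            # estimate the per-position category prior from one batch
            item = next(dataset)
            batch = np.asarray(item[0] if isinstance(item, tuple) else item)
            self.baseline_prior = batch.reshape(-1, self.k).mean(axis=0)
        score_model = self.build_score_model(
            np.random.default_rng(self.seed + 1), cache=cache
        )
        losses = train(score_model, dataset, cache, config)
        return DiffusionResults(self, score_model, cache, losses, config)


class DiffusionResults:
    """Fitted score field plus sampling and likelihood machinery."""

    def __init__(self, model: DirichletDiffusion, score_model, cache, losses, config):
        self.model = model
        self.score_model = score_model
        self.cache = cache
        self.losses = list(losses)
        self.config = config

    # -- generation -----------------------------------------------------------

    def sample(
        self,
        n_samples: int,
        sampler: SamplerConfig | None = None,
        condition: np.ndarray | None = None,
        seed: int | None = None,
    ):
        """Reverse-diffusion samples: (simplex points, category array)."""
        sampler = sampler or SamplerConfig()
        rng = np.random.default_rng(self.model.seed + 1000 if seed is None else seed)
        return sample(
            self.score_model, self.model.spec, sampler, n_samples,
            self.model.length, rng, condition,
        )

    def inpaint(
        self,
        clamp_positions,
        clamp_values,
        n_samples: int,
        sampler: SamplerConfig | None = None,
        condition: np.ndarray | None = None,
        seed: int | None = None,
    ) -> np.ndarray:
        """Conditional samples with clamped positions (category array)."""
        sampler = sampler or SamplerConfig()
        rng = np.random.default_rng(self.model.seed + 2000 if seed is None else seed)
        return inpaint(
            self.score_model, self.model.spec, sampler, self.model.length,
            np.asarray(clamp_positions), np.asarray(clamp_values),
            n_samples, rng, condition,
        )

    # -- likelihood -----------------------------------------------------------

    def elbo(
        self,
        y: np.ndarray,
        config: LikelihoodConfig | None = None,
        n_mc: int = 8,
        t0_ladder=None,
        per_symbol_bits: bool = False,
        condition: np.ndarray | None = None,
        seed: int | None = None,
    ):
        """Discrete-data ELBO of a category sequence ``y``."""
        rng = np.random.default_rng(self.model.seed + 3000 if seed is None else seed)
        return discrete_elbo(
            self.score_model, y, self.model.spec, config, n_mc=n_mc,
            rng=rng, condition=condition, t0_ladder=t0_ladder,
            per_symbol_bits=per_symbol_bits,
        )

    def log_likelihood_v(self, v0, config=None, seed: int | None = None) -> float:
        """Continuous-space log-density of a v-state via the flow ODE."""
        rng = np.random.default_rng(self.model.seed + 4000 if seed is None else seed)
        return ode_log_likelihood(
            self.score_model, v0, self.model.spec, config, rng=rng
        )

    # -- bookkeeping ----------------------------------------------------------

    def save(self, path) -> None:
        save_params(self.score_model.params(), path)

    def load(self, path) -> None:
        load_params(self.score_model.params(), path)

    def summary(self) -> str:
        m = self.model
        n_params = sum(p.value.size for p in self.score_model.params())
        final = (
            f"{np.mean(self.losses[-50:]):.4f}" if self.losses else "untrained"
        )
        lines = [
            "Dirichlet diffusion score model",
            "=" * 34,
            f"categories (k):        {m.k}",
            f"sequence length:       {m.length}",
            f"stick processes:       {[(p.a, p.b) for p in m.spec.params]}",
            f"score model:           {type(self.score_model).__name__}"
            + (
                f" [{type(self.score_model.net).__name__} residual]"
                if isinstance(self.score_model, ResidualScoreModel)
                else ""
            ),
            f"trainable parameters:  {n_params}",
            f"training steps:        {len(self.losses)}"
            f"  (batch {self.config.batch_size}, lr {self.config.lr})",
            f"final loss (last-50 mean): {final}",
            f"time grid:             {len(self.cache.time_grid)} points in "
            f"[{self.cache.time_grid[0]:.3g}, {self.cache.time_grid[-1]:.3g}]",
        ]
        return "\n".join(lines)
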