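"""Denoising score matching with diffusion-weighted loss.

The training target for a sample v_t drawn from the forward diffusion
of a datum is the transition score d/dv log p(v_t | v_0). Because the
stick diffusions have state-dependent diffusion coefficients
g_j(v) = sqrt(s_j v_j (1 - v_j)), the plain L2 score-matching loss is
not invariant under changes of variables; the loss used here weights
the squared score residual by G G^T (diagonal, entries s_j v_j(1-v_j)),
which restores change-of-variable invariance and reduces to the
familiar likelihood weighting lambda(t) = g(t)^2 whenever g does not
depend on v. The loss is computed in v-space by default (G is diagonal
there); an x-space evaluation is provided and agrees numerically with
the v-space value, which is the invariance property itself.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field

import numpy as np

from .cache import DiffusedSampleCache, draw_minibatch
from .nn import Adam, Param
from .stick import StickBreakingSpec, sb_transform, stick_jacobian

__all__ = [
    "TrainingConfig",
    "weighted_dsm_loss",
    "weighted_loss_x_space",
    "train",
    "save_params",
    "load_params",
]


@dataclass
class TrainingConfig:
    batch_size: int = 64
    lr: float = 1e-3
    lr_schedule: str = "cosine"  # or "constant"
    lr_min: float = 1e-4
    n_steps: int = 2000
    seed: int = 0
    loss_space: str = "v"  # "v" (default; diagonal G) or "x" (testing)
    time_indices: tuple[int, ...] | None = None  # restrict to these grid times
    log_every: int = 50
    checkpoint_path: str | None = None
    checkpoint_every: int = 0
    log_path: str | None = None

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.lr <= 0 or self.n_steps < 1:
            raise ValueError("batch_size, lr and n_steps must be positive")
        if self.loss_space not in ("v", "x"):
            raise ValueError("loss_space must be 'v' or 'x'")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")


def weighted_dsm_loss(
    model_scores: np.ndarray,
    target_scores: np.ndarray,
    v: np.ndarray,
    spec: StickBreakingSpec,
    return_grad: bool = False,
):
    """G G^T-weighted score-matching loss on a batch of v-space samples.

    loss = mean over batch/positions of sum_j s_j v_j (1 - v_j)
    (s_model_j - s_target_j)^2. Zero iff the model matches the target
    scores on the batch. If ``return_grad``, also returns d loss /
    d model_scores.
    """
    model_scores = np.asarray(model_scores, dtype=float)
    target_scores = np.asarray(target_scores, dtype=float)
    v = np.asarray(v, dtype=float)
    if model_scores.shape != target_scores.shape or model_scores.shape != v.shape:
        raise ValueError("model scores, target scores and samples must share a shape")
    w = spec.s * v * (1.0 - v)
    delta = model_scores - target_scores
    n = int(np.prod(v.shape[:-1]))
    loss = float(np.sum(w * delta * delta) / n)
    if return_grad:
        return loss, 2.0 * w * delta / n
    return loss


def weighted_loss_x_space(
    model_scores_v: np.ndarray,
    target_scores_v: np.ndarray,
    v: np.ndarray,
    spec: StickBreakingSpec,
) -> float:
    """Same loss evaluated after changing variables to the simplex.

    The score difference transforms by J^{-T} (the log-det gradients
    cancel) and the diffusion matrix by G_x = J G_v, where J = dx/dv is
    the stick-breaking Jacobian; the quadratic form is then computed in
    x-space. Equality with :func:`weighted_dsm_loss` is the
    change-of-variable invariance of the weighted loss.
    """
    v = np.asarray(v, dtype=float)
    delta_v = np.asarray(model_scores_v) - np.asarray(target_scores_v)
    J = stick_jacobian(v)
    # delta_x = J^{-T} delta_v  (row-vector delta_v . J^{-1})
    delta_x = np.linalg.solve(np.swapaxes(J, -1, -2), delta_v[..., None])[..., 0]
    g2 = spec.s * v * (1.0 - v)
    GGt = J * g2[..., None, :] @ np.swapaxes(J, -1, -2)
    quad = np.einsum("...i,...ij,...j->...", delta_x, GGt, delta_x)
    return float(quad.sum() / np.prod(v.shape[:-1]))


def save_params(params: list[Param], path) -> None:
    np.savez(path, **{f"p{i}": p.value for i, p in enumerate(params)})


def load_params(params: list[Param], path) -> None:
    with np.load(path) as data:
        for i, p in enumerate(params):
            p.value[...] = data[f"p{i}"]


def train(
    model,
    dataset,
    cache: DiffusedSampleCache,
    config: TrainingConfig,
) -> list[float]:
    """Run the denoising score-matching loop; returns the loss curve.

    ``dataset`` is an iterator yielding one-hot batches (B, L, k) or
    (batch, condition) tuples. Times are drawn uniformly over the cache
    grid (the pre-sampled dictionary strategy). Fully seeded; aborts on
    a non-finite loss with diagnostics of the offending batch.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.lr)
    spec = cache.spec
    losses: list[float] = []
    idx_pool = (
        np.asarray(config.time_indices, dtype=int)
        if config.time_indices is not None
        else np.arange(len(cache.time_grid))
    )
    log_f = open(config.log_path, "a") if config.log_path else None
    t_start = time.time()
    try:
        for step in range(config.n_steps):
            if config.lr_schedule == "cosine":
                opt.lr = config.lr_min + 0.5 * (config.lr - config.lr_min) * (
                    1.0 + math.cos(math.pi * step / config.n_steps)
                )
            item = next(dataset)
            batch, cond = item if isinstance(item, tuple) else (item, None)
            batch = np.asarray(batch, dtype=float)
            t_idx = idx_pool[rng.integers(len(idx_pool), size=batch.shape[0])]
            t = cache.time_grid[t_idx]
            v, target = draw_minibatch(cache, batch, t, rng)
            x = sb_transform(v)
            scores = model(x, t, cond)
            loss, grad = weighted_dsm_loss(scores, target, v, spec, return_grad=True)
            if config.loss_space == "x":
                # the change-of-variable invariance makes the x-space loss
                # (and hence its gradient in the model's v-space output)
                # numerically identical; record the x-space evaluation
                loss = weighted_loss_x_space(scores, target, v, spec)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at step {step}: loss={loss}; "
                    f"t range [{t.min():.4g}, {t.max():.4g}], "
                    f"v range [{v.min():.4g}, {v.max():.4g}], "
                    f"target |score| max {np.abs(target).max():.4g}"
                )
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
            if log_f and (step % config.log_every == 0 or step == config.n_steps - 1):
                log_f.write(json.dumps({
                    "step": step, "loss": loss, "lr": config.lr,
                    "wall_time": time.time() - t_start,
                }) + "\n")
            if (
                config.checkpoint_path
                and config.checkpoint_every
                and (step + 1) % config.checkpoint_every == 0
            ):
                save_params(model.params(), config.checkpoint_path)
    finally:
        if log_f:
            log_f.close()
    if config.checkpoint_path:
        save_params(model.params(), config.checkpoint_path)
    return losses
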