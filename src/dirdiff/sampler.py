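"""Reverse-time SDE sampling on the simplex, with time dilation and
inpainting.

Each stick coordinate follows the time-reversal of its Jacobi
diffusion,

    dv = { (s/2)[a(1-v) - bv] - s(1-2v) - s v(1-v) score } dt
         + sqrt(s v (1-v)) dw_bar ,

with the trained score model substituted for the true v-space score.
Integration runs from the horizon T down to a small cutoff time using
Euler-Maruyama with interior clamping; initial states are exact
stationary Dirichlet draws via stick-breaking, so no burn-in is needed.

Time dilation (factor c >= 1) is implemented on a stretched clock: c
times as many full-size SDE integration steps are spent per unit of
model time, so the state equilibrates more thoroughly toward the
sharpening intermediate densities and terminal samples concentrate near
high-density regions. With a flat stationary law this biases samples
toward modes without retraining; c = 1 recovers unbiased sampling.

Conditional generation uses the inpainting rule: at every reverse step,
clamped positions are overwritten with forward-diffused versions of
their fixed one-hot values at the current model time (pre-simulated as
consistent forward trajectories), while free positions follow the
reverse SDE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cache import DEFAULT_T_MAX
from .jacobi import DEFAULT_T_MIN, EPS_INTERIOR, forward_trajectory_em
from .stick import (
    StickBreakingSpec,
    onehot_to_stick,
    sample_stationary_v,
    sb_transform,
)

__all__ = ["SamplerConfig", "reverse_step", "reverse_drift", "sample", "inpaint", "discretize"]


@dataclass
class SamplerConfig:
    n_steps: int = 100
    time_dilation: int = 1
    t_start: float = DEFAULT_T_MAX
    t_end: float = DEFAULT_T_MIN
    discretization: str = "argmax"  # or "categorical"
    schedule: str = "log"  # or "linear"

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.time_dilation < 1:
            raise ValueError("time_dilation must be >= 1")
        if not 0 < self.t_end < self.t_start:
            raise ValueError("need 0 < t_end < t_start")
        if self.discretization not in ("argmax", "categorical"):
            raise ValueError("discretization must be 'argmax' or 'categorical'")
        if self.schedule not in ("log", "linear"):
            raise ValueError("schedule must be 'log' or 'linear'")


def reverse_drift(
    v: np.ndarray, score_v: np.ndarray, spec: StickBreakingSpec
) -> np.ndarray:
    """Drift of the reverse SDE per stick dimension (see module docs)."""
    a, b, s = spec.a, spec.b, spec.s
    return 0.5 * s * (a * (1.0 - v) - b * v) - s * (1.0 - 2.0 * v) - s * v * (1.0 - v) * score_v


def reverse_step(
    v: np.ndarray,
    score_v: np.ndarray,
    spec: StickBreakingSpec,
    dt: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """One Euler-Maruyama step of the reverse SDE toward smaller time.

    ``dt > 0`` is the step magnitude; ``rng=None`` gives the zero-noise
    (pure drift) variant. Output is clamped to the eps-interior.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    drift = reverse_drift(v, score_v, spec)
    new = v - drift * dt
    if rng is not None:
        g = np.sqrt(np.clip(spec.s * v * (1.0 - v), 0.0, None) * dt)
        new = new + g * rng.standard_normal(v.shape)
    return np.clip(new, EPS_INTERIOR, 1.0 - EPS_INTERIOR)


def discretize(
    x: np.ndarray, rule: str = "argmax", rng: np.random.Generator | None = None
) -> np.ndarray:
    """Convert simplex points (..., k) to category indices.

    ``argmax`` is deterministic; ``categorical`` treats x as the
    parameter of a categorical emission and draws from it.
    """
    if rule == "argmax":
        return np.argmax(x, axis=-1)
    if rule == "categorical":
        if rng is None:
            raise ValueError("categorical discretization needs an rng")
        p = np.clip(x, 0.0, None)
        p = p / p.sum(axis=-1, keepdims=True)
        u = rng.random(p.shape[:-1] + (1,))
        return (np.cumsum(p, axis=-1) < u).sum(axis=-1)
    raise ValueError(f"unknown discretization rule {rule!r}")


def _reverse_times(config: SamplerConfig) -> tuple[np.ndarray, np.ndarray]:
    """Model-time schedule and SDE step sizes under time dilation.

    Returns (model times at which the score is evaluated, SDE step
    size per sub-step). Total sub-steps are n_steps * c: model time
    advances 1/c as fast as the SDE clock, so c times as many
    integration steps are spent per unit of model time. The default
    "log" schedule shrinks steps proportionally to t, matching the
    ~1/t growth of transition scores as t -> 0; "linear" uses constant
    steps.
    """
    c = config.time_dilation
    n_total = config.n_steps * c
    if config.schedule == "log":
        grid = np.geomspace(config.t_start, config.t_end, n_total + 1)
    else:
        grid = np.linspace(config.t_start, config.t_end, n_total + 1)
    dt_sde = c * (grid[:-1] - grid[1:])
    return grid[:-1], dt_sde


def _integrate(
    model,
    spec: StickBreakingSpec,
    config: SamplerConfig,
    n_samples: int,
    length: int,
    rng: np.random.Generator,
    condition: np.ndarray | None = None,
    clamp_mask: np.ndarray | None = None,
    clamp_traj: np.ndarray | None = None,
) -> np.ndarray:
    times, dt_sde = _reverse_times(config)
    v = sample_stationary_v(spec, (n_samples, length), rng)
    for i, t in enumerate(times):
        if clamp_mask is not None:
            # permuting the trajectory bank decorrelates clamp states
            # across steps (fresh q_t draws, as in standard SDE
            # inpainting), which measurably improves completions
            v[:, clamp_mask, :] = clamp_traj[i][rng.permutation(n_samples)]
        x = sb_transform(v)
        score = model(x, np.full(n_samples, t), condition)
        if not np.all(np.isfinite(score)):
            raise FloatingPointError(
                f"non-finite score at reverse step {i} (model time {t:.4g})"
            )
        v = reverse_step(v, score, spec, float(dt_sde[i]), rng)
    if clamp_mask is not None:
        v[:, clamp_mask, :] = clamp_traj[-1]
    return v


def sample(
    model,
    spec: StickBreakingSpec,
    config: SamplerConfig,
    n_samples: int,
    length: int,
    rng: np.random.Generator,
    condition: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Unconditional (or track-conditioned) sampling.

    Returns (x, categories): terminal simplex points (n_samples,
    length, k) and discretized categories (n_samples, length).
    """
    v = _integrate(model, spec, config, n_samples, length, rng, condition)
    x = sb_transform(v)
    return x, discretize(x, config.discretization, rng)


def _clamp_trajectories(
    spec: StickBreakingSpec,
    clamp_values: np.ndarray,
    times_desc: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    steps_per_unit: int = 200,
) -> np.ndarray:
    """Forward-diffused stick states of the clamped one-hot values.

    Simulated once as consistent EM trajectories, snapshotted at the
    reverse schedule's model times; returns array of shape
    (n_times, n_samples, n_clamped, k-1) ordered like ``times_desc``
    (descending model time).
    """
    times_asc = times_desc[::-1]
    n_clamp = len(clamp_values)
    init, determined = onehot_to_stick(np.asarray(clamp_values), spec.k)
    out = np.empty((len(times_asc), n_samples, n_clamp, spec.k - 1))
    for j, p in enumerate(spec.params):
        x0 = np.empty((n_samples, n_clamp))
        det_j = determined[:, j]
        x0[:, det_j] = init[det_j, j]
        # undetermined dims are stationary: start from a Beta draw
        n_und = int((~det_j).sum())
        if n_und:
            x0[:, ~det_j] = rng.beta(p.a, p.b, size=(n_samples, n_und))
        traj = forward_trajectory_em(
            p, x0.ravel(), times_asc, rng, steps_per_unit=steps_per_unit
        ).reshape(len(times_asc), n_samples, n_clamp)
        out[..., j] = traj
    return np.clip(out[::-1], EPS_INTERIOR, 1.0 - EPS_INTERIOR)


def inpaint(
    model,
    spec: StickBreakingSpec,
    config: SamplerConfig,
    length: int,
    clamp_positions: np.ndarray,
    clamp_values: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    condition: np.ndarray | None = None,
) -> np.ndarray:
    """Conditional sampling with clamped positions; returns categories.

    Clamped positions follow pre-simulated forward diffusions of their
    one-hot values at every reverse model time; free positions follow
    the reverse SDE. After discretization the clamped positions equal
    the clamp values exactly.
    """
    clamp_positions = np.asarray(clamp_positions, dtype=int)
    clamp_values = np.asarray(clamp_values, dtype=int)
    if clamp_positions.shape != clamp_values.shape:
        raise ValueError("clamp positions and values must align")
    if len(np.unique(clamp_positions)) != len(clamp_positions):
        raise ValueError("duplicate clamp positions are contradictory")
    if np.any((clamp_positions < 0) | (clamp_positions >= length)):
        raise ValueError("clamp position out of range")
    if np.any((clamp_values < 0) | (clamp_values >= spec.k)):
        raise ValueError("clamp value out of range")
    mask = np.zeros(length, dtype=bool)
    mask[clamp_positions] = True
    order = np.argsort(clamp_positions)
    times, _ = _reverse_times(config)
    traj = _clamp_trajectories(spec, clamp_values[order], times, n_samples, rng)
    v = _integrate(
        model, spec, config, n_samples, length, rng, condition,
        clamp_mask=mask, clamp_traj=traj,
    )
    x = sb_transform(v)
    cats = discretize(x, config.discretization, rng)
    cats[:, clamp_positions] = clamp_values
    return cats
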