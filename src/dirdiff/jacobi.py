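"""Univariate Jacobi diffusion on the unit interval.

The process solves the Itô SDE

    dx = (s/2) [a (1 - x) - b x] dt + sqrt(s x (1 - x)) dw ,

with speed factor ``s > 0`` and shape parameters ``a, b > 0``. Its
stationary law is Beta(a, b): near the boundaries the diffusion
coefficient vanishes while the drift points inward, so trajectories are
confined to [0, 1]. The transition density has a classical spectral
expansion in modified Jacobi polynomials, which this module evaluates
together with its analytic x-derivative (the transition *score* used as
the regression target in denoising score matching).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, eval_jacobi, gammaln

__all__ = [
    "JacobiParams",
    "SpectralExpansion",
    "stationary_log_density",
    "stationary_score",
    "eigenvalue",
    "jacobi_poly",
    "jacobi_poly_deriv",
    "log_dn",
    "transition_log_density",
    "transition_score",
    "forward_sample_em",
    "forward_trajectory_em",
    "DEFAULT_T_MIN",
    "EPS_INTERIOR",
]

#: Lower time cutoff below which the spectral series is not evaluated
#: (it converges slowly as t -> 0); matches the likelihood module's
#: default lower integration time.
DEFAULT_T_MIN = 1e-2

#: Defensive interior clamp used by the Euler-Maruyama integrators.
EPS_INTERIOR = 1e-6

#: Floor applied to truncated densities before taking logs.
DENSITY_FLOOR = 1e-40


@dataclass(frozen=True)
class JacobiParams:
    """Parameters (a, b, s) of one univariate Jacobi diffusion.

    ``a`` and ``b`` fix the stationary Beta(a, b) law (stationary mean
    a / (a + b)); ``s`` is a pure time rescaling of the process.
    """

    a: float
    b: float
    s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.s > 0):
            raise ValueError(
                f"JacobiParams requires a, b, s > 0; got a={self.a}, b={self.b}, s={self.s}"
            )

    @property
    def stationary_mean(self) -> float:
        return self.a / (self.a + self.b)

    def with_speed_preset(self, preset: str) -> "JacobiParams":
        """Return a copy with ``s`` set by a named preset.

        ``"unit"`` is s = 1. ``"inv-sum"`` sets s = 2 / (a + b), one
        reading of the ambiguous alternative convention; the speed
        factor is deliberately a free parameter and any positive value
        is valid.
        """
        if preset == "unit":
            return JacobiParams(self.a, self.b, 1.0)
        if preset == "inv-sum":
            return JacobiParams(self.a, self.b, 2.0 / (self.a + self.b))
        raise ValueError(f"unknown speed preset {preset!r}")


def _check_unit_interval(x: np.ndarray | float, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError(f"{name} must lie in [0, 1]")
    return x


def stationary_log_density(params: JacobiParams, x) -> np.ndarray | float:
    """Log of the stationary Beta(a, b) density at ``x``."""
    x = _check_unit_interval(x)
    a, b = params.a, params.b
    with np.errstate(divide="ignore"):
        out = (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - betaln(a, b)
    return out if out.ndim else float(out)


def stationary_score(params: JacobiParams, x) -> np.ndarray | float:
    """d/dx log Beta(a,b) density: (a-1)/x - (b-1)/(1-x)."""
    x = np.asarray(x, dtype=float)
    out = (params.a - 1.0) / x - (params.b - 1.0) / (1.0 - x)
    return out if out.ndim else float(out)


def eigenvalue(n: int, params: JacobiParams) -> float:
    """Generator eigenvalue lambda_n = -(s/2) n (n - 1 + a + b)."""
    if n < 0:
        raise ValueError("polynomial order n must be >= 0")
    return -0.5 * params.s * n * (n - 1.0 + params.a + params.b)


def jacobi_poly(n: int, params: JacobiParams, x) -> np.ndarray | float:
    """Modified Jacobi polynomial R_n on [0, 1].

    R_n(x) = P_n^{(b-1, a-1)}(2x - 1) in terms of the classical Jacobi
    polynomials; the family is orthogonal under the Beta(a, b) weight
    and R_n is an exact eigenfunction of the diffusion generator with
    eigenvalue lambda_n. R_0 is identically 1.
    """
    if n < 0:
        raise ValueError("polynomial order n must be >= 0")
    x = np.asarray(x, dtype=float)
    out = eval_jacobi(n, params.b - 1.0, params.a - 1.0, 2.0 * x - 1.0)
    out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


def jacobi_poly_deriv(n: int, params: JacobiParams, x) -> np.ndarray | float:
    """d/dx R_n(x) = (n + a + b - 1) P_{n-1}^{(b, a)}(2x - 1)."""
    if n < 0:
        raise ValueError("polynomial order n must be >= 0")
    x = np.asarray(x, dtype=float)
    if n == 0:
        out = np.zeros_like(x)
    else:
        out = (n + params.a + params.b - 1.0) * eval_jacobi(
            n - 1, params.b, params.a, 2.0 * x - 1.0
        )
        out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


def log_dn(n: int, params: JacobiParams) -> float:
    """Log of the expansion coefficient d_n = 1 / <R_n, R_n>_{Beta(a,b)}.

    Closed form from the Jacobi-polynomial norm; d_0 = 1.
    """
    if n == 0:
        return 0.0
    a, b = params.a, params.b
    return (
        gammaln(a)
        + gammaln(b)
        - gammaln(a + b)
        + math.log(2.0 * n + a + b - 1.0)
        + gammaln(n + a + b - 1.0)
        + gammaln(n + 1.0)
        - gammaln(n + a)
        - gammaln(n + b)
    )


def _poly_matrix(params: JacobiParams, orders: np.ndarray, x: np.ndarray) -> np.ndarray:
    """R_n(x) for every n in ``orders``; shape (len(orders),) + x.shape."""
    return eval_jacobi(
        orders.reshape(orders.shape + (1,) * np.ndim(x)),
        params.b - 1.0,
        params.a - 1.0,
        2.0 * np.asarray(x, dtype=float) - 1.0,
    )


def _poly_deriv_matrix(params: JacobiParams, orders: np.ndarray, x: np.ndarray) -> np.ndarray:
    """R_n'(x) for every n in ``orders``."""
    x = np.asarray(x, dtype=float)
    n = orders.reshape(orders.shape + (1,) * np.ndim(x)).astype(float)
    out = (n + params.a + params.b - 1.0) * eval_jacobi(
        np.maximum(n - 1, 0), params.b, params.a, 2.0 * x - 1.0
    )
    return np.where(n == 0, 0.0, out)


@dataclass
class SpectralExpansion:
    """Truncated spectral expansion of the transition density.

    Holds, for one parameter set, the eigenvalues, coefficients d_n and
    endpoint bounds on |R_n| used by the adaptive truncation rule:
    at time t, terms are kept while exp(lambda_n t) d_n max|R_n|^2
    >= ``tol``, up to ``max_terms``. One expansion built at the floor
    time serves all larger times (fewer terms are simply used).
    """

    params: JacobiParams
    n_terms: int
    eigenvalues: np.ndarray = field(repr=False)
    dn: np.ndarray = field(repr=False)
    r_end2: np.ndarray = field(repr=False)
    tol: float = 1e-8

    @classmethod
    def build(
        cls, params: JacobiParams, t: float, tol: float = 1e-8, max_terms: int = 200
    ) -> "SpectralExpansion":
        """Choose the truncation order adequate for time ``t``."""
        if t <= 0:
            raise ValueError("t must be positive")
        orders = np.arange(max_terms + 1)
        lams = np.array([eigenvalue(n, params) for n in orders])
        dns = np.exp([log_dn(n, params) for n in orders])
        # |R_n| on [0,1] is bounded by its endpoint values for a,b >= 1/2
        r_end2 = np.maximum(
            np.abs(_poly_matrix(params, orders, np.array(0.0))),
            np.abs(_poly_matrix(params, orders, np.array(1.0))),
        ) ** 2
        bounds = np.exp(lams * t) * dns * r_end2
        keep = np.nonzero(bounds >= tol)[0]
        n_terms = int(keep.max()) + 1 if len(keep) else 1
        n_terms = max(n_terms, 3)
        return cls(
            params=params,
            n_terms=n_terms,
            eigenvalues=lams[:n_terms],
            dn=dns[:n_terms],
            r_end2=r_end2[:n_terms],
            tol=tol,
        )

    def n_for_t(self, t: float) -> int:
        """Terms needed at time ``t`` (monotone decreasing in t)."""
        bounds = np.exp(self.eigenvalues * t) * self.dn * self.r_end2
        keep = np.nonzero(bounds >= self.tol)[0]
        return max(int(keep.max()) + 1 if len(keep) else 1, 3)


_EXPANSION_CACHE: dict[tuple, SpectralExpansion] = {}


def _get_expansion(params: JacobiParams, t: float) -> SpectralExpansion:
    """Cached expansion per parameter set, built once at the floor time."""
    key = (params.a, params.b, params.s)
    exp = _EXPANSION_CACHE.get(key)
    if exp is None:
        exp = SpectralExpansion.build(params, min(t, DEFAULT_T_MIN))
        _EXPANSION_CACHE[key] = exp
    return exp


def _series_terms(
    params: JacobiParams, expansion: SpectralExpansion, x0: float, xt: np.ndarray, t: float
):
    """exp(lambda_n t) d_n R_n(x0) for needed n, and R_n(xt)."""
    N = min(expansion.n_for_t(t), expansion.n_terms)
    orders = np.arange(N)
    w = np.exp(expansion.eigenvalues[:N] * t) * expansion.dn[:N]
    r0 = _poly_matrix(params, orders, np.array(float(x0)))
    rt = _poly_matrix(params, orders, xt)
    return w * r0, rt


def transition_log_density(
    params: JacobiParams,
    x0: float,
    xt,
    t: float,
    expansion: SpectralExpansion | None = None,
) -> np.ndarray | float:
    """Log transition density log p(x_t | x_0) by spectral expansion.

    p(x_t | x_0) = B_{a,b}(x_t) * [1 + sum_{n>=1} e^{lambda_n t} d_n
    R_n(x_0) R_n(x_t)]. Truncation can make the series slightly
    negative for small t; values are floored at a tiny positive
    constant (with a warning when the negativity is material).
    """
    if t <= 0:
        raise ValueError("t must be positive")
    if t < DEFAULT_T_MIN:
        raise ValueError(
            f"t={t} is below the spectral-validity floor {DEFAULT_T_MIN}; "
            "the truncated series is unreliable there"
        )
    xt_arr = _check_unit_interval(np.asarray(xt, dtype=float), "xt")
    scalar = xt_arr.ndim == 0
    xt_arr = np.atleast_1d(xt_arr)
    if expansion is None:
        expansion = _get_expansion(params, t)
    coef, rt = _series_terms(params, expansion, float(x0), xt_arr, t)
    series = coef @ rt  # 1 + sum_{n>=1} ... (n=0 term is exactly 1)
    dens = np.exp(stationary_log_density(params, np.clip(xt_arr, 1e-300, 1.0 - 1e-16))) * series
    if np.any(series < -1e-3):
        warnings.warn(
            "spectral transition density truncated series went materially "
            f"negative (min {series.min():.3g}); clamping",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.log(np.clip(dens, DENSITY_FLOOR, None))
    return float(out[0]) if scalar else out


def transition_score(
    params: JacobiParams,
    x0: float,
    xt,
    t: float,
    expansion: SpectralExpansion | None = None,
) -> np.ndarray | float:
    """Analytic d/dx_t log p(x_t | x_0).

    Sum of the stationary Beta score and the logarithmic derivative of
    the truncated series; agrees with central finite differences of
    :func:`transition_log_density` on interior points.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    xt_arr = np.asarray(xt, dtype=float)
    scalar = xt_arr.ndim == 0
    xt_arr = np.atleast_1d(xt_arr)
    if np.any((xt_arr <= 0.0) | (xt_arr >= 1.0)):
        raise ValueError("transition score diverges at the boundary; xt must be interior")
    if expansion is None:
        expansion = _get_expansion(params, t)
    coef, rt = _series_terms(params, expansion, float(x0), xt_arr, t)
    drt = _poly_deriv_matrix(params, np.arange(len(coef)), xt_arr)
    series = coef @ rt
    dseries = coef @ drt
    series = np.where(np.abs(series) < 1e-12, 1e-12, series)
    out = stationary_score(params, xt_arr) + dseries / series
    return float(out[0]) if scalar else out


def _em_steps(params: JacobiParams, x, dt: float, noise: np.ndarray) -> np.ndarray:
    a, b, s = params.a, params.b, params.s
    drift = 0.5 * s * (a * (1.0 - x) - b * x)
    diff = np.sqrt(np.clip(s * x * (1.0 - x), 0.0, None) * dt)
    return np.clip(x + drift * dt + diff * noise, EPS_INTERIOR, 1.0 - EPS_INTERIOR)


def forward_sample_em(
    params: JacobiParams,
    x0,
    t: float,
    n_steps: int | None = None,
    rng: np.random.Generator | None = None,
    steps_per_unit: int = 1000,
) -> np.ndarray | float:
    """Euler-Maruyama endpoint of the forward diffusion after time ``t``.

    ``x0`` may be a scalar or an array (independent trajectories). Each
    intermediate state is clamped to the eps-interior of [0, 1]; the
    output is deterministic given ``rng``'s seed.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_steps is None:
        n_steps = max(1, int(math.ceil(steps_per_unit * t)))
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    x = np.atleast_1d(_check_unit_interval(x0, "x0")).astype(float).copy()
    scalar = np.ndim(x0) == 0
    dt = t / n_steps
    for _ in range(n_steps):
        x = _em_steps(params, x, dt, rng.standard_normal(x.shape))
    return float(x[0]) if scalar else x


def forward_trajectory_em(
    params: JacobiParams,
    x0,
    times,
    rng: np.random.Generator,
    steps_per_unit: int = 1000,
) -> np.ndarray:
    """EM snapshots of independent trajectories at increasing ``times``.

    Returns an array of shape (len(times),) + shape(x0); a single pass
    of the integrator, so the snapshots are jointly consistent states
    of the same trajectories.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0) or times[0] <= 0:
        raise ValueError("times must be strictly increasing and positive")
    x = np.atleast_1d(_check_unit_interval(x0, "x0")).astype(float).copy()
    out = np.empty((len(times),) + x.shape)
    t_prev = 0.0
    for i, t in enumerate(times):
        span = t - t_prev
        n_steps = max(1, int(math.ceil(steps_per_unit * span)))
        dt = span / n_steps
        for _ in range(n_steps):
            x = _em_steps(params, x, dt, rng.standard_normal(x.shape))
        out[i] = x
        t_prev = t
    return out
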