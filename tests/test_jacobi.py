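"""Univariate Jacobi diffusion: stationary law, spectrum, transition
density and Euler-Maruyama simulation."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import beta as beta_dist, kstest

from dirdiff.jacobi import (
    JacobiParams,
    SpectralExpansion,
    eigenvalue,
    forward_sample_em,
    forward_trajectory_em,
    jacobi_poly,
    jacobi_poly_deriv,
    log_dn,
    stationary_log_density,
    stationary_score,
    transition_log_density,
    transition_score,
)

PARAM_SETS = [JacobiParams(1, 1, 1), JacobiParams(1, 3, 1), JacobiParams(2, 2, 1)]


class TestStationary:
    def test_uniform_case_is_flat(self):
        assert stationary_log_density(JacobiParams(1, 1, 1), 0.37) == pytest.approx(0.0)

    def test_beta22_mode_density(self):
        assert stationary_log_density(JacobiParams(2, 2, 1), 0.5) == pytest.approx(
            np.log(1.5)
        )

    @pytest.mark.parametrize("p", PARAM_SETS)
    def test_normalizes(self, p):
        val, _ = quad(lambda x: np.exp(stationary_log_density(p, x)), 0, 1)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            stationary_log_density(JacobiParams(1, 1, 1), 1.2)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            JacobiParams(0.0, 1.0, 1.0)

    def test_speed_presets(self):
        p = JacobiParams(1, 3, 5.0)
        assert p.with_speed_preset("unit").s == 1.0
        assert p.with_speed_preset("inv-sum").s == pytest.approx(0.5)


class TestSpectrum:
    @pytest.mark.parametrize(
        "n,a,b,s,expected",
        [(0, 2.0, 5.0, 3.0, 0.0), (1, 1, 1, 1, -1.0), (2, 1, 3, 2, -10.0)],
    )
    def test_eigenvalue_formula(self, n, a, b, s, expected):
        assert eigenvalue(n, JacobiParams(a, b, s)) == pytest.approx(expected)

    def test_eigenvalues_strictly_decreasing(self):
        p = JacobiParams(1.5, 0.7, 1.3)
        lams = [eigenvalue(n, p) for n in range(10)]
        assert lams[0] == 0.0
        assert all(l2 < l1 for l1, l2 in zip(lams, lams[1:]))

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            eigenvalue(-1, PARAM_SETS[0])

    def test_zeroth_polynomial_is_one(self):
        x = np.linspace(0, 1, 7)
        assert np.allclose(jacobi_poly(0, JacobiParams(1.7, 2.3, 1), x), 1.0)

    @pytest.mark.parametrize("p", PARAM_SETS + [JacobiParams(1.5, 0.7, 1)])
    def test_orthogonality_and_normalization(self, p):
        """Quadrature oracle: <R_m, R_n>_Beta = delta_mn / d_n."""
        for m, n in [(1, 2), (0, 3), (2, 4)]:
            val, _ = quad(
                lambda x: np.exp(stationary_log_density(p, x))
                * jacobi_poly(m, p, x) * jacobi_poly(n, p, x),
                0, 1, limit=200,
            )
            assert val == pytest.approx(0.0, abs=1e-8)
        for n in (1, 3):
            val, _ = quad(
                lambda x: np.exp(stationary_log_density(p, x))
                * jacobi_poly(n, p, x) ** 2,
                0, 1, limit=200,
            )
            assert val == pytest.approx(np.exp(-log_dn(n, p)), rel=1e-8)

    @pytest.mark.parametrize("p", PARAM_SETS)
    @pytest.mark.parametrize("n", [1, 2, 4])
    def test_polynomials_are_generator_eigenfunctions(self, p, n):
        """Finite-difference generator oracle: L R_n = lambda_n R_n."""
        xs = np.linspace(0.1, 0.9, 9)
        h = 1e-5
        f = lambda x: jacobi_poly(n, p, x)
        d1 = (f(xs + h) - f(xs - h)) / (2 * h)
        d2 = (f(xs + h) - 2 * f(xs) + f(xs - h)) / h**2
        gen = 0.5 * p.s * (p.a * (1 - xs) - p.b * xs) * d1 + 0.5 * p.s * xs * (1 - xs) * d2
        lam = eigenvalue(n, p)
        assert np.allclose(gen, lam * f(xs), rtol=1e-4, atol=1e-5)

    def test_polynomial_derivative_matches_finite_difference(self):
        p = JacobiParams(1, 3, 1)
        xs = np.linspace(0.05, 0.95, 11)
        h = 1e-6
        for n in (1, 2, 5):
            fd = (jacobi_poly(n, p, xs + h) - jacobi_poly(n, p, xs - h)) / (2 * h)
            assert np.allclose(jacobi_poly_deriv(n, p, xs), fd, rtol=1e-6, atol=1e-6)


class TestTransitionDensity:
    def test_long_time_limit_is_stationary(self):
        p = JacobiParams(1, 1, 1)
        val = transition_log_density(p, 0.3, 0.5, 100.0)
        assert val == pytest.approx(0.0, abs=1e-10)  # log of uniform density

    @pytest.mark.parametrize("p", PARAM_SETS)
    @pytest.mark.parametrize("t", [0.25, 0.5])
    def test_normalizes_from_vertex(self, p, t):
        val, _ = quad(
            lambda x: np.exp(transition_log_density(p, 1.0, x, t)), 0, 1, limit=400
        )
        assert val == pytest.approx(1.0, abs=1e-3)

    def test_chapman_kolmogorov(self):
        """Composition over a time split reproduces the direct density."""
        p = JacobiParams(1, 3, 1)
        t1, t2 = 0.4, 0.6
        for xt in (0.2, 0.5, 0.8):
            direct = np.exp(transition_log_density(p, 1.0, xt, t1 + t2))
            comp, _ = quad(
                lambda xm: np.exp(transition_log_density(p, 1.0, xm, t1))
                * np.exp(transition_log_density(p, xm, xt, t2)),
                0, 1, limit=200,
            )
            assert comp == pytest.approx(direct, abs=1e-3)

    def test_time_validation(self):
        p = JacobiParams(1, 1, 1)
        with pytest.raises(ValueError):
            transition_log_density(p, 0.5, 0.5, -1.0)
        with pytest.raises(ValueError):
            transition_log_density(p, 0.5, 0.5, 1e-4)

    def test_adaptive_truncation_grows_for_small_t(self):
        p = JacobiParams(1, 1, 1)
        exp_small = SpectralExpansion.build(p, 0.01)
        exp_large = SpectralExpansion.build(p, 1.0)
        assert exp_small.n_terms > exp_large.n_terms
        assert exp_small.n_for_t(1.0) < exp_small.n_terms


class TestTransitionScore:
    def test_matches_finite_difference(self):
        p = JacobiParams(1, 3, 1)
        h = 1e-6
        fd = (
            transition_log_density(p, 1.0, 0.6 + h, 0.3)
            - transition_log_density(p, 1.0, 0.6 - h, 0.3)
        ) / (2 * h)
        assert transition_score(p, 1.0, 0.6, 0.3) == pytest.approx(fd, abs=1e-4)

    def test_long_time_limit_is_stationary_score(self):
        for p, xt in [(JacobiParams(1, 1, 1), 0.3), (JacobiParams(2, 2, 1), 0.7)]:
            val = transition_score(p, 1.0, xt, 50.0)
            assert val == pytest.approx(stationary_score(p, xt), abs=1e-8)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            transition_score(JacobiParams(1, 1, 1), 1.0, 0.0, 0.5)


class TestEulerMaruyama:
    def test_deterministic_given_seed(self):
        p = JacobiParams(1, 3, 1)
        a = forward_sample_em(p, 0.0, 1.0, rng=np.random.default_rng(5))
        b = forward_sample_em(p, 0.0, 1.0, rng=np.random.default_rng(5))
        assert a == b

    def test_step_count_validation(self):
        with pytest.raises(ValueError):
            forward_sample_em(JacobiParams(1, 1, 1), 0.5, 1.0, n_steps=0)

    def test_trajectories_confined_to_unit_interval(self):
        p = JacobiParams(1, 1, 1)
        rng = np.random.default_rng(0)
        traj = forward_trajectory_em(p, np.full(200, 1.0), np.linspace(0.1, 3, 12), rng)
        assert traj.min() >= 0.0 and traj.max() <= 1.0

    def test_stationary_mean_reached_from_vertex(self):
        """Stationary-moment oracle: mean -> a/(a+b) after long diffusion."""
        p = JacobiParams(1, 3, 1)
        xs = forward_sample_em(
            p, np.zeros(5000), 4.0, rng=np.random.default_rng(0), steps_per_unit=400
        )
        assert xs.mean() == pytest.approx(0.25, abs=0.02)

    def test_stationary_start_stays_stationary(self):
        """KS oracle: Beta(a,b)-started chains remain Beta(a,b)."""
        p = JacobiParams(2, 2, 1)
        rng = np.random.default_rng(1)
        x0 = rng.beta(2, 2, size=3000)
        xs = forward_sample_em(p, x0, 1.0, rng=rng, steps_per_unit=400)
        assert kstest(xs, beta_dist(2, 2).cdf).pvalue > 0.01
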