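"""Stick-breaking transform, simplex diffusion and score conversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare, kstest

from dirdiff.jacobi import JacobiParams, stationary_score, transition_score
from dirdiff.stick import (
    StickBreakingSpec,
    flat_spec,
    forward_sample_multivariate,
    log_det_jacobian,
    onehot_to_stick,
    sample_stationary_v,
    sb_inverse,
    sb_transform,
    score_v_to_x,
    score_x_to_v,
    stick_jacobian,
)

interior = st.floats(0.01, 0.99)


class TestTransform:
    def test_two_category_case(self):
        assert np.allclose(sb_transform(np.array([0.3])), [0.3, 0.7])

    def test_exhausted_stick_ignores_later_breaks(self):
        x = sb_transform(np.array([1.0, 0.4, 0.9]))
        assert np.allclose(x, [1, 0, 0, 0])

    @given(st.lists(interior, min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_output_on_simplex(self, vs):
        x = sb_transform(np.array(vs))
        assert x.min() >= 0
        assert x.sum() == pytest.approx(1.0, abs=1e-9)

    @given(st.lists(interior, min_size=2, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, vs):
        v = np.array(vs)
        v2, det = sb_inverse(sb_transform(v))
        assert det.all()
        assert np.allclose(v2, v, atol=1e-9)

    def test_inverse_of_interior_point(self):
        v, det = sb_inverse(np.array([0.2, 0.3, 0.5]))
        assert det.all()
        assert np.allclose(v, [0.2, 0.375])

    def test_inverse_of_onehot_third_category(self):
        v, det = sb_inverse(np.array([0.0, 0.0, 1.0, 0.0]))
        assert np.allclose(v, [0, 0, 1])
        assert det.all()

    def test_inverse_of_onehot_first_category_undetermined_tail(self):
        v, det = sb_inverse(np.array([1.0, 0.0, 0.0, 0.0]))
        assert v[0] == 1.0
        assert det.tolist() == [True, False, False]
        assert np.all(np.isnan(v[1:]))

    def test_onehot_stick_structure(self):
        init, det = onehot_to_stick(np.array([0, 2, 3]), 4)
        assert np.array_equal(init, [[1, 0, 0], [0, 0, 1], [0, 0, 0]])
        assert np.array_equal(det, [[True, False, False],
                                    [True, True, True],
                                    [True, True, True]])


class TestFlatSpec:
    def test_two_category_preset(self):
        spec = flat_spec(2)
        assert (spec.params[0].a, spec.params[0].b) == (1.0, 1.0)

    def test_four_category_preset(self):
        spec = flat_spec(4)
        assert [(p.a, p.b) for p in spec.params] == [(1, 3), (1, 2), (1, 1)]

    def test_too_few_categories_rejected(self):
        with pytest.raises(ValueError):
            flat_spec(1)

    def test_mismatched_param_count_rejected(self):
        with pytest.raises(ValueError):
            StickBreakingSpec(k=3, params=(JacobiParams(1, 1),))

    def test_stationary_marginals_match_dirichlet(self):
        """Dirichlet oracle: first coordinate of Dir(1,..,1) is Beta(1, k-1)."""
        k = 5
        rng = np.random.default_rng(0)
        x = sb_transform(sample_stationary_v(flat_spec(k), (10_000,), rng))
        from scipy.stats import beta

        for i in range(k):
            assert kstest(x[:, i], beta(1, k - 1).cdf).pvalue > 0.01


class TestJacobian:
    def test_matches_numerical_differentiation(self):
        v0 = np.array([0.3, 0.5, 0.2])
        J = stick_jacobian(v0)
        num = np.zeros((3, 3))
        for j in range(3):
            e = np.zeros(3)
            e[j] = 1e-6
            num[:, j] = (sb_transform(v0 + e)[:3] - sb_transform(v0 - e)[:3]) / 2e-6
        assert np.allclose(J, num, atol=1e-6)

    def test_log_det_matches_dense_determinant(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0.05, 0.95, (20, 4))
        dense = np.log(np.abs(np.linalg.det(stick_jacobian(v))))
        assert np.allclose(log_det_jacobian(v), dense, atol=1e-9)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            stick_jacobian(np.array([0.0, 0.5]))


class TestScoreConversion:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0.05, 0.95, (10, 3))
        s = rng.normal(size=(10, 3))
        back = score_x_to_v(v, score_v_to_x(v, s))
        assert np.allclose(back, s, atol=1e-9)

    def test_two_category_identity(self):
        # x = (v, 1-v): dx_1/dv = 1 and no log-det term, so scores match
        v = np.array([[0.4]])
        s = np.array([[2.3]])
        assert score_v_to_x(v, s) == pytest.approx(2.3)

    def test_flat_dirichlet_score_is_zero_in_x_space(self):
        """Analytic oracle: Dir(1,...,1) is flat, so its x-score vanishes
        while the independent Beta(1, k-i) sticks have nonzero v-scores."""
        spec = flat_spec(5)
        rng = np.random.default_rng(5)
        v = sample_stationary_v(spec, (50,), rng)
        s_v = np.stack(
            [stationary_score(p, v[..., j]) for j, p in enumerate(spec.params)], -1
        )
        assert np.abs(score_v_to_x(v, s_v)).max() < 1e-9
        assert np.abs(s_v).max() > 0.1


class TestForwardMultivariate:
    def test_rejects_non_onehot(self):
        spec = flat_spec(3)
        with pytest.raises(ValueError):
            forward_sample_multivariate(
                spec, np.array([0.5, 0.5, 0.0]), 1.0, np.random.default_rng(0)
            )

    def test_two_category_reduces_to_univariate(self):
        from dirdiff.jacobi import forward_sample_em

        spec = flat_spec(2)
        x0 = np.tile([1.0, 0.0], (40, 1))  # category 0 -> v init 1
        v, _ = forward_sample_multivariate(
            spec, x0, 0.5, np.random.default_rng(9), steps_per_unit=200
        )
        uni = forward_sample_em(
            spec.params[0], np.ones(40), 0.5,
            rng=np.random.default_rng(9), steps_per_unit=200,
        )
        assert np.allclose(v[:, 0], uni)

    def test_undetermined_dims_carry_stationary_scores(self):
        spec = flat_spec(4)
        x0 = np.tile([1.0, 0, 0, 0], (200, 1))  # dims 1, 2 undetermined
        v, score = forward_sample_multivariate(
            spec, x0, 0.5, np.random.default_rng(1), steps_per_unit=100
        )
        for j in (1, 2):
            expected = stationary_score(spec.params[j], v[:, j])
            assert np.allclose(score[:, j], expected)

    def test_reaches_flat_dirichlet_at_long_times(self):
        """Uniformity oracle: per-stick PIT values are uniform and the
        argmax category is equidistributed."""
        spec = flat_spec(3)
        rng = np.random.default_rng(2)
        cats = rng.integers(3, size=2000)
        x0 = np.eye(3)[cats]
        v, _ = forward_sample_multivariate(spec, x0, 8.0, rng, steps_per_unit=150)
        from scipy.stats import beta

        for j, p in enumerate(spec.params):
            u = beta(p.a, p.b).cdf(v[:, j])
            assert kstest(u, "uniform").pvalue > 0.01
        counts = np.bincount(np.argmax(sb_transform(v), axis=-1), minlength=3)
        assert chisquare(counts).pvalue > 0.01
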