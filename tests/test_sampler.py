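"""Reverse-time SDE sampling: drift formula, stationarity, exact-score
recovery, time dilation mechanics and inpainting."""

import numpy as np
import pytest

from dirdiff.jacobi import stationary_score
from dirdiff.sampler import (
    SamplerConfig,
    _reverse_times,
    discretize,
    inpaint,
    reverse_drift,
    reverse_step,
    sample,
)
from dirdiff.stick import flat_spec, sample_stationary_v, sb_transform

from conftest import GridMixtureScore, TwoCategoryMixtureScore


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_steps=0)
        with pytest.raises(ValueError):
            SamplerConfig(time_dilation=0)
        with pytest.raises(ValueError):
            SamplerConfig(t_end=5.0)
        with pytest.raises(ValueError):
            SamplerConfig(discretization="round")
        with pytest.raises(ValueError):
            SamplerConfig(schedule="sqrt")

    def test_dilation_multiplies_substeps_not_model_time(self):
        base = SamplerConfig(n_steps=50, time_dilation=1)
        dil = SamplerConfig(n_steps=50, time_dilation=4)
        t1, dt1 = _reverse_times(base)
        t4, dt4 = _reverse_times(dil)
        assert len(t4) == 4 * len(t1)
        # same model-time span, 4x the total SDE time
        assert t4[0] == t1[0] and t4[-1] < t1[0]
        assert dt4.sum() == pytest.approx(4 * dt1.sum())


class TestReverseStep:
    def test_zero_noise_reduces_to_drift_formula(self):
        spec = flat_spec(3)
        v = np.array([[[0.3, 0.6]]])
        score = np.array([[[1.5, -0.7]]])
        dt = 1e-3
        stepped = reverse_step(v, score, spec, dt, rng=None)
        expected = v - reverse_drift(v, score, spec) * dt
        assert np.allclose(stepped, expected)

    def test_drift_formula_hand_checked(self):
        # k=2 flat spec (a=b=s=1) at v=0.5 with score 2:
        # (1/2)(1(1-.5)-1(.5)) - (1-2*.5) - .5*.5*2 = -0.5
        spec = flat_spec(2)
        d = reverse_drift(np.array([0.5]), np.array([2.0]), spec)
        assert d == pytest.approx(-0.5)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            reverse_step(np.array([0.5]), np.array([0.0]), flat_spec(2), 0.0, None)

    def test_stationary_law_preserved_at_large_t(self):
        """One reverse step with the true stationary score keeps the
        stationary moments (the reverse of a stationary process is
        stationary)."""
        spec = flat_spec(4)
        rng = np.random.default_rng(0)
        v = sample_stationary_v(spec, (10_000, 1), rng)
        score = np.stack(
            [stationary_score(p, v[..., j]) for j, p in enumerate(spec.params)], -1
        )
        stepped = reverse_step(v, score, spec, 0.02, rng)
        for j, p in enumerate(spec.params):
            target = p.a / (p.a + p.b)
            se = np.sqrt(stepped[..., j].var() / len(v))
            assert abs(stepped[..., j].mean() - target) < 4 * se + 0.02 * 0.1

    def test_trajectories_stay_in_unit_cube(self):
        spec = flat_spec(3)
        rng = np.random.default_rng(1)
        v = sample_stationary_v(spec, (64, 4), rng)
        for _ in range(50):
            score = rng.normal(scale=5.0, size=v.shape)
            v = reverse_step(v, score, spec, 0.05, rng)
            assert v.min() >= 0.0 and v.max() <= 1.0


class TestDiscretize:
    def test_argmax(self):
        x = np.array([[0.1, 0.7, 0.2], [0.5, 0.2, 0.3]])
        assert discretize(x).tolist() == [1, 0]

    def test_categorical_draw_frequencies(self):
        x = np.tile([0.2, 0.8], (5000, 1))
        cats = discretize(x, "categorical", np.random.default_rng(0))
        assert np.mean(cats == 1) == pytest.approx(0.8, abs=0.02)

    def test_categorical_requires_rng(self):
        with pytest.raises(ValueError):
            discretize(np.array([[0.5, 0.5]]), "categorical")


class TestExactScoreSampling:
    def test_two_point_mixture_recovers_weights(self):
        """Core correctness: with the exact mixture score (computable for
        a two-point data distribution via the spectral density) the
        sampler's terminal categorical law matches the data law."""
        spec = flat_spec(2)
        oracle = TwoCategoryMixtureScore(p1=0.7)
        cfg = SamplerConfig(n_steps=60)
        _, cats = sample(oracle, spec, cfg, 1500, 1, np.random.default_rng(3))
        freq = float(np.mean(cats == 1))
        assert freq == pytest.approx(0.7, abs=0.035)

    def test_stationary_score_gives_uniform_categories(self):
        """A model returning the stationary score reverses the stationary
        process, so terminal categories are uniform."""
        from scipy.stats import chisquare

        spec = flat_spec(4)

        class StationaryScore:
            def __call__(self, x, t, condition=None):
                from dirdiff.stick import sb_inverse

                v, _ = sb_inverse(np.asarray(x))
                v = np.clip(np.nan_to_num(v, nan=0.5), 1e-6, 1 - 1e-6)
                return np.stack(
                    [stationary_score(p, v[..., j]) for j, p in enumerate(spec.params)],
                    -1,
                )

            def params(self):
                return []

        _, cats = sample(
            StationaryScore(), spec, SamplerConfig(n_steps=50), 500, 4,
            np.random.default_rng(4),
        )
        counts = np.bincount(cats.ravel(), minlength=4)
        assert chisquare(counts).pvalue > 0.01


@pytest.fixture(scope="module")
def oracle():
    return TwoCategoryMixtureScore(p1=0.5)


class TestInpaint:
    def test_all_positions_clamped_returns_clamps(self, oracle):
        spec = flat_spec(2)
        clamps = np.array([1, 0, 1, 1])
        cats = inpaint(
            oracle, spec, SamplerConfig(n_steps=30), 4,
            np.arange(4), clamps, 5, np.random.default_rng(5),
        )
        assert np.array_equal(cats, np.tile(clamps, (5, 1)))

    def test_contradictory_clamps_rejected(self, oracle):
        with pytest.raises(ValueError):
            inpaint(
                oracle, flat_spec(2), SamplerConfig(n_steps=5), 4,
                np.array([1, 1]), np.array([0, 1]), 1, np.random.default_rng(0),
            )

    def test_out_of_range_clamps_rejected(self, oracle):
        with pytest.raises(ValueError):
            inpaint(
                oracle, flat_spec(2), SamplerConfig(n_steps=5), 4,
                np.array([7]), np.array([0]), 1, np.random.default_rng(0),
            )

    def test_solving_with_exact_score_improves_with_dilation(self, mini_grids):
        """With the exact mixture score over all 288 valid 4x4 grids,
        single-sample solving of a unique-solution 8-clue puzzle is far
        above the ~1e-5 chance level and improves with time dilation.
        (Replacement inpainting is an approximate conditional sampler,
        so completions remain below the 100% unconditional validity of
        the exact score; see the methods note.)"""
        from dirdiff.tasks import count_solutions, make_puzzle, solves

        spec = flat_spec(4)
        oracle = GridMixtureScore(spec, (mini_grids - 1).reshape(288, 16))
        rng = np.random.default_rng(7)
        puzzle = make_puzzle(mini_grids[42], 8, rng)
        assert count_solutions(puzzle, limit=2) == 1
        flat = puzzle.ravel()
        pos = np.nonzero(flat != 0)[0]
        rates = {}
        for c in (1, 4):
            cats = inpaint(
                oracle, spec, SamplerConfig(n_steps=80, time_dilation=c),
                16, pos, flat[pos] - 1, 48, np.random.default_rng(8),
            )
            rates[c] = np.mean([
                solves(puzzle, g) for g in cats.reshape(-1, 4, 4) + 1
            ])
        assert rates[1] > 0.2  # chance is ~1e-5
        assert rates[4] >= rates[1] - 2.5 * np.sqrt(0.5 / 48)

    def test_unclamped_positions_follow_the_model_law(self):
        """Null conditioning: free positions of an inpainting run have the
        same terminal distribution as unconditional samples."""
        spec = flat_spec(2)
        oracle = TwoCategoryMixtureScore(p1=0.7)
        cfg = SamplerConfig(n_steps=40)
        cats = inpaint(
            oracle, spec, cfg, 3, np.array([0]), np.array([0]), 600,
            np.random.default_rng(6),
        )
        free = cats[:, 1:]
        assert float(np.mean(free == 1)) == pytest.approx(0.7, abs=0.05)
        assert np.all(cats[:, 0] == 0)
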