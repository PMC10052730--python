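import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulmopt.optim import (
    Bounds,
    IGWOConfig,
    LeaderWeights,
    convergence_coefficient,
    estimate_prey,
    gwo_minimize,
    igwo_minimize,
    noise_sigma,
    sine_cosine_position,
    sphere,
    update_position,
)

from conftest import StubRng


class TestLeaderWeights:
    def test_default_valid(self):
        w = LeaderWeights()
        assert w.as_array().sum() == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "weights",
        [(0.3, 0.3, 0.4), (0.5, 0.2, 0.3), (0.4, 0.3, 0.2), (1.1, -0.05, -0.05)],
    )
    def test_invalid_weights_rejected(self, weights):
        with pytest.raises(ValueError):
            LeaderWeights(*weights)


class TestConvergenceCoefficient:
    def test_endpoints(self):
        assert convergence_coefficient(0, 200) == pytest.approx(1.8)
        assert convergence_coefficient(200, 200) == pytest.approx(0.0)

    def test_upward_jump_at_stage_switch(self):
        assert convergence_coefficient(49, 100) == pytest.approx(0.918)
        assert convergence_coefficient(50, 100) == pytest.approx(1.2)

    def test_domain_error(self):
        with pytest.raises(ValueError, match="outside"):
            convergence_coefficient(201, 200)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(T=st.integers(2, 500))
    def test_range(self, T):
        hs = [convergence_coefficient(t, T) for t in range(T + 1)]
        assert all(0.0 <= h <= 1.8 for h in hs)


class TestNoiseSigma:
    def test_endpoints(self):
        assert noise_sigma(0, 100, 1.0, 1e-6) == pytest.approx(1.0)
        assert noise_sigma(100, 100, 1.0, 1e-6) == pytest.approx(1e-6)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        T=st.integers(1, 300),
        sigma0=st.floats(1e-3, 10.0),
        ratio=st.floats(1e-8, 0.5),
    )
    def test_strictly_decreasing(self, T, sigma0, ratio):
        sigma_min = sigma0 * ratio
        vals = [noise_sigma(t, T, sigma0, sigma_min) for t in range(T + 1)]
        assert np.all(np.diff(vals) < 0)

    def test_invalid_configuration(self):
        with pytest.raises(ValueError):
            noise_sigma(0, 10, 0.1, 0.2)


class TestEstimatePrey:
    def test_identical_leaders_exact(self, rng):
        p = np.array([1.0, -2.0, 0.5])
        out = estimate_prey(p, p, p, LeaderWeights(), 0.0, rng)
        np.testing.assert_allclose(out, p)

    def test_hand_value(self, rng):
        out = estimate_prey(
            np.array([1.0]),
            np.array([2.0]),
            np.array([3.0]),
            LeaderWeights(0.5, 0.3, 0.2),
            0.0,
            rng,
        )
        np.testing.assert_allclose(out, [1.7])

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="same shape"):
            estimate_prey(np.zeros(2), np.zeros(3), np.zeros(2), LeaderWeights(), 0.0, rng)


class TestUpdatePosition:
    def test_zero_displacement(self):
        b = Bounds.cube(-5, 5, 2)
        prey = np.array([1.0, -1.0])
        out = update_position(prey.copy(), prey, 1.0, b, StubRng(0.25))
        np.testing.assert_allclose(out, prey)

    def test_hand_value(self):
        # prey=0, x=1, h=1, r=1 -> R=1 -> 0 - 1*(0-1) = 1
        out = update_position(
            np.array([1.0]), np.array([0.0]), 1.0, Bounds.cube(-5, 5, 1), StubRng(1.0)
        )
        np.testing.assert_allclose(out, [1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), h=st.floats(0.0, 1.8))
    def test_always_within_bounds(self, seed, h):
        gen = np.random.default_rng(seed)
        b = Bounds(np.array([-2.0, 0.0, -1.0]), np.array([2.0, 3.0, 0.5]))
        x = gen.uniform(b.lower, b.upper)
        prey = gen.normal(scale=4.0, size=3)  # may lie far outside
        out = update_position(x, prey, h, b, gen)
        assert b.contains(out)


class TestSineCosinePosition:
    def test_theta_zero_returns_m3(self):
        m1, m2, m3 = np.array([1.0]), np.array([2.0]), np.array([3.0])
        np.testing.assert_allclose(sine_cosine_position(m1, m2, m3, 0.0), m3)

    def test_theta_right_angle_returns_m1(self):
        m1, m2, m3 = np.array([1.0]), np.array([2.0]), np.array([3.0])
        np.testing.assert_allclose(
            sine_cosine_position(m1, m2, m3, np.pi / 2), m1, atol=1e-15
        )

    def test_hand_value_at_quarter_pi(self):
        one = np.array([1.0])
        out = sine_cosine_position(one, one, one, np.pi / 4)
        np.testing.assert_allclose(out, [np.sqrt(2) / 2 + 0.5 + np.sqrt(2) / 2])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="same shape"):
            sine_cosine_position(np.zeros(2), np.zeros(2), np.zeros(3), 0.1)


class TestPackMinimizers:
    def test_pop_below_three_rejected(self):
        with pytest.raises(ValueError, match="pop_size"):
            IGWOConfig(pop_size=2)

    @pytest.mark.parametrize("minimize", [gwo_minimize, igwo_minimize])
    def test_seeded_reproducibility(self, minimize):
        cfg = IGWOConfig(pop_size=6, iterations=25, seed=3)
        b = Bounds.cube(-5, 5, 4)
        r1 = minimize(sphere, b, cfg)
        r2 = minimize(sphere, b, cfg)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)
        np.testing.assert_array_equal(r1.trace, r2.trace)
        assert r1.n_evaluations == r2.n_evaluations

    @pytest.mark.parametrize("minimize", [gwo_minimize, igwo_minimize])
    @settings(deadline=None, max_examples=8, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_trace_non_increasing(self, minimize, seed):
        cfg = IGWOConfig(pop_size=5, iterations=15, seed=seed)
        res = minimize(sphere, Bounds.cube(-4, 4, 3), cfg)
        assert np.all(np.diff(res.trace) <= 0)
        assert res.best_fitness == res.trace[-1]
        assert sphere(res.best_position) == pytest.approx(res.best_fitness)

    def test_igwo_feasibility_of_evaluated_points(self):
        b = Bounds.cube(-2, 2, 3)

        def checked(x):
            assert b.contains(x)
            return sphere(x)

        igwo_minimize(checked, b, IGWOConfig(pop_size=5, iterations=20, seed=0))

    def test_igwo_converges_on_small_sphere(self):
        cfg = IGWOConfig(pop_size=15, iterations=80, seed=1)
        res = igwo_minimize(sphere, Bounds.cube(-5, 5, 4), cfg)
        assert res.best_fitness < 1e-3
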