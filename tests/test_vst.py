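"""Generalized Anscombe transform, its inverses, and the stabilization law."""

import numpy as np
import pytest

from pgbm3d import (
    NoiseParams,
    algebraic_inverse,
    asymptotic_inverse,
    build_exact_inverse_table,
    exact_unbiased_inverse,
    generalized_anscombe,
    simulate_pg_noise,
)
from pgbm3d.vst import VSTSpec, default_rate_grid


PURE_POISSON = NoiseParams(alpha=1.0, mu_g=0.0, sigma_g=0.0)


class TestForward:
    def test_classical_anscombe_values(self):
        # alpha=1, mu=sigma=0 reduces to 2*sqrt(z + 3/8)
        assert generalized_anscombe(np.array([[0.0]]), PURE_POISSON)[0, 0] == pytest.approx(
            2 * np.sqrt(3 / 8)
        )
        assert generalized_anscombe(np.array([[1.0]]), PURE_POISSON)[0, 0] == pytest.approx(
            2 * np.sqrt(11 / 8)
        )

    def test_strictly_increasing_above_clamp(self):
        p = NoiseParams(alpha=2.0, mu_g=5.0, sigma_g=1.0)
        z = np.linspace(5.0, 500.0, 200).reshape(1, -1)
        f = generalized_anscombe(z, p)
        assert np.all(np.diff(f[0]) > 0)

    def test_radicand_clamped_to_zero(self):
        p = NoiseParams(alpha=1.0, mu_g=100.0, sigma_g=0.0)
        f = generalized_anscombe(np.array([[0.0]]), p)
        assert f[0, 0] == 0.0

    @pytest.mark.parametrize("y", [20.0, 50.0, 100.0, 200.0])
    def test_stabilization_to_unit_variance(self, y):
        """Var(f(z)) within [0.9, 1.1] across the working intensity range."""
        p = NoiseParams(alpha=1.0, mu_g=0.0, sigma_g=2.0)
        z = simulate_pg_noise(np.full((600, 600), y), p, seed=int(y))
        f = generalized_anscombe(z, p)
        assert 0.9 <= f.var() <= 1.1


class TestAlgebraicAndAsymptotic:
    def test_algebraic_inverts_forward_exactly(self):
        p = NoiseParams(alpha=1.7, mu_g=3.0, sigma_g=2.0)
        z = np.linspace(5.0, 800.0, 50).reshape(5, 10)
        np.testing.assert_allclose(
            algebraic_inverse(generalized_anscombe(z, p), p), z, rtol=1e-12
        )

    def test_asymptotic_is_algebraic_plus_quarter_alpha(self):
        p = NoiseParams(alpha=2.0, mu_g=0.0, sigma_g=1.0)
        d = np.array([[4.0, 10.0]])
        np.testing.assert_allclose(
            asymptotic_inverse(d, p) - algebraic_inverse(d, p), 0.25 * p.alpha
        )

    def test_constant_in_constant_out(self):
        p = NoiseParams(alpha=1.0)
        out = algebraic_inverse(np.full((3, 3), 5.0), p)
        assert np.ptp(out) == 0.0


class TestExactInverseTable:
    def test_degenerate_distribution_at_zero(self):
        spec = build_exact_inverse_table(PURE_POISSON, np.array([0.0, 1.0, 5.0]))
        assert spec.expected[0] == pytest.approx(2 * np.sqrt(3 / 8))

    def test_table_matches_monte_carlo_expectation(self):
        """Tabulated E[f(z)|y] agrees with a simulation oracle at y=100."""
        p = NoiseParams(alpha=1.0, mu_g=0.0, sigma_g=0.5)
        spec = build_exact_inverse_table(p, np.array([50.0, 100.0, 150.0]))
        z = simulate_pg_noise(np.full((1000, 1000), 100.0), p, seed=17)
        f = generalized_anscombe(z, p)
        se = f.std() / np.sqrt(f.size)
        assert abs(spec.expected[1] - f.mean()) < 3 * se

    def test_table_strictly_increasing(self):
        p = NoiseParams(alpha=2.0, mu_g=4.0, sigma_g=3.0)
        spec = build_exact_inverse_table(p, default_rate_grid(300.0, n=128))
        assert np.all(np.diff(spec.expected) > 0)

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            build_exact_inverse_table(PURE_POISSON, np.array([1.0, 1.0, 2.0]))


class TestExactInverse:
    def test_round_trip_through_expectation(self):
        p = NoiseParams(alpha=1.0, mu_g=0.0, sigma_g=1.0)
        spec = build_exact_inverse_table(p, default_rate_grid(200.0, n=256))
        d = np.interp(100.0, spec.y_grid, spec.expected)
        y_hat = exact_unbiased_inverse(np.array([[d]]), spec)[0, 0]
        assert y_hat == pytest.approx(100.0, abs=0.5)

    def test_identity_on_grid_within_interpolation_tolerance(self):
        p = NoiseParams(alpha=1.5, mu_g=2.0, sigma_g=1.0)
        spec = build_exact_inverse_table(p, default_rate_grid(100.0, n=256))
        back = exact_unbiased_inverse(spec.expected.reshape(1, -1), spec)[0]
        assert np.max(np.abs(back - spec.y_grid)) < 1e-3 * max(1.0, spec.y_grid.max())

    def test_monotone_non_decreasing(self):
        p = NoiseParams(alpha=1.0, mu_g=0.0, sigma_g=1.0)
        spec = build_exact_inverse_table(p, default_rate_grid(50.0, n=128))
        d = np.linspace(-1.0, spec.expected[-1] + 5.0, 400).reshape(1, -1)
        out = exact_unbiased_inverse(d, spec)[0]
        assert np.all(np.diff(out) >= -1e-9)

    def test_below_table_maps_to_zero_and_constant_stays_constant(self):
        p = NoiseParams(alpha=1.0, mu_g=0.0, sigma_g=1.0)
        spec = build_exact_inverse_table(p, default_rate_grid(50.0, n=64))
        out = exact_unbiased_inverse(np.full((2, 2), spec.expected[0] - 1.0), spec)
        np.testing.assert_array_equal(out, 0.0)
        out2 = exact_unbiased_inverse(np.full((2, 2), spec.expected[10]), spec)
        assert np.ptp(out2) == 0.0

    def test_exact_inverse_beats_algebraic_at_low_counts(self):
        """At y=5 the expectation-based inverse has a smaller reconstruction
        error of the E-estimate than naive function inversion."""
        p = NoiseParams(alpha=1.0, mu_g=0.0, sigma_g=1.0)
        spec = build_exact_inverse_table(p, default_rate_grid(20.0, n=256))
        y = 5.0
        d = np.interp(y, spec.y_grid, spec.expected)
        err_exact = abs(exact_unbiased_inverse(np.array([[d]]), spec)[0, 0] - y)
        alg_rate = (algebraic_inverse(np.array([[d]]), p)[0, 0] - p.mu_g) / p.alpha
        err_algebraic = abs(alg_rate - y)
        assert err_exact < err_algebraic


class TestSpecSerialization:
    def test_json_round_trip(self, tmp_path):
        p = NoiseParams(alpha=1.2, mu_g=8.0, sigma_g=3.0)
        spec = build_exact_inverse_table(p, default_rate_grid(100.0, n=64))
        path = tmp_path / "vst.json"
        spec.to_json(path)
        loaded = VSTSpec.from_json(path)
        assert loaded.params == p
        np.testing.assert_array_equal(loaded.expected, spec.expected)

    def test_non_monotone_table_rejected(self):
        with pytest.raises(ValueError):
            VSTSpec(PURE_POISSON, np.array([0.0, 1.0]), np.array([2.0, 1.0]))


class TestForwardInverseProperties:
    """Property-based checks across the parameter space."""

    def test_algebraic_round_trip_property(self):
        from hypothesis import given, settings, strategies as st

        @settings(deadline=None, derandomize=True, max_examples=60)
        @given(
            alpha=st.floats(0.1, 50.0),
            mu=st.floats(-10.0, 50.0),
            sigma=st.floats(0.0, 30.0),
            z=st.floats(0.0, 5000.0),
        )
        def check(alpha, mu, sigma, z):
            p = NoiseParams(alpha=alpha, mu_g=mu, sigma_g=sigma)
            arr = np.array([[z]])
            f = generalized_anscombe(arr, p)
            if f[0, 0] > 0:  # above the clamp point the forward is invertible
                back = algebraic_inverse(f, p)[0, 0]
                assert back == pytest.approx(z, rel=1e-9, abs=1e-6)

        check()
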