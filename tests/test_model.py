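"""Geometry, Förster rates and master-equation generator construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nanomig import (
    DonorConfiguration,
    RateMatrix,
    SystemParams,
    build_rate_matrix,
    chord_distance,
    forster_rate,
    sample_configuration,
)


class TestSystemParams:
    def test_xi_and_surface_area_are_derived_exactly(self):
        p = SystemParams(10, radius=2.0, critical_radius=0.5, lifetime=3.0)
        assert p.xi == 0.5 / 2.0
        assert p.surface_area == pytest.approx(16.0 * np.pi, rel=1e-15)

    def test_from_xi_roundtrip(self):
        p = SystemParams.from_xi(5, 0.25, radius=4.0)
        assert p.critical_radius == 1.0
        assert p.xi == 0.25

    @pytest.mark.parametrize("kwargs", [
        {"n_donors": 0}, {"n_donors": -3}, {"n_donors": 2, "radius": 0.0},
        {"n_donors": 2, "critical_radius": -1.0}, {"n_donors": 2, "lifetime": 0.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SystemParams(**kwargs)


class TestSampling:
    def test_single_donor_sits_on_sphere(self):
        cfg = sample_configuration(SystemParams(1, radius=3.0), seed=0)
        assert cfg.positions.shape == (1, 3)
        assert np.linalg.norm(cfg.positions[0]) == pytest.approx(3.0, rel=1e-12)

    def test_fixed_seed_reproduces_positions(self):
        p = SystemParams(20)
        a = sample_configuration(p, seed=42)
        b = sample_configuration(p, seed=42)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_area_uniformity_of_z_coordinate(self):
        # area-uniform points have z uniform on [-R, R]
        cfg = sample_configuration(SystemParams(10_000), seed=7)
        z = cfg.positions[:, 2]
        se = 1.0 / np.sqrt(3.0 * z.size)  # Var(z) = R^2/3
        assert abs(z.mean()) < 3.0 * se
        assert stats.kstest(z, stats.uniform(loc=-1.0, scale=2.0).cdf).pvalue > 0.01

    def test_pairwise_chord_distance_density(self):
        # independent pairs: chord length density f(u) = u / (2 R^2) on [0, 2R]
        cfg = sample_configuration(SystemParams(4000), seed=11)
        pairs = cfg.positions.reshape(-1, 2, 3)
        d = np.linalg.norm(pairs[:, 0] - pairs[:, 1], axis=1)
        assert stats.kstest(d, lambda u: u ** 2 / 4.0).pvalue > 0.01

    def test_table_roundtrip(self):
        cfg = sample_configuration(SystemParams(6, radius=2.5), seed=3)
        back = DonorConfiguration.from_table(cfg.to_table())
        np.testing.assert_array_equal(back.positions, cfg.positions)
        assert back.radius == cfg.radius


class TestChordDistance:
    def test_antipodal_points(self):
        assert chord_distance([0, 0, 2.0], [0, 0, -2.0]) == pytest.approx(4.0)

    @pytest.mark.parametrize("theta", [0.0, 0.3, np.pi / 2, 2.5, np.pi])
    def test_polar_angle_formula(self, theta):
        r = 1.7
        p = [r * np.sin(theta), 0.0, r * np.cos(theta)]
        assert chord_distance(p, [0, 0, r]) == pytest.approx(
            2.0 * r * np.sin(theta / 2.0), abs=1e-12)


class TestForsterRate:
    def test_reference_values(self, unit_params):
        p = SystemParams(2, critical_radius=2.0, lifetime=4.0)
        assert forster_rate(2.0, p) == pytest.approx(1.0 / 4.0)
        assert forster_rate(4.0, p) == pytest.approx(1.0 / (64.0 * 4.0))

    def test_zero_distance_rejected(self, unit_params):
        with pytest.raises(ValueError, match="coincident"):
            forster_rate(0.0, unit_params)

    @settings(max_examples=50, derandomize=True)
    @given(r=st.floats(0.05, 50.0), scale=st.floats(0.1, 10.0))
    def test_monotone_and_scale_covariant(self, r, scale):
        p1 = SystemParams(2, critical_radius=1.0)
        p2 = SystemParams(2, radius=scale, critical_radius=scale)
        assert forster_rate(r, p1) > forster_rate(r * 1.01, p1)
        assert forster_rate(scale * r, p2) == pytest.approx(
            forster_rate(r, p1), rel=1e-12)


class TestRateMatrix:
    def test_two_donor_exchange_matrix(self):
        p = SystemParams(2, critical_radius=1.0, lifetime=1.0)
        cfg = DonorConfiguration(np.array([[0, 0, 1.0], [0, 0, -1.0]]), radius=1.0)
        W = build_rate_matrix(cfg, p)
        w = (1.0 / 2.0) ** 6
        np.testing.assert_allclose(W.entries, [[-w, w], [w, -w]], rtol=1e-14)

    def test_single_donor_gives_zero_generator(self):
        cfg = sample_configuration(SystemParams(1), seed=0)
        W = build_rate_matrix(cfg, SystemParams(1))
        assert W.entries.shape == (1, 1) and W.entries[0, 0] == 0.0

    def test_generator_properties(self, small_system):
        cfg = sample_configuration(small_system, seed=5)
        W = build_rate_matrix(cfg, small_system)
        scale = np.max(W.entries - np.diag(np.diag(W.entries)))
        assert np.abs(np.ones(W.n) @ W.entries).max() < 1e-10 * scale
        np.testing.assert_allclose(W.entries, W.entries.T, rtol=1e-13)
        assert np.all(W.outflow >= 0.0)

    def test_coincident_donors_named_in_error(self):
        pos = np.array([[0, 0, 1.0], [0, 0, 1.0], [0, 1.0, 0]])
        cfg = DonorConfiguration(pos, radius=1.0)
        with pytest.raises(ValueError, match="donors 1 and 2"):
            build_rate_matrix(cfg, SystemParams(3))

    def test_r_min_clips_extreme_rates(self):
        eps = 1e-8
        pos = np.array([[0, 0, 1.0],
                        [np.sin(eps), 0, np.cos(eps)],
                        [0, 1.0, 0]])
        cfg = DonorConfiguration(pos / np.linalg.norm(pos, axis=1)[:, None], radius=1.0)
        p = SystemParams(3)
        clipped = build_rate_matrix(cfg, p, r_min=0.01)
        assert clipped.entries[1, 0] == pytest.approx(forster_rate(0.01, p))

    def test_column_sum_invariant_rejected(self):
        with pytest.raises(ValueError, match="sum to zero"):
            RateMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
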