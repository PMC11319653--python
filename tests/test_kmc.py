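"""Kinetic Monte-Carlo: trajectories, estimators, and exactness of the
fast-cluster aggregation."""

import numpy as np
import pytest

from nanomig import (
    DonorConfiguration,
    SystemParams,
    build_rate_matrix,
    ensemble_green_sd,
    estimate_anisotropy,
    estimate_green_sd,
    estimate_msd,
    sample_configuration,
    simulate_trajectory,
)
from nanomig.kmc import _ConfigTables, _site_at_emission


def _two_state(w: float):
    p = SystemParams(2, critical_radius=w ** (1 / 6.0) * 2.0)
    cfg = DonorConfiguration(np.array([[0, 0, 1.0], [0, 0, -1.0]]), radius=1.0)
    return build_rate_matrix(cfg, p)


class TestTrajectories:
    def test_single_donor_never_hops(self):
        cfg = sample_configuration(SystemParams(1), seed=0)
        W = build_rate_matrix(cfg, SystemParams(1))
        traj = simulate_trajectory(W, 10.0, seed=1)
        assert traj.jump_times.size == 0
        assert traj.site_at(5.0) == 0

    def test_two_state_hop_count_is_poissonian(self):
        # constant total rate w => hop count over [0, t] has mean w t
        w, t_max, n = 2.5, 4.0, 1500
        W = _two_state(w)
        counts = [simulate_trajectory(W, t_max, seed=k).jump_times.size
                  for k in range(n)]
        se = np.sqrt(w * t_max / n)
        assert abs(np.mean(counts) - w * t_max) < 3.0 * se

    def test_dwell_times_match_total_outflow(self):
        # three donors at right angles: tame, asymmetry-free rates
        p = SystemParams.from_xi(3, 0.8)
        cfg = DonorConfiguration(np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]]),
                                 radius=1.0)
        W = build_rate_matrix(cfg, p)
        mean = 1.0 / W.outflow[0]
        first_dwells = [traj.jump_times[0]
                        for traj in (simulate_trajectory(W, 20.0 * mean, seed=k)
                                     for k in range(800))
                        if traj.jump_times.size]
        assert abs(np.mean(first_dwells) - mean) < 3.0 * mean / np.sqrt(800)


class TestGreenSD:
    def test_starts_exactly_at_one(self, small_system, time_grid):
        est = estimate_green_sd(small_system, 20, 5, time_grid, seed=0)
        assert est.mean[0] == 1.0

    def test_matches_matrix_exponential_oracle(self):
        p = SystemParams.from_xi(5, 0.3)
        grid = np.linspace(0.0, 4.0, 21)
        oracle = ensemble_green_sd(p, 200, grid, seed=1)
        kmc = estimate_green_sd(p, 200, 60, grid, seed=2)
        comb = np.sqrt(oracle.se ** 2 + kmc.se ** 2)
        diff = np.abs(oracle.mean - kmc.mean)
        assert np.all(diff <= 3.0 * np.where(comb > 0, comb, np.inf) + 1e-12)

    def test_long_time_plateau_is_one_over_n(self):
        # the slowest configurations (a donor weakly coupled across the
        # sphere) need several lifetimes to equilibrate; t = 10 tau is deep
        # in the plateau for the whole ensemble
        p = SystemParams.from_xi(10, 1.0)
        est = estimate_green_sd(p, 120, 8, np.array([0.0, 10.0]), seed=3)
        assert abs(est.mean[-1] - 0.1) < 3.0 * est.se[-1]

    def test_anisotropy_is_identity_on_normalized_curve(self, small_system, time_grid):
        est = estimate_green_sd(small_system, 10, 4, time_grid, seed=4)
        ani = estimate_anisotropy(est)
        np.testing.assert_array_equal(ani.mean, est.mean)
        np.testing.assert_array_equal(ani.se, est.se)


class TestClusterAggregationExactness:
    """The aggregated sampler must be unbiased against the exact resolvent.

    The lifetime-weighted mean of any site function f is
    (1/tau) f^T (I/tau - W)^(-1) e_1, computable exactly per configuration;
    the KMC emission-site sampler must agree within Monte-Carlo error even
    when the threshold forces heavy aggregation.
    """

    @pytest.mark.parametrize("fast_factor", [1e-2, 3.0, 300.0])
    def test_emission_site_distribution_unbiased(self, fast_factor):
        p = SystemParams.from_xi(12, 0.6)
        n_cfg, n_traj = 60, 60
        diffs, variances = [], []
        for child in np.random.SeedSequence(77).spawn(n_cfg):
            rng = np.random.default_rng(child)
            cfg = sample_configuration(p, rng)
            W = build_rate_matrix(cfg, p)
            d2 = np.sum((cfg.positions - cfg.positions[0]) ** 2, axis=1)
            col = np.linalg.solve(np.eye(12) / p.lifetime - W.entries,
                                  np.eye(12)[:, 0]) / p.lifetime
            exact = float(d2 @ col)
            tables = _ConfigTables(W, p.lifetime, fast_factor)
            samples = np.array([
                d2[_site_at_emission(tables, rng.exponential(p.lifetime), rng)]
                for _ in range(n_traj)])
            diffs.append(samples.mean() - exact)
            variances.append(samples.var(ddof=1) / n_traj)
        z = np.mean(diffs) / (np.sqrt(np.sum(variances)) / n_cfg)
        assert abs(z) < 3.0


class TestMsd:
    def test_single_donor_displacement_is_zero(self):
        est = estimate_msd(SystemParams(1), 5, 5, seed=0)
        assert est.relative_rms == 0.0

    def test_vanishing_migration_freezes_the_excitation(self):
        est = estimate_msd(SystemParams.from_xi(10, 1e-3), 20, 5, seed=1)
        assert est.relative_rms < 1e-6 / 1e-3  # far below one hop distance

    def test_bounded_by_sphere_diameter(self):
        est = estimate_msd(SystemParams.from_xi(30, 0.5), 40, 5, seed=2)
        assert 0.0 <= est.relative_rms <= 2.0 / 0.5

    def test_emission_sampling_agrees_with_lifetime_quadrature(self):
        # <r^2> at an Exponential(tau) time == int (1/tau) e^(-t/tau) <r^2(t)> dt
        p = SystemParams.from_xi(12, 0.5)
        grid = np.linspace(0.0, 9.0, 181)
        est = estimate_msd(p, 150, 8, seed=3, time_grid=grid)
        weights = np.exp(-grid / p.lifetime) / p.lifetime
        quad_route = np.trapezoid(weights * est.curve.mean, grid)
        direct = est.relative_rms ** 2
        se_quad = np.trapezoid(weights * est.curve.se, grid)
        tol = 3.0 * np.hypot(2.0 * est.relative_rms * est.standard_error, se_quad)
        assert abs(direct - quad_route) < tol + 0.02 * direct

    def test_msd_grows_with_donor_count(self):
        # mirrors the saturation curves: more donors, farther migration
        xi = 0.5
        small = estimate_msd(SystemParams.from_xi(10, xi), 80, 5, seed=4)
        large = estimate_msd(SystemParams.from_xi(100, xi), 80, 5, seed=5)
        spread = 3.0 * np.hypot(small.standard_error, large.standard_error)
        assert large.relative_rms > small.relative_rms - spread
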