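import numpy as np
import pytest

from ootrack.geometry import distances_to_cortex
from ootrack.sim import (
    ConfigError,
    DensityGrid,
    StaticRodConfig,
    crescent_score,
    run_cargo_transport,
    sample_static_rods,
)
from ootrack.sim.common import density_from_positions, distances_to_posterior_arc


class TestConfig:
    def test_walker_step_must_fit_capture_radius(self):
        with pytest.raises(ConfigError):
            StaticRodConfig(v_walk=0.47, dt=2.0, capture_radius=0.5).validate()

    def test_epsilon_bounds(self):
        with pytest.raises(ConfigError):
            StaticRodConfig(epsilon=0.0).validate()
        with pytest.raises(ConfigError):
            StaticRodConfig(epsilon=1.2).validate()


class TestRodSampling:
    def test_pre_truncation_mean_length(self, geom):
        cfg = StaticRodConfig(epsilon=0.5, n_mts=10_000)
        rods = sample_static_rods(cfg, geom, seed=3)
        target = 0.5 * geom.L_AP
        se = target / np.sqrt(len(rods))  # exponential: sd = mean
        assert abs(rods.raw_length.mean() - target) < 3 * se

    def test_no_anchor_on_posterior_arc(self, geom):
        cfg = StaticRodConfig(epsilon=0.5, n_mts=2000)
        rods = sample_static_rods(cfg, geom, seed=4)
        assert (distances_to_posterior_arc(rods.anchor, geom) > 0).all()

    def test_majority_of_plus_ends_point_posterior(self, geom):
        cfg = StaticRodConfig(epsilon=0.5, n_mts=5000)
        rods = sample_static_rods(cfg, geom, seed=5)
        frac = float(np.mean(rods.direction @ geom.ap_axis > 0))
        assert frac > 0.5

    def test_tips_inside_or_on_cortex(self, geom):
        rods = sample_static_rods(StaticRodConfig(n_mts=500), geom, seed=6)
        assert geom.contains(rods.tip).all()


class TestCargoTransport:
    def test_frozen_dynamics_leave_cargo_in_place(self, geom):
        cfg = StaticRodConfig(
            n_mts=30, n_cargo=40, v_walk=0.0, D_cyto=0.0, k_unbind=0.0,
            T_total=20.0, dt=1.0, capture_radius=1e-9, seed=1,
        )
        rods = sample_static_rods(cfg, geom, seed=1)
        res = run_cargo_transport(rods, cfg, geom, seed=2)
        res2 = run_cargo_transport(rods, cfg, geom, seed=2)
        assert np.allclose(res.positions, res2.positions)
        assert res.meta["anchored_fraction"] == 0.0

    def test_cargo_count_conserved(self, geom):
        cfg = StaticRodConfig(n_mts=60, n_cargo=80, T_total=120.0, dt=1.0, seed=9)
        rods = sample_static_rods(cfg, geom, seed=9)
        res = run_cargo_transport(rods, cfg, geom, seed=10)
        assert int(res.density.counts.sum()) == 80
        assert len(res.positions) == 80

    def test_determinism_under_fixed_seed(self, geom):
        cfg = StaticRodConfig(n_mts=50, n_cargo=50, T_total=60.0, dt=1.0, seed=12)
        rods = sample_static_rods(cfg, geom)
        a = run_cargo_transport(rods, cfg, geom)
        b = run_cargo_transport(rods, cfg, geom)
        assert np.array_equal(a.positions, b.positions)

    def test_long_rods_deliver_cargo_to_cortex(self, geom):
        """epsilon -> 1 with no unbinding: rods span the cell and nearly all
        cargo ends at the cortex (most of it anchored at the posterior)."""
        cfg = StaticRodConfig(
            epsilon=1.0, k_unbind=0.0, n_mts=200, n_cargo=150,
            T_total=5400.0, dt=1.0, seed=5,
        )
        rods = sample_static_rods(cfg, geom, seed=5)
        res = run_cargo_transport(rods, cfg, geom, seed=6)
        d = distances_to_cortex(res.positions, geom)
        assert np.mean(d <= 2.0) >= 0.9


class TestCrescentScore:
    def test_uniform_density_scores_one(self, geom):
        grid = density_from_positions(np.zeros((0, 2)), geom, cell=1.0)
        counts = np.ones_like(grid.counts)
        uniform = DensityGrid(grid.x_edges, grid.y_edges, counts)
        assert crescent_score(uniform, geom) == pytest.approx(1.0, abs=0.05)

    def test_hand_placed_density_ratio(self, geom):
        """10 particles in shell cells vs 10 spread over 4x the area -> 4.0."""
        grid = density_from_positions(np.zeros((0, 2)), geom, cell=1.0)
        counts = np.zeros_like(grid.counts)
        centers = grid.centers
        inside = geom.contains(centers)
        d_arc = distances_to_posterior_arc(centers, geom)
        proj = centers @ geom.ap_axis
        cortex_proj = geom.cortex @ geom.ap_axis
        thr = cortex_proj.min() + (2.0 / 3.0) * (cortex_proj.max() - cortex_proj.min())
        shell_idx = np.nonzero(inside & (d_arc <= 2.0))[0]
        region_idx = np.nonzero(inside & (proj >= thr) & (d_arc > 2.0))[0]
        n_shell = len(shell_idx)
        n_region = 4 * n_shell
        assert n_region <= len(region_idx)
        flat = counts.ravel()
        flat[shell_idx] = 10.0 / n_shell
        flat[region_idx[:n_region]] = 10.0 / n_region
        score = crescent_score(DensityGrid(grid.x_edges, grid.y_edges, flat.reshape(counts.shape)), geom)
        assert score == pytest.approx(4.0 * len(region_idx) / n_region, rel=1e-9)

    def test_all_cargo_in_shell_gives_inf(self, geom):
        grid = density_from_positions(np.zeros((0, 2)), geom, cell=1.0)
        counts = np.zeros_like(grid.counts)
        centers = grid.centers
        inside = geom.contains(centers)
        d_arc = distances_to_posterior_arc(centers, geom)
        flat = counts.ravel()
        flat[np.nonzero(inside & (d_arc <= 2.0))[0]] = 5.0
        score = crescent_score(DensityGrid(grid.x_edges, grid.y_edges, flat.reshape(counts.shape)), geom)
        assert np.isinf(score)
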