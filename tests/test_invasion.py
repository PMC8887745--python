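"""The 4-move anisotropic random walk."""

import numpy as np
import pytest

from spheroflow import (GridSpec, SimConfig, StepSizes, canonical_field,
                        seed_cells, simulate_invasion, step_sizes, walk_step)


class _FixedMoveRng:
    """Deterministic stand-in drawing always the same move index."""

    def __init__(self, move):
        self.move = move

    def integers(self, lo, hi, n):
        return np.full(n, self.move)


@pytest.fixture(scope="module")
def uniform0():
    return canonical_field("uniform_angle", GridSpec.centered((0, 0), 4, 4),
                           angle_deg=0.0)


@pytest.fixture(scope="module")
def uniform90():
    return canonical_field("uniform_angle", GridSpec.centered((0, 0), 4, 4),
                           angle_deg=90.0)


class TestStepSizes:
    def test_sqrt_scaling_example(self):
        assert step_sizes(220.0, 0.0, 100).k_p == pytest.approx(22.0)

    def test_zero_distance_and_single_step(self):
        assert step_sizes(0.0, 0.0, 50) == StepSizes(0.0, 0.0)
        assert step_sizes(120.0, 60.0, 1) == StepSizes(120.0, 60.0)

    def test_linear_scaling_switch(self):
        assert step_sizes(220.0, 0.0, 100, scaling="linear").k_p == pytest.approx(2.2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            step_sizes(220.0, 0.0, 0)
        with pytest.raises(ValueError):
            step_sizes(-1.0, 0.0, 10)
        with pytest.raises(ValueError):
            step_sizes(1.0, 0.0, 10, scaling="exp")


class TestWalkStep:
    def test_parallel_plus_move_along_alpha_zero(self, uniform0):
        k = StepSizes(k_p=22.0, k_v=0.0)
        nxt = walk_step(np.array([[3.0, 4.0]]), uniform0, k, _FixedMoveRng(0))
        assert np.allclose(nxt, [[3.0 + 22.0, 4.0]])

    def test_four_moves_match_step_equations(self, uniform0):
        # alpha = 0: parallel moves are +-x, perpendicular moves are +-y
        k = StepSizes(k_p=10.0, k_v=4.0)
        expected = {0: (10.0, 0.0), 1: (-10.0, 0.0),
                    2: (0.0, 4.0), 3: (0.0, -4.0)}
        for move, d in expected.items():
            nxt = walk_step(np.zeros((1, 2)), uniform0, k, _FixedMoveRng(move))
            assert np.allclose(nxt, [d], atol=1e-12)

    def test_kv_zero_on_vertical_field_moves_only_vertically(self, uniform90, rng):
        pos = np.zeros((500, 2))
        k = StepSizes(k_p=22.0, k_v=0.0)
        for _ in range(20):
            pos = walk_step(pos, uniform90, k, rng)
        assert np.allclose(pos[:, 0], 0.0, atol=1e-12)
        assert np.abs(pos[:, 1]).max() > 0

    def test_msd_is_N_k_squared_for_equal_steps(self, uniform0, rng):
        n, N, k = 4000, 100, 7.0
        pos = np.zeros((n, 2))
        ks = StepSizes(k, k)
        for _ in range(N):
            pos = walk_step(pos, uniform0, ks, rng)
        msd = (pos**2).sum(axis=1).mean()
        assert msd == pytest.approx(N * k**2, rel=0.1)

    def test_isotropy_when_kp_equals_kv(self, rng):
        grid = canonical_field("radial", GridSpec.centered((0, 0), 8, 8))
        pos = np.zeros((4000, 2)) + [50.0, 0.0]
        ks = StepSizes(10.0, 10.0)
        for _ in range(100):
            pos = walk_step(pos, grid, ks, rng)
        disp = pos - [50.0, 0.0]
        ratio = (disp[:, 0]**2).mean() / (disp[:, 1]**2).mean()
        assert ratio == pytest.approx(1.0, rel=0.1)


class TestSeedCells:
    def test_boundary_mode_radii_exact(self):
        cfg = SimConfig(n_cells=200, radius=150.0, seeding="boundary", seed=1)
        p = seed_cells(cfg)
        assert np.allclose(np.hypot(p[:, 0], p[:, 1]), 150.0)

    def test_disk_mode_mean_radius_two_thirds(self):
        cfg = SimConfig(n_cells=20000, radius=150.0, seeding="disk", seed=1)
        p = seed_cells(cfg)
        assert np.hypot(p[:, 0], p[:, 1]).mean() == pytest.approx(100.0, rel=0.02)

    def test_single_cell_and_offcenter(self):
        cfg = SimConfig(n_cells=1, center=(100.0, -50.0), seeding="boundary")
        p = seed_cells(cfg)
        assert p.shape == (1, 2)
        assert np.hypot(p[0, 0] - 100.0, p[0, 1] + 50.0) == pytest.approx(150.0)


class TestSimulateInvasion:
    def test_zero_step_sizes_keep_cells_static(self, uniform90):
        cfg = SimConfig(r_p=0.0, r_v=0.0, days=2, n_cells=50, seed=5)
        cells = simulate_invasion(cfg, uniform90)
        assert np.array_equal(cells.frames[0], cells.frames[-1])

    def test_deterministic_given_seed(self, uniform90):
        cfg = SimConfig(days=1, n_cells=100, seed=9)
        a = simulate_invasion(cfg, uniform90)
        b = simulate_invasion(cfg, uniform90)
        assert np.array_equal(a.frames, b.frames)

    def test_radial_field_preserves_polar_angles(self):
        grid = canonical_field("radial", GridSpec.centered((0, 0), 8, 8))
        cfg = SimConfig(r_p=50.0, r_v=0.0, days=1, n_cells=500, seed=2)
        cells = simulate_invasion(cfg, grid)
        pol0 = np.arctan2(cells.frames[0][:, 1], cells.frames[0][:, 0])
        pol1 = np.arctan2(cells.frames[-1][:, 1], cells.frames[-1][:, 0])
        # radial motion: angle unchanged modulo a possible flip through 0
        d = np.abs((pol1 - pol0 + np.pi) % (2 * np.pi) - np.pi)
        assert (np.minimum(d, np.pi - d) < 1e-9).all()

    def test_uniform_field_displacement_colinear(self):
        grid = canonical_field("uniform_angle", GridSpec.centered((0, 0), 4, 4),
                               angle_deg=37.0)
        cfg = SimConfig(r_p=100.0, r_v=0.0, days=1, n_cells=200, seed=4)
        cells = simulate_invasion(cfg, grid)
        disp = cells.frames[-1] - cells.frames[0]
        perp = np.array([-np.sin(np.radians(37.0)), np.cos(np.radians(37.0))])
        assert np.abs(disp @ perp).max() < 1e-9

    def test_cell_count_conserved(self, uniform90):
        cfg = SimConfig(days=2, n_cells=123, seed=0)
        cells = simulate_invasion(cfg, uniform90)
        assert cells.frames.shape == (3, 123, 2)

    @pytest.mark.parametrize("N", [25, 100, 400])
    def test_day_statistics_insensitive_to_N_under_sqrt_scaling(self, uniform90, N):
        cfg = SimConfig(r_p=220.0, r_v=0.0, days=1, n_cells=4000, N=N, seed=11)
        cells = simulate_invasion(cfg, uniform90)
        disp = cells.frames[-1] - cells.frames[0]
        # day-1 parallel MSD = r_p^2 / 2 (half the moves are null)
        assert (disp[:, 1]**2).mean() == pytest.approx(220.0**2 / 2, rel=0.1)

    def test_redraw_null_moves_doubles_parallel_diffusivity(self, uniform90):
        base = SimConfig(r_p=220.0, r_v=0.0, days=1, n_cells=4000, seed=12)
        msd = {}
        for redraw in (False, True):
            cells = simulate_invasion(base.with_(redraw_null_moves=redraw),
                                      uniform90)
            disp = cells.frames[-1] - cells.frames[0]
            msd[redraw] = (disp[:, 1]**2).mean()
        assert msd[True] / msd[False] == pytest.approx(2.0, rel=0.1)

    def test_parameter_recovery_from_day1_msd(self, uniform90):
        # estimating r_p from the simulated day-1 parallel MSD recovers the
        # input within the replicate confidence interval
        r_p = 220.0
        est = []
        for s in range(20):
            cfg = SimConfig(r_p=r_p, r_v=0.0, days=1, n_cells=500, seed=100 + s)
            cells = simulate_invasion(cfg, uniform90)
            disp = cells.frames[-1] - cells.frames[0]
            est.append(np.sqrt(2.0 * (disp[:, 1]**2).mean()))
        est = np.asarray(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - r_p) < 3 * se + 1e-9
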