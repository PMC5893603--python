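"""Slab selection, ROI meshing, cell averaging and discrete vorticity."""

import numpy as np
import pytest

from glycoflow import (
    FlowFieldModel,
    GeneratorConfig,
    Observations,
    SlabSpec,
    Trajectory,
    VelocityField,
    grid_velocity_field,
    make_grid,
    sample_frame,
    select_slab,
    vorticity_field,
)

from conftest import ROI, field_at_centers, make_frame


class TestSelectSlab:
    def test_inclusive_halfwidth_boundaries(self):
        pos = np.array([[0, 0, 230.0], [0, 0, 240.0], [0, 0, 251.0]])
        frame = make_frame(0.0, pos, np.zeros((3, 3)))
        traj = Trajectory([frame], 0.1, ((0, 10), (0, 10), (0, 300)))
        obs = select_slab(traj, SlabSpec(240.0, 10.0), (0.0, 1.0))
        assert len(obs) == 2

    def test_observation_count_is_particles_times_frames(self):
        m = FlowFieldModel("uniform", {"ux": 1.0, "uy": 0.0}, thermal_sigma=0.0)
        cfg = GeneratorConfig(
            n_particles=100, box=((0, 50), (0, 50), (100.0, 120.0)), n_frames=10, seed=1
        )
        from glycoflow import generate_trajectory

        traj = generate_trajectory(m, cfg)
        obs = select_slab(traj, SlabSpec(110.0, 10.0), (0.0, 1.0))
        assert len(obs) == 1000  # every particle of every frame is in-slab

    def test_slab_outside_box_yields_empty_valid_result(self, tiny_trajectory):
        obs = select_slab(tiny_trajectory, SlabSpec(1000.0, 5.0), (0.0, 1.0))
        assert len(obs) == 0

    def test_time_window_filters_frames(self, tiny_trajectory):
        obs_all = select_slab(tiny_trajectory, SlabSpec(150.0, 200.0), (0.0, 1.0))
        obs_first = select_slab(tiny_trajectory, SlabSpec(150.0, 200.0), (0.0, 0.05))
        assert len(obs_first) * 2 == len(obs_all)


class TestMakeGrid:
    def test_roi_meshes_into_484_cells(self, roi_grid):
        assert (roi_grid.nx, roi_grid.ny) == (22, 22)
        assert roi_grid.n_cells == 484

    def test_small_grid(self):
        g = make_grid(((0, 16), (0, 9)), 8, 9)
        assert (g.nx, g.ny) == (2, 1)

    def test_non_divisible_extent_rejected_with_remainder(self):
        with pytest.raises(ValueError, match="remainder"):
            make_grid(((0, 10), (0, 9)), 8, 9)


class TestGridVelocityField:
    def test_single_observation_defines_its_cell(self, roi_grid):
        obs = Observations(
            np.array([-87.0]), np.array([-98.0]), np.array([2.0]), np.array([-1.0])
        )
        fld = grid_velocity_field(obs, roi_grid)
        assert fld.mean_vx[0, 0] == 2.0 and fld.mean_vy[0, 0] == -1.0
        assert fld.occupancy[0, 0] == 1
        assert fld.occupancy.sum() == 1

    def test_means_match_direct_recomputation(self, roi_grid, rotation_model):
        # oracle: recompute per-cell means directly from the observation list
        cfg = GeneratorConfig(
            n_particles=20_000, box=(*ROI, (0.0, 10.0)), seed=6
        )
        frame = sample_frame(rotation_model, cfg)
        obs = Observations(
            frame.positions[:, 0], frame.positions[:, 1],
            frame.velocities[:, 0], frame.velocities[:, 1],
        )
        fld = grid_velocity_field(obs, roi_grid)
        ix = np.floor((obs.x + 88.0) / 8.0).astype(int)
        iy = np.floor((obs.y + 99.0) / 9.0).astype(int)
        for ci, cj in [(0, 0), (10, 10), (21, 21), (5, 17)]:
            mask = (ix == ci) & (iy == cj)
            if mask.any():
                assert fld.mean_vx[ci, cj] == pytest.approx(obs.vx[mask].mean())
                assert fld.mean_vy[ci, cj] == pytest.approx(obs.vy[mask].mean())

    def test_upper_boundary_observation_discarded(self, roi_grid):
        obs = Observations(
            np.array([88.0, 0.0]), np.array([0.0, 99.0]),
            np.ones(2), np.ones(2),
        )
        fld = grid_velocity_field(obs, roi_grid)
        assert fld.discarded == 2
        assert fld.occupancy.sum() == 0

    def test_occupancy_conservation(self, roi_grid):
        rng = np.random.default_rng(0)
        obs = Observations(
            rng.uniform(-120, 120, 5000), rng.uniform(-120, 120, 5000),
            rng.normal(size=5000), rng.normal(size=5000),
        )
        fld = grid_velocity_field(obs, roi_grid)
        assert fld.occupancy.sum() + fld.discarded == 5000


class TestVorticity:
    def test_uniform_field_has_zero_vorticity(self, roi_grid, uniform_model):
        fld = field_at_centers(uniform_model, roi_grid)
        w = vorticity_field(fld).w
        assert w.shape == (21, 21)
        np.testing.assert_array_equal(w, np.zeros_like(w))

    def test_rigid_rotation_gives_twice_omega(self, roi_grid, rotation_model):
        # forward differences are exact on affine fields: w = 2*omega in 1/ns
        w = vorticity_field(field_at_centers(rotation_model, roi_grid)).w
        np.testing.assert_allclose(w, 0.1, atol=1e-14)

    def test_shear_gives_minus_gamma(self, roi_grid):
        m = FlowFieldModel("shear", {"gamma": 0.7}, thermal_sigma=0.0)
        w = vorticity_field(field_at_centers(m, roi_grid)).w
        np.testing.assert_allclose(w, -0.7, atol=1e-13)

    def test_irrotational_affine_field_gives_zero(self, roi_grid):
        # gradient field v = (a*x, -a*y) has zero curl
        g = roi_grid
        xc, yc = np.meshgrid(g.x_centers, g.y_centers, indexing="ij")
        fld = VelocityField(g, 0.03 * xc, -0.03 * yc, np.ones_like(xc, int))
        np.testing.assert_allclose(vorticity_field(fld).w, 0.0, atol=1e-14)

    def test_linearity(self, roi_grid, rotation_model):
        m2 = FlowFieldModel("shear", {"gamma": 0.4}, thermal_sigma=0.0)
        f1 = field_at_centers(rotation_model, roi_grid)
        f2 = field_at_centers(m2, roi_grid)
        combo = VelocityField(
            roi_grid,
            2.0 * f1.mean_vx + 3.0 * f2.mean_vx,
            2.0 * f1.mean_vy + 3.0 * f2.mean_vy,
            np.ones_like(f1.occupancy),
        )
        w_combo = vorticity_field(combo).w
        w_expected = 2.0 * vorticity_field(f1).w + 3.0 * vorticity_field(f2).w
        np.testing.assert_allclose(w_combo, w_expected, atol=1e-13)

    def test_missing_cells_propagate(self, roi_grid, uniform_model):
        fld = field_at_centers(uniform_model, roi_grid)
        fld.mean_vx[5, 5] = np.nan
        fld.mean_vy[5, 5] = np.nan
        fld.occupancy[5, 5] = 0
        w = vorticity_field(fld).w
        assert np.isnan(w[5, 5]) and np.isnan(w[4, 5]) and np.isnan(w[5, 4])
        assert np.isfinite(w[6, 6])

    def test_units_conversion_to_per_second(self, roi_grid, rotation_model):
        vort = vorticity_field(field_at_centers(rotation_model, roi_grid))
        np.testing.assert_allclose(vort.w_per_s, vort.w * 1e9)

    def test_grid_too_small_rejected(self):
        g = make_grid(((0, 8), (0, 9)), 8, 9)
        fld = VelocityField(g, np.ones((1, 1)), np.ones((1, 1)), np.ones((1, 1), int))
        with pytest.raises(ValueError, match="2"):
            vorticity_field(fld)
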