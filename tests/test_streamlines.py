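"""Streamline interpolation, integration and length statistics."""

import numpy as np
import pytest

from glycoflow import (
    FlowFieldModel,
    ObstacleDisc,
    VelocityField,
    cell_center_seeds,
    interpolate_velocity,
    random_seeds,
    streamline_lengths,
    trace_streamline,
    trace_streamlines,
)

from conftest import field_at_centers


class TestInterpolation:
    def test_cell_center_returns_cell_mean(self, roi_grid, rotation_model):
        fld = field_at_centers(rotation_model, roi_grid)
        x, y = roi_grid.x_centers[3], roi_grid.y_centers[7]
        assert interpolate_velocity(fld, x, y) == (
            pytest.approx(fld.mean_vx[3, 7]), pytest.approx(fld.mean_vy[3, 7])
        )

    def test_bilinear_reproduces_affine_fields(self, roi_grid, rotation_model):
        fld = field_at_centers(rotation_model, roi_grid)
        rng = np.random.default_rng(1)
        from glycoflow import evaluate_field

        for _ in range(50):
            x = rng.uniform(roi_grid.x_centers[0], roi_grid.x_centers[-1])
            y = rng.uniform(roi_grid.y_centers[0], roi_grid.y_centers[-1])
            vx, vy = interpolate_velocity(fld, x, y)
            ex, ey = evaluate_field(rotation_model, x, y)
            assert vx == pytest.approx(ex, abs=1e-12)
            assert vy == pytest.approx(ey, abs=1e-12)

    def test_missing_contributor_yields_missing(self, roi_grid, uniform_model):
        fld = field_at_centers(uniform_model, roi_grid)
        fld.mean_vx[10, 10] = np.nan
        fld.occupancy[10, 10] = 0
        # a query between centres (10,10) and (11,11) touches the missing cell
        x = 0.5 * (roi_grid.x_centers[10] + roi_grid.x_centers[11])
        y = 0.5 * (roi_grid.y_centers[10] + roi_grid.y_centers[11])
        assert interpolate_velocity(fld, x, y) is None

    def test_outside_roi_rejected(self, roi_grid, uniform_model):
        fld = field_at_centers(uniform_model, roi_grid)
        with pytest.raises(ValueError, match="outside"):
            interpolate_velocity(fld, 200.0, 0.0)


class TestTracing:
    def test_uniform_field_straight_line_of_roi_extent(self, roi_grid, uniform_model):
        fld = field_at_centers(uniform_model, roi_grid)
        s = trace_streamline(fld, (-88.0, 0.0))
        assert s.termination == "exited_roi"
        assert s.length == pytest.approx(176.0, abs=1e-6)
        # maximum perpendicular deviation from the chord
        assert np.max(np.abs(s.points[:, 1])) < 1e-6

    def test_zero_field_stagnates_immediately(self, roi_grid):
        g = roi_grid
        zeros = np.zeros((g.nx, g.ny))
        fld = VelocityField(g, zeros, zeros.copy(), np.ones((g.nx, g.ny), int))
        s = trace_streamline(fld, (0.0, 0.0))
        assert s.termination == "stagnation"
        assert s.length == 0.0

    def test_rigid_rotation_orbit_conserves_radius(self, roi_grid, rotation_model):
        fld = field_at_centers(rotation_model, roi_grid)
        r0 = 60.0
        n = int(np.ceil(2 * np.pi * r0)) + 5
        s = trace_streamline(fld, (r0, 0.0), step=1.0, max_steps=n)
        r = np.hypot(s.points[:, 0], s.points[:, 1])
        assert s.termination == "max_steps"
        assert np.max(np.abs(r - r0)) / r0 < 1e-3

    def test_length_invariant_under_field_rescaling(self, roi_grid, rotation_model):
        fld = field_at_centers(rotation_model, roi_grid)
        scaled = VelocityField(
            roi_grid, 7.5 * fld.mean_vx, 7.5 * fld.mean_vy, fld.occupancy
        )
        s1 = trace_streamline(fld, (30.0, 20.0), step=1.0, max_steps=100)
        s2 = trace_streamline(scaled, (30.0, 20.0), step=1.0, max_steps=100)
        assert s1.length == pytest.approx(s2.length, rel=1e-12)
        np.testing.assert_allclose(s1.points, s2.points, atol=1e-9)

    def test_reversed_field_retraces_the_path(self, roi_grid, rotation_model):
        fld = field_at_centers(rotation_model, roi_grid)
        fwd = trace_streamline(fld, (40.0, 10.0), step=0.5, max_steps=60)
        rev_field = VelocityField(
            roi_grid, -fld.mean_vx, -fld.mean_vy, fld.occupancy
        )
        end = tuple(fwd.points[-1])
        back = trace_streamline(rev_field, end, step=0.5, max_steps=60)
        np.testing.assert_allclose(back.points[-1], fwd.points[0], atol=1e-6)

    def test_seed_in_missing_cell_terminates_with_one_point(self, roi_grid, uniform_model):
        fld = field_at_centers(uniform_model, roi_grid)
        fld.mean_vx[:, :] = np.nan
        fld.mean_vy[:, :] = np.nan
        fld.occupancy[:, :] = 0
        s = trace_streamline(fld, (0.0, 0.0))
        assert s.termination == "missing_data"
        assert s.n_points == 1

    def test_streamline_count_equals_seed_count(self, roi_grid, rotation_model):
        fld = field_at_centers(rotation_model, roi_grid)
        seeds = cell_center_seeds(fld)
        assert len(seeds) == 484
        sset = trace_streamlines(fld, seeds, max_steps=50)
        assert len(sset) == len(seeds)

    def test_random_seeds_lie_inside_roi(self, roi_grid):
        seeds = random_seeds(roi_grid, 100, np.random.default_rng(3))
        assert np.all(seeds[:, 0] >= -88) and np.all(seeds[:, 0] <= 88)
        assert np.all(seeds[:, 1] >= -99) and np.all(seeds[:, 1] <= 99)

    def test_seed_outside_roi_rejected(self, roi_grid, uniform_model):
        fld = field_at_centers(uniform_model, roi_grid)
        with pytest.raises(ValueError, match="seeds"):
            trace_streamline(fld, (100.0, 0.0))


class TestLengths:
    def test_min_points_filter_excludes_degenerate_traces(self, roi_grid, uniform_model):
        fld = field_at_centers(uniform_model, roi_grid)
        fld.mean_vx[0, :] = np.nan  # left column missing -> 1-point streamlines
        fld.mean_vy[0, :] = np.nan
        fld.occupancy[0, :] = 0
        seeds = np.array([[-86.0, 0.0], [0.0, 0.0]])
        sset = trace_streamlines(fld, seeds)
        lengths = streamline_lengths(sset, min_points=2)
        assert len(lengths) == 1

    def test_left_column_seeds_run_to_the_right_boundary(self, roi_grid, uniform_model):
        fld = field_at_centers(uniform_model, roi_grid)
        x0 = roi_grid.x_centers[0]
        seeds = np.column_stack([np.full(22, x0), roi_grid.y_centers])
        sset = trace_streamlines(fld, seeds)
        lengths = streamline_lengths(sset)
        np.testing.assert_allclose(lengths, 88.0 - x0, atol=1e-6)

    def test_all_excluded_warns_and_returns_empty(self, roi_grid):
        g = roi_grid
        zeros = np.zeros((g.nx, g.ny))
        fld = VelocityField(g, zeros, zeros.copy(), np.ones((g.nx, g.ny), int))
        sset = trace_streamlines(fld, np.array([[0.0, 0.0]]))
        with pytest.warns(UserWarning, match="excluded"):
            lengths = streamline_lengths(sset, min_points=2)
        assert lengths.size == 0

    def test_obstacles_shorten_matched_streamlines(self, roi_grid):
        # mirrors the mechanism by which obstacles break streamlines: with
        # identical seeds and settings, full-blockage discs can only shorten
        base = FlowFieldModel("uniform", {"ux": 1.0, "uy": 0.0}, thermal_sigma=0.0)
        discs = [
            ObstacleDisc((0.0, -50.0), 20.0, 0.0),
            ObstacleDisc((20.0, 40.0), 25.0, 0.0),
        ]
        obst = FlowFieldModel("obstacle_slowdown", {"base": base, "discs": discs},
                              thermal_sigma=0.0)
        f_base = field_at_centers(base, roi_grid)
        f_obst = field_at_centers(obst, roi_grid)
        x0 = roi_grid.x_centers[0]
        seeds = np.column_stack([np.full(22, x0), roi_grid.y_centers])
        stagnation = 0.01  # m/s: below this the flow counts as blocked
        l_base = streamline_lengths(
            trace_streamlines(f_base, seeds, stagnation_speed=stagnation)
        )
        l_obst = streamline_lengths(
            trace_streamlines(f_obst, seeds, stagnation_speed=stagnation)
        )
        assert np.all(l_obst <= l_base + 1e-9)
        assert l_obst.mean() < l_base.mean()
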