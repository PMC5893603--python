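import numpy as np
import pytest

from glycoflow import (
    FlowFieldModel,
    GeneratorConfig,
    ParticleFrame,
    Trajectory,
    VelocityField,
    evaluate_field,
    make_grid,
)

ROI = ((-88.0, 88.0), (-99.0, 99.0))


@pytest.fixture
def roi_grid():
    """The canonical 22x22 ROI mesh (8 x 9 Å cells)."""
    return make_grid(ROI, 8.0, 9.0)


def field_at_centers(model: FlowFieldModel, grid) -> VelocityField:
    """Noise-free velocity field sampled exactly at cell centres."""
    xc, yc = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
    vx, vy = evaluate_field(model, xc, yc)
    occ = np.ones_like(vx, dtype=int)
    return VelocityField(grid, np.asarray(vx, float), np.asarray(vy, float), occ)


def make_frame(time=0.0, positions=None, velocities=None, region=None, species=None):
    """Small hand-specified frame with sensible defaults."""
    if positions is None:
        positions = np.array([[0.0, 0.0, 10.0], [1.0, 1.0, 20.0], [2.0, 2.0, 30.0]])
    n = len(positions)
    if velocities is None:
        velocities = np.zeros((n, 3))
    if region is None:
        region = np.array(["ectodomain"] * n, dtype=object)
    if species is None:
        species = np.array(["water-O"] * n, dtype=object)
    return ParticleFrame(time, positions, velocities, species, region)


@pytest.fixture
def tiny_trajectory():
    """Two frames, three particles, dt = 0.1 ns, mixed regions."""
    pos = np.array([[5.0, 5.0, 50.0], [10.0, 10.0, 150.0], [15.0, 15.0, 250.0]])
    vel = np.array([[1.0, 0.0, 0.0], [2.0, 0.5, 0.0], [3.0, -0.5, 0.0]])
    region = np.array(["cytoplasm", "ectodomain", "ectodomain"], dtype=object)
    frames = [
        make_frame(0.0, pos, vel, region),
        make_frame(0.1, pos + 0.5, vel * 1.1, region),
    ]
    return Trajectory(frames, 0.1, ((0.0, 100.0), (0.0, 100.0), (0.0, 300.0)))


@pytest.fixture
def uniform_model():
    return FlowFieldModel("uniform", {"ux": 1.0, "uy": 0.0}, thermal_sigma=0.0)


@pytest.fixture
def rotation_model():
    return FlowFieldModel(
        "rigid_rotation", {"omega": 0.05, "center": (0.0, 0.0)}, thermal_sigma=0.0
    )
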