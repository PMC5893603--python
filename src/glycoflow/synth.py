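"""Synthetic particle-flow generator with known ground truth.

Emulates the statistical structure of a thermostatted water ensemble at
310 K drifting through a box: per-particle velocities are an analytic drift
field evaluated at the particle position plus isotropic Gaussian thermal
noise (Maxwell–Boltzmann per component, sigma = sqrt(kB*T/m) ≈ 378 m/s for
water), so the per-particle signal-to-noise ratio matches the regime where
bulk drift (cm/s–m/s) is buried under thermal motion.  Obstacle-slowdown
fields — a base drift attenuated inside static discs — stand in for the
steric hindrance of flexible sugar chains at the level of the mean field.

Every downstream estimator (bulk velocity, height profile, gridded field,
vorticity, streamlines) can therefore be tested against the analytic field
the generator drew from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trajectory import ParticleFrame, Trajectory
from .units import ANG_PER_NS_TO_M_PER_S, M_PER_S_TO_ANG_PER_NS, WATER_SIGMA_310K

__all__ = [
    "FlowFieldModel",
    "ObstacleDisc",
    "GeneratorConfig",
    "evaluate_field",
    "sample_frame",
    "generate_trajectory",
]

FIELD_KINDS = ("uniform", "shear", "rigid_rotation", "vortex_lattice", "obstacle_slowdown")


@dataclass(frozen=True)
class ObstacleDisc:
    """Static attenuation disc: velocities inside are scaled by ``attenuation``."""

    center: tuple[float, float]  # Å
    radius: float  # Å
    attenuation: float  # in [0, 1]; 0 = full blockage

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("obstacle radius must be positive")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")


@dataclass(frozen=True)
class FlowFieldModel:
    """Analytic planar drift field plus thermal-noise scale.

    ``kind`` selects the parameterisation (all velocities in m/s, lengths Å):

    * ``uniform``: ``ux``, ``uy``.
    * ``shear``: rate ``gamma`` (1/ns); vx = gamma * (y − y0) expressed in
      m/s (1 Å/ns = 0.1 m/s), along the ``axis`` coordinate ("y" or "z").
    * ``rigid_rotation``: angular rate ``omega`` (rad/ns) about ``center``;
      v = omega × r with the same Å/ns → m/s conversion.
    * ``vortex_lattice``: Taylor–Green-style cellular field with ``amplitude``
      (m/s) and ``wavelength`` (Å).
    * ``obstacle_slowdown``: ``base`` field multiplied by each containing
      disc's attenuation factor.

    ``thermal_sigma`` (m/s, per velocity component) controls the Gaussian
    noise added on sampling; ``drift_force_fN`` is bookkeeping metadata for
    the external-force label a trajectory is meant to emulate.
    """

    kind: str
    parameters: dict = field(default_factory=dict)
    thermal_sigma: float = WATER_SIGMA_310K
    drift_force_fN: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in FIELD_KINDS:
            raise ValueError(f"unknown field kind {self.kind!r}; valid: {FIELD_KINDS}")
        if self.thermal_sigma < 0:
            raise ValueError("thermal_sigma must be non-negative")
        if self.kind == "obstacle_slowdown":
            base = self.parameters.get("base")
            if not isinstance(base, FlowFieldModel):
                raise ValueError("obstacle_slowdown requires a 'base' FlowFieldModel")
            for disc in self.parameters.get("discs", ()):
                if not isinstance(disc, ObstacleDisc):
                    raise ValueError("'discs' must contain ObstacleDisc instances")


def evaluate_field(model: FlowFieldModel, x, y, z=None):
    """Ground-truth drift velocity ``(vx, vy)`` in m/s at ``(x, y)`` in Å.

    Accepts scalars or broadcastable arrays; deterministic (no noise).
    A shear field with ``axis="z"`` needs the optional ``z`` coordinate
    (used for height-stratified profiles); planar analyses never pass it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p = model.parameters
    if model.kind == "uniform":
        ux, uy = float(p.get("ux", 0.0)), float(p.get("uy", 0.0))
        vx = np.full(np.broadcast(x, y).shape, ux)
        vy = np.full(np.broadcast(x, y).shape, uy)
    elif model.kind == "shear":
        gamma = float(p["gamma"])  # 1/ns
        origin = float(p.get("origin", 0.0))
        axis = p.get("axis", "y")
        if axis == "y":
            coord = y - origin
        elif axis == "z":
            if z is None:
                raise ValueError("shear with axis='z' needs the z coordinate")
            coord = np.asarray(z, dtype=float) - origin
        else:
            raise ValueError(f"shear axis must be 'y' or 'z', got {axis!r}")
        vx = gamma * coord * ANG_PER_NS_TO_M_PER_S
        vy = np.zeros_like(vx)
    elif model.kind == "rigid_rotation":
        omega = float(p["omega"])  # rad/ns
        cx, cy = p.get("center", (0.0, 0.0))
        vx = -omega * (y - cy) * ANG_PER_NS_TO_M_PER_S
        vy = omega * (x - cx) * ANG_PER_NS_TO_M_PER_S
    elif model.kind == "vortex_lattice":
        amp = float(p["amplitude"])  # m/s
        lam = float(p["wavelength"])  # Å
        k = 2.0 * np.pi / lam
        vx = amp * np.sin(k * x) * np.cos(k * y)
        vy = -amp * np.cos(k * x) * np.sin(k * y)
    elif model.kind == "obstacle_slowdown":
        vx, vy = evaluate_field(p["base"], x, y, z)
        vx = np.array(vx, dtype=float, copy=True)
        vy = np.array(vy, dtype=float, copy=True)
        for disc in p.get("discs", ()):
            cx, cy = disc.center
            inside = (x - cx) ** 2 + (y - cy) ** 2 <= disc.radius**2
            vx = np.where(inside, vx * disc.attenuation, vx)
            vy = np.where(inside, vy * disc.attenuation, vy)
    else:  # pragma: no cover - guarded by __post_init__
        raise ValueError(f"unknown field kind {model.kind!r}")
    if vx.ndim == 0:
        return float(vx), float(vy)
    return vx, vy


@dataclass(frozen=True)
class GeneratorConfig:
    """Size, geometry and reproducibility settings of a synthetic trajectory.

    ``ectodomain_fraction`` is the fraction of box height (from the top)
    labelled ``ectodomain``; the remainder is ``cytoplasm``, mirroring the
    two compartments separated by the lipid bilayer.  ``drift_off_time``
    (ns), if set, switches the drift field off from that time onward — the
    force-release schedule of a "starting N ns only" forcing case.
    """

    n_particles: int
    box: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    n_frames: int = 1
    frame_interval: float = 0.1  # ns, the canonical sampling interval
    seed: int = 0
    ectodomain_fraction: float = 0.75
    mode: str = "advect"  # or "resample": i.i.d. positions every frame
    drift_off_time: float | None = None

    def __post_init__(self) -> None:
        if self.n_particles <= 0:
            raise ValueError("n_particles must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not 0.0 <= self.ectodomain_fraction <= 1.0:
            raise ValueError("ectodomain_fraction must lie in [0, 1]")
        if self.mode not in ("advect", "resample"):
            raise ValueError("mode must be 'advect' or 'resample'")


def _region_labels(z: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    (z0, z1) = config.box[2]
    threshold = z1 - config.ectodomain_fraction * (z1 - z0)
    labels = np.where(z >= threshold, "ectodomain", "cytoplasm")
    return labels.astype(object)


def _drift_active(model: FlowFieldModel, config: GeneratorConfig, time: float) -> bool:
    return config.drift_off_time is None or time < config.drift_off_time


def _frame_from_positions(
    model: FlowFieldModel,
    config: GeneratorConfig,
    time: float,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> ParticleFrame:
    n = config.n_particles
    if _drift_active(model, config, time):
        vx, vy = evaluate_field(model, positions[:, 0], positions[:, 1], positions[:, 2])
    else:
        vx = np.zeros(n)
        vy = np.zeros(n)
    velocities = np.column_stack([vx, vy, np.zeros(n)])
    if model.thermal_sigma > 0:
        velocities = velocities + rng.normal(0.0, model.thermal_sigma, size=(n, 3))
    species = np.full(n, "water-O", dtype=object)
    region = _region_labels(positions[:, 2], config)
    return ParticleFrame(time, positions, velocities, species, region)


def _uniform_positions(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    lo = np.array([ax[0] for ax in config.box])
    hi = np.array([ax[1] for ax in config.box])
    return lo + rng.random((config.n_particles, 3)) * (hi - lo)


def sample_frame(
    model: FlowFieldModel,
    config: GeneratorConfig,
    time: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ParticleFrame:
    """Draw one frame: uniform positions, field + Gaussian noise velocities."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    positions = _uniform_positions(config, rng)
    return _frame_from_positions(model, config, time, positions, rng)


def generate_trajectory(model: FlowFieldModel, config: GeneratorConfig) -> Trajectory:
    """Generate ``config.n_frames`` frames, reproducible from ``config.seed``.

    In ``advect`` mode particle positions follow the local drift between
    frames (x += v_drift * dt, wrapped periodically into the box); in
    ``resample`` mode positions are redrawn i.i.d. uniform every frame.
    Velocities are re-sampled (field + fresh noise) each frame either way.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([ax[0] for ax in config.box])
    span = np.array([ax[1] - ax[0] for ax in config.box])
    positions = _uniform_positions(config, rng)
    frames = []
    for k in range(config.n_frames):
        time = k * config.frame_interval
        if config.mode == "resample" and k > 0:
            positions = _uniform_positions(config, rng)
        frames.append(_frame_from_positions(model, config, time, positions, rng))
        if config.mode == "advect" and k + 1 < config.n_frames:
            if _drift_active(model, config, time):
                vx, vy = evaluate_field(model, positions[:, 0], positions[:, 1], positions[:, 2])
                step = np.column_stack([vx, vy, np.zeros(config.n_particles)])
                positions = positions + step * config.frame_interval * M_PER_S_TO_ANG_PER_NS
                positions = lo + np.mod(positions - lo, span)
    return Trajectory(frames, config.frame_interval, config.box)
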