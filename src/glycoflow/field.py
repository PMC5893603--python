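"""Slab selection, ROI meshing, per-cell velocity averaging and discrete vorticity.

Planar analysis proceeds in three steps: collect all (particle, frame)
observations inside a horizontal slab (canonically 24 ± 1 nm above the
ectodomain origin) over a time window; mesh the region of interest
(canonically x ∈ [−88, 88] Å, y ∈ [−99, 99] Å at 8 × 9 Å cells, 484 cells)
and average vx, vy per cell; then estimate the z-component of the curl by
forward differences on the cell lattice,

    w[i, j] = (vy[i+1, j] − vy[i, j]) / Δx − (vx[i, j+1] − vx[i, j]) / Δy,

which is exact for fields affine in (x, y) evaluated at cell centres.
Vorticity is carried internally in 1/ns; a converter to 1/s is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory
from .units import GRAD_M_PER_S_PER_ANG_TO_PER_NS, PER_NS_TO_PER_S

__all__ = [
    "SlabSpec",
    "GridSpec",
    "Observations",
    "VelocityField",
    "VorticityField",
    "select_slab",
    "make_grid",
    "grid_velocity_field",
    "vorticity_field",
]

_DIV_TOL = 1e-9


@dataclass(frozen=True)
class SlabSpec:
    """Horizontal analysis slab: |z − z_center| ≤ z_halfwidth (Å)."""

    z_center: float
    z_halfwidth: float

    def __post_init__(self) -> None:
        if self.z_halfwidth <= 0:
            raise ValueError("z_halfwidth must be positive")


@dataclass(frozen=True)
class GridSpec:
    """Uniform rectangular mesh of the planar ROI.

    The extents must be integer multiples of the cell sides (within 1e-9),
    otherwise construction fails with the offending remainder.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("grid extents must be positive")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sides must be positive")
        for name, extent, step in (
            ("x", self.x_max - self.x_min, self.dx),
            ("y", self.y_max - self.y_min, self.dy),
        ):
            ratio = extent / step
            if abs(ratio - round(ratio)) > _DIV_TOL * max(1.0, ratio):
                remainder = extent - round(extent / step - 0.5) * step
                raise ValueError(
                    f"{name} extent {extent} is not divisible by d{name}={step} "
                    f"(remainder {remainder:g})"
                )

    @property
    def nx(self) -> int:
        return round((self.x_max - self.x_min) / self.dx)

    @property
    def ny(self) -> int:
        return round((self.y_max - self.y_min) / self.dy)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_min + (np.arange(self.ny) + 0.5) * self.dy


@dataclass
class Observations:
    """Flat set of planar (particle, frame) observations: x, y (Å), vx, vy (m/s)."""

    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class VelocityField:
    """Per-cell mean planar velocities with occupancy counts.

    ``mean_vx``/``mean_vy`` are ``(nx, ny)`` arrays in m/s, NaN where the
    cell received no observation; ``occupancy`` counts observations per cell;
    ``discarded`` counts observations outside the ROI.
    """

    grid: GridSpec
    mean_vx: np.ndarray
    mean_vy: np.ndarray
    occupancy: np.ndarray
    time_span: tuple[float, float] | None = None
    discarded: int = 0

    def defined_mask(self) -> np.ndarray:
        return self.occupancy > 0


@dataclass
class VorticityField:
    """Forward-difference vorticity on the (nx−1) × (ny−1) interior lattice.

    ``w`` is in 1/ns, NaN where any stencil cell was undefined.
    """

    grid: GridSpec
    w: np.ndarray

    @property
    def w_per_s(self) -> np.ndarray:
        return self.w * PER_NS_TO_PER_S

    def samples(self) -> np.ndarray:
        """Defined vorticity values as a flat sample (1/ns)."""
        return self.w[np.isfinite(self.w)]


def select_slab(
    traj: Trajectory, slab: SlabSpec, time_window: tuple[float, float]
) -> Observations:
    """All (particle, frame) observations with |z − z_center| ≤ z_halfwidth
    and frame time inside ``time_window`` (both ends inclusive).

    An empty result is valid — sparse occupancy is expected at nanoscale.
    """
    t0, t1 = time_window
    xs, ys, vxs, vys = [], [], [], []
    for frame in traj.frames:
        if frame.time < t0 - 1e-12 or frame.time > t1 + 1e-12:
            continue
        z = frame.positions[:, 2]
        mask = np.abs(z - slab.z_center) <= slab.z_halfwidth
        xs.append(frame.positions[mask, 0])
        ys.append(frame.positions[mask, 1])
        vxs.append(frame.velocities[mask, 0])
        vys.append(frame.velocities[mask, 1])
    if not xs:
        empty = np.empty(0)
        return Observations(empty, empty.copy(), empty.copy(), empty.copy())
    return Observations(
        np.concatenate(xs), np.concatenate(ys), np.concatenate(vxs), np.concatenate(vys)
    )


def make_grid(
    roi: tuple[tuple[float, float], tuple[float, float]], dx: float, dy: float
) -> GridSpec:
    """Mesh ``roi = ((x_min, x_max), (y_min, y_max))`` into dx × dy cells."""
    (x0, x1), (y0, y1) = roi
    return GridSpec(x0, x1, y0, y1, dx, dy)


def grid_velocity_field(
    obs: Observations,
    grid: GridSpec,
    time_span: tuple[float, float] | None = None,
) -> VelocityField:
    """Assign observations to half-open cells and average vx, vy per cell.

    Cells are ``[x_i, x_{i+1}) × [y_j, y_{j+1})``; observations at the upper
    ROI boundary (or outside) are discarded and counted in ``discarded``.
    """
    nx, ny = grid.nx, grid.ny
    ix = np.floor((obs.x - grid.x_min) / grid.dx).astype(int)
    iy = np.floor((obs.y - grid.y_min) / grid.dy).astype(int)
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    flat = ix[ok] * ny + iy[ok]
    counts = np.bincount(flat, minlength=nx * ny)
    sum_vx = np.bincount(flat, weights=obs.vx[ok], minlength=nx * ny)
    sum_vy = np.bincount(flat, weights=obs.vy[ok], minlength=nx * ny)
    with np.errstate(invalid="ignore"):
        mean_vx = np.where(counts > 0, sum_vx / np.maximum(counts, 1), np.nan)
        mean_vy = np.where(counts > 0, sum_vy / np.maximum(counts, 1), np.nan)
    return VelocityField(
        grid=grid,
        mean_vx=mean_vx.reshape(nx, ny),
        mean_vy=mean_vy.reshape(nx, ny),
        occupancy=counts.reshape(nx, ny),
        time_span=time_span,
        discarded=int(len(obs) - ok.sum()),
    )


def vorticity_field(field: VelocityField) -> VorticityField:
    """Forward-difference curl estimate on the interior lattice, 1/ns.

    Defined only where the cell itself and both forward neighbours are
    occupied; missing cells propagate (no zero-filling, since zero vorticity
    is physically meaningful).
    """
    grid = field.grid
    if grid.nx < 2 or grid.ny < 2:
        raise ValueError("vorticity needs a grid of at least 2×2 cells")
    vx, vy = field.mean_vx, field.mean_vy
    dvy_dx = (vy[1:, :-1] - vy[:-1, :-1]) / grid.dx
    dvx_dy = (vx[:-1, 1:] - vx[:-1, :-1]) / grid.dy
    w = (dvy_dx - dvx_dy) * GRAD_M_PER_S_PER_ANG_TO_PER_NS
    return VorticityField(grid=grid, w=w)
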