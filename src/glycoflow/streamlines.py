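"""Streamline integration through a cell-averaged planar velocity field.

Streamlines are integrated with classical 4th-order Runge–Kutta in
*arc-length* parameterisation, dX/ds = v(X)/|v(X)|, so the analysed length
is purely geometric and invariant under rescaling of the field magnitude.
Cell-mean velocities are treated as point values at cell centres and
interpolated bilinearly; within half a cell of the ROI boundary the query
clamps onto the centre lattice, which reduces to the nearest-cell value in
the normal direction.  A trace terminates when it exits the ROI (final point
clipped to the boundary), when the local speed falls to the stagnation
threshold, when interpolation hits an unoccupied cell, or at the step cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .field import GridSpec, VelocityField

__all__ = [
    "Streamline",
    "StreamlineSet",
    "interpolate_velocity",
    "trace_streamline",
    "trace_streamlines",
    "streamline_lengths",
    "cell_center_seeds",
    "random_seeds",
]

TERMINATIONS = ("exited_roi", "max_steps", "stagnation", "missing_data")


@dataclass
class Streamline:
    """Integrated polyline with its arc length (Å)."""

    points: np.ndarray  # (p, 2), p >= 1
    seed: tuple[float, float]
    termination: str
    length: float = dataclass_field(init=False)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1 or self.points.shape[1] != 2:
            raise ValueError("a streamline needs at least one (x, y) point")
        if self.termination not in TERMINATIONS:
            raise ValueError(f"unknown termination {self.termination!r}")
        segs = np.diff(self.points, axis=0)
        self.length = float(np.hypot(segs[:, 0], segs[:, 1]).sum())

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class StreamlineSet:
    """A collection of streamlines plus the settings that produced them."""

    streamlines: list[Streamline]
    step: float
    max_steps: int
    stagnation_speed: float

    def __len__(self) -> int:
        return len(self.streamlines)


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------


def _interp_batch(fld: VelocityField, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear velocity at each point; returns ``(v, missing)``.

    Cells with zero bilinear weight do not count as contributors, so a query
    exactly at an occupied cell centre returns that cell's mean even when a
    neighbour is unoccupied.
    """
    g = fld.grid
    nx, ny = g.nx, g.ny
    gx = np.clip((pts[:, 0] - (g.x_min + 0.5 * g.dx)) / g.dx, 0.0, nx - 1.0)
    gy = np.clip((pts[:, 1] - (g.y_min + 0.5 * g.dy)) / g.dy, 0.0, ny - 1.0)
    i = np.clip(np.floor(gx).astype(int), 0, max(nx - 2, 0))
    j = np.clip(np.floor(gy).astype(int), 0, max(ny - 2, 0))
    tx = np.clip(gx - i, 0.0, 1.0)
    ty = np.clip(gy - j, 0.0, 1.0)
    i1 = np.minimum(i + 1, nx - 1)
    j1 = np.minimum(j + 1, ny - 1)
    weights = [(1 - tx) * (1 - ty), tx * (1 - ty), (1 - tx) * ty, tx * ty]
    cells = [(i, j), (i1, j), (i, j1), (i1, j1)]
    v = np.zeros((len(pts), 2))
    missing = np.zeros(len(pts), dtype=bool)
    for w, (ci, cj) in zip(weights, cells):
        cvx = fld.mean_vx[ci, cj]
        cvy = fld.mean_vy[ci, cj]
        contributes = w > 0.0
        missing |= contributes & ~np.isfinite(cvx)
        v[:, 0] += np.where(contributes, w * np.nan_to_num(cvx), 0.0)
        v[:, 1] += np.where(contributes, w * np.nan_to_num(cvy), 0.0)
    return v, missing


def interpolate_velocity(fld: VelocityField, x: float, y: float):
    """Velocity (m/s) at ``(x, y)``, or ``None`` where data is missing.

    Raises ``ValueError`` for points outside the ROI.
    """
    g = fld.grid
    if not (g.x_min <= x <= g.x_max and g.y_min <= y <= g.y_max):
        raise ValueError(f"point ({x}, {y}) lies outside the ROI")
    v, missing = _interp_batch(fld, np.array([[x, y]], dtype=float))
    if missing[0]:
        return None
    return float(v[0, 0]), float(v[0, 1])


# ---------------------------------------------------------------------------
# tracing
# ---------------------------------------------------------------------------


def _clip_to_boundary(p: np.ndarray, q: np.ndarray, g: GridSpec) -> np.ndarray:
    """First intersection of segment p→q with the ROI rectangle boundary."""
    t_exit = 1.0
    for axis, lo, hi in ((0, g.x_min, g.x_max), (1, g.y_min, g.y_max)):
        d = q[axis] - p[axis]
        if d > 0 and q[axis] > hi:
            t_exit = min(t_exit, (hi - p[axis]) / d)
        elif d < 0 and q[axis] < lo:
            t_exit = min(t_exit, (lo - p[axis]) / d)
    return p + t_exit * (q - p)


def _default_stagnation_speed(fld: VelocityField) -> float:
    mask = fld.defined_mask()
    if not mask.any():
        return 0.0
    rms = float(np.sqrt(np.mean(fld.mean_vx[mask] ** 2 + fld.mean_vy[mask] ** 2)))
    return 1e-6 * rms


def trace_streamlines(
    fld: VelocityField,
    seeds: np.ndarray,
    step: float | None = None,
    max_steps: int | None = None,
    stagnation_speed: float | None = None,
) -> StreamlineSet:
    """Trace one streamline per seed point (all seeds must lie in the ROI).

    Defaults: ``step`` = min(dx, dy)/4 (resolves cell-scale curvature),
    ``max_steps`` = 10 × ROI perimeter / step (caps closed orbits),
    ``stagnation_speed`` = 1e-6 × RMS speed of the occupied cells.
    """
    g = fld.grid
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if seeds.shape[1] != 2:
        raise ValueError("seeds must be (n, 2)")
    inside = (
        (seeds[:, 0] >= g.x_min)
        & (seeds[:, 0] <= g.x_max)
        & (seeds[:, 1] >= g.y_min)
        & (seeds[:, 1] <= g.y_max)
    )
    if not inside.all():
        raise ValueError("all seeds must lie inside the ROI")
    if step is None:
        step = min(g.dx, g.dy) / 4.0
    if step <= 0:
        raise ValueError("step must be positive")
    perimeter = 2.0 * ((g.x_max - g.x_min) + (g.y_max - g.y_min))
    if max_steps is None:
        max_steps = int(10.0 * perimeter / step)
    if stagnation_speed is None:
        stagnation_speed = _default_stagnation_speed(fld)

    m = seeds.shape[0]
    pos = seeds.copy()
    points: list[list[np.ndarray]] = [[pos[k].copy()] for k in range(m)]
    termination = np.array([""] * m, dtype=object)
    active = np.ones(m, dtype=bool)

    def clamp(p: np.ndarray) -> np.ndarray:
        out = p.copy()
        out[:, 0] = np.clip(out[:, 0], g.x_min, g.x_max)
        out[:, 1] = np.clip(out[:, 1], g.y_min, g.y_max)
        return out

    for _ in range(max_steps):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        p = pos[idx]
        # evaluate the four RK4 slopes; a missing or stagnant evaluation at
        # any substep terminates the trace at the current point
        dead_missing = np.zeros(idx.size, dtype=bool)
        dead_stagnant = np.zeros(idx.size, dtype=bool)
        slopes = []
        for offset in (None, 0.5, 0.5, 1.0):
            if offset is None:
                q = p
            else:
                q = clamp(p + offset * step * slopes[-1])
            v, miss = _interp_batch(fld, q)
            speed = np.hypot(v[:, 0], v[:, 1])
            dead_missing |= miss
            dead_stagnant |= ~miss & (speed <= stagnation_speed)
            dead = dead_missing | dead_stagnant
            speed_safe = np.where(dead | (speed == 0.0), 1.0, speed)
            slopes.append(v / speed_safe[:, None])
        termination[idx[dead_missing]] = "missing_data"
        termination[idx[dead_stagnant & ~dead_missing]] = "stagnation"
        active[idx[dead_missing | dead_stagnant]] = False

        live = ~(dead_missing | dead_stagnant)
        if not live.any():
            continue
        li = idx[live]
        k1, k2, k3, k4 = (s[live] for s in slopes)
        new_p = pos[li] + (step / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        outside = (
            (new_p[:, 0] < g.x_min)
            | (new_p[:, 0] > g.x_max)
            | (new_p[:, 1] < g.y_min)
            | (new_p[:, 1] > g.y_max)
        )
        for row, k in enumerate(li):
            q = new_p[row]
            if outside[row]:
                q = _clip_to_boundary(pos[k], q, g)
                termination[k] = "exited_roi"
                active[k] = False
            pos[k] = q
            points[k].append(q.copy())
    termination[active] = "max_steps"

    streamlines = [
        Streamline(np.array(points[k]), (float(seeds[k, 0]), float(seeds[k, 1])), str(termination[k]))
        for k in range(m)
    ]
    return StreamlineSet(streamlines, float(step), int(max_steps), float(stagnation_speed))


def trace_streamline(
    fld: VelocityField,
    seed: tuple[float, float],
    step: float | None = None,
    max_steps: int | None = None,
    stagnation_speed: float | None = None,
) -> Streamline:
    """Trace a single streamline from ``seed``; see :func:`trace_streamlines`."""
    sset = trace_streamlines(fld, np.array([seed]), step, max_steps, stagnation_speed)
    return sset.streamlines[0]


# ---------------------------------------------------------------------------
# seeding and length extraction
# ---------------------------------------------------------------------------


def cell_center_seeds(fld: VelocityField, occupied_only: bool = True) -> np.ndarray:
    """One seed per (occupied) grid cell centre — configuration-independent
    seeding that keeps streamline counts comparable across cases."""
    g = fld.grid
    xc, yc = np.meshgrid(g.x_centers, g.y_centers, indexing="ij")
    seeds = np.column_stack([xc.ravel(), yc.ravel()])
    if occupied_only:
        seeds = seeds[fld.defined_mask().ravel()]
    return seeds


def random_seeds(grid: GridSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` uniform random seeds inside the ROI."""
    x = grid.x_min + rng.random(n) * (grid.x_max - grid.x_min)
    y = grid.y_min + rng.random(n) * (grid.y_max - grid.y_min)
    return np.column_stack([x, y])


def streamline_lengths(sset: StreamlineSet, min_points: int = 2) -> np.ndarray:
    """Arc lengths (Å) of streamlines with at least ``min_points`` points.

    Degenerate one-point traces (seeds that immediately stagnated or hit
    missing data) are excluded by default; if everything is excluded an empty
    array is returned with a warning.
    """
    lengths = np.array(
        [s.length for s in sset.streamlines if s.n_points >= min_points]
    )
    if lengths.size == 0:
        warnings.warn("all streamlines excluded by the min_points filter", stacklevel=2)
    return lengths
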