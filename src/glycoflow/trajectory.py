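"""Core particle-trajectory data types and readers/writers.

A :class:`ParticleFrame` holds one snapshot of per-particle positions (Å),
velocities (m/s), species labels and region labels; a :class:`Trajectory` is a
uniformly sampled, time-ordered sequence of frames inside a rectangular box.

Two on-disk representations are supported:

* an extended-XYZ-style text format — one block per frame: a particle-count
  line, a ``key=value`` metadata line (``time``, ``box``, ``columns``), then
  one row per particle ``species x y z vx vy vz region``;
* a binary cache (numpy ``.npz``) that round-trips bit-exactly and is meant
  for fast re-analysis of large trajectories.
"""

from __future__ import annotations

import shlex
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "REGION_LABELS",
    "ParticleFrame",
    "Trajectory",
    "RegionSpec",
    "TrajectoryParseError",
    "TrajectoryStructureError",
    "read_trajectory",
    "write_trajectory",
    "select_region",
]

#: The region vocabulary: lumen-side ectodomain (where flow is driven),
#: cytoplasm below the bilayer, and everything excluded from analysis.
REGION_LABELS: tuple[str, ...] = ("ectodomain", "cytoplasm", "excluded")

_TIME_TOL_NS = 1e-9


class TrajectoryParseError(ValueError):
    """A frame could not be parsed; the message names the frame index."""


class TrajectoryStructureError(ValueError):
    """Frames are mutually inconsistent (particle count, ordering, timing)."""


@dataclass
class ParticleFrame:
    """One trajectory snapshot.

    Parameters
    ----------
    time
        Frame timestamp in ns; finite and non-negative.
    positions
        ``(n, 3)`` float array, Å.
    velocities
        ``(n, 3)`` float array, m/s, same particle ordering as ``positions``.
    species
        Length-``n`` array of categorical labels (e.g. ``"water-O"``).
    region
        Length-``n`` array of labels drawn from :data:`REGION_LABELS`.
    """

    time: float
    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    region: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.species = np.asarray(self.species, dtype=object)
        self.region = np.asarray(self.region, dtype=object)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if self.velocities.shape != self.positions.shape:
            raise ValueError("velocities must match positions in shape")
        n = self.positions.shape[0]
        if self.species.shape != (n,) or self.region.shape != (n,):
            raise ValueError("species and region must be length-n 1D arrays")
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError("frame time must be finite and non-negative")
        unknown = set(map(str, self.region)) - set(REGION_LABELS)
        if unknown:
            raise ValueError(
                f"unknown region labels {sorted(unknown)}; valid: {list(REGION_LABELS)}"
            )

    @property
    def particle_count(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Time-ordered frames with uniform spacing inside a rectangular box.

    ``box`` is ``((x0, x1), (y0, y1), (z0, z1))`` in Å.
    """

    frames: list[ParticleFrame]
    frame_interval: float
    box: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        box = tuple(tuple(float(v) for v in ax) for ax in self.box)
        if len(box) != 3 or any(len(ax) != 2 or ax[1] <= ax[0] for ax in box):
            raise ValueError("box must be three (lo, hi) pairs with hi > lo")
        self.box = box  # type: ignore[assignment]
        n0 = self.frames[0].particle_count
        for i, fr in enumerate(self.frames):
            if fr.particle_count != n0:
                raise TrajectoryStructureError(
                    f"frame {i} has {fr.particle_count} particles, frame 0 has {n0}"
                )
        times = np.array([fr.time for fr in self.frames])
        if len(times) > 1:
            if np.any(np.diff(times) <= 0):
                raise TrajectoryStructureError("frame times must strictly increase")
            if np.any(np.abs(np.diff(times) - self.frame_interval) > _TIME_TOL_NS):
                raise TrajectoryStructureError(
                    "frame spacing must equal frame_interval within 1e-9 ns"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def particle_count(self) -> int:
        return self.frames[0].particle_count

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])


@dataclass
class RegionSpec:
    """Geometry of the ectodomain analysis region.

    ``z_origin`` is the height origin (Å) from which stratified profiles are
    measured; ``z_extent`` its vertical extent.  ``force_zone``, if given, is a
    rectangular sub-box ``((x0,x1),(y0,y1),(z0,z1))`` where drift is imposed.
    """

    z_origin: float
    z_extent: float
    force_zone: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.z_extent <= 0:
            raise ValueError("z_extent must be positive")

    def validate_within(self, box: Sequence[Sequence[float]]) -> None:
        if self.force_zone is None:
            return
        for (lo, hi), (blo, bhi) in zip(self.force_zone, box):
            if lo < blo or hi > bhi:
                raise ValueError("force_zone must lie within the box")


# ---------------------------------------------------------------------------
# extended-XYZ dialect
# ---------------------------------------------------------------------------

_COLUMNS = "species:x:y:z:vx:vy:vz:region"


def _format_frame(fr: ParticleFrame, box) -> str:
    (x0, x1), (y0, y1), (z0, z1) = box
    lines = [str(fr.particle_count)]
    lines.append(
        f'time={fr.time!r} box="{x0!r} {x1!r} {y0!r} {y1!r} {z0!r} {z1!r}" '
        f"columns={_COLUMNS}"
    )
    for i in range(fr.particle_count):
        x, y, z = fr.positions[i]
        vx, vy, vz = fr.velocities[i]
        lines.append(
            f"{fr.species[i]} {x:.10g} {y:.10g} {z:.10g} "
            f"{vx:.10g} {vy:.10g} {vz:.10g} {fr.region[i]}"
        )
    return "\n".join(lines)


def _parse_metadata(line: str, frame_index: int) -> dict:
    meta = {}
    try:
        for token in shlex.split(line):
            if "=" not in token:
                raise ValueError(f"metadata token {token!r} is not key=value")
            key, value = token.split("=", 1)
            meta[key] = value
    except ValueError as exc:
        raise TrajectoryParseError(f"frame {frame_index}: bad metadata line ({exc})")
    return meta


def _read_extxyz(path: Path) -> Trajectory:
    text = path.read_text()
    lines = text.splitlines()
    frames: list[ParticleFrame] = []
    box = None
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        idx = len(frames)
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise TrajectoryParseError(
                f"frame {idx}: expected particle count, got {lines[pos]!r}"
            )
        if pos + 1 >= len(lines):
            raise TrajectoryParseError(f"frame {idx}: missing metadata line")
        meta = _parse_metadata(lines[pos + 1], idx)
        for key in ("time", "box"):
            if key not in meta:
                raise TrajectoryParseError(f"frame {idx}: metadata lacks {key!r}")
        if meta.get("columns", _COLUMNS) != _COLUMNS:
            raise TrajectoryParseError(
                f"frame {idx}: unsupported columns declaration {meta['columns']!r}"
            )
        try:
            time = float(meta["time"])
            bvals = [float(v) for v in meta["box"].split()]
            if len(bvals) != 6:
                raise ValueError("box needs 6 numbers")
        except ValueError as exc:
            raise TrajectoryParseError(f"frame {idx}: bad metadata values ({exc})")
        frame_box = ((bvals[0], bvals[1]), (bvals[2], bvals[3]), (bvals[4], bvals[5]))
        if box is None:
            box = frame_box
        rows = lines[pos + 2 : pos + 2 + n]
        if len(rows) < n:
            raise TrajectoryParseError(
                f"frame {idx}: expected {n} particle rows, found {len(rows)}"
            )
        positions = np.empty((n, 3))
        velocities = np.empty((n, 3))
        species = np.empty(n, dtype=object)
        region = np.empty(n, dtype=object)
        for i, row in enumerate(rows):
            parts = row.split()
            if len(parts) != 8:
                raise TrajectoryParseError(
                    f"frame {idx}: particle row {i} has {len(parts)} fields, expected 8"
                )
            species[i] = parts[0]
            try:
                positions[i] = [float(v) for v in parts[1:4]]
                velocities[i] = [float(v) for v in parts[4:7]]
            except ValueError as exc:
                raise TrajectoryParseError(f"frame {idx}: particle row {i}: {exc}")
            region[i] = parts[7]
        try:
            frames.append(ParticleFrame(time, positions, velocities, species, region))
        except ValueError as exc:
            raise TrajectoryParseError(f"frame {idx}: {exc}")
        pos += 2 + n
    if not frames:
        raise TrajectoryParseError("file contains no frames")
    if len(frames) > 1:
        interval = frames[1].time - frames[0].time
    else:
        interval = 0.1  # canonical sampling interval when a single frame is stored
    return Trajectory(frames, interval, box)


# ---------------------------------------------------------------------------
# binary cache (npz)
# ---------------------------------------------------------------------------


def _write_cache(traj: Trajectory, path: Path) -> None:
    species = np.asarray(traj.frames[0].species, dtype="U32")
    region = np.stack([np.asarray(fr.region, dtype="U16") for fr in traj.frames])
    np.savez(
        path,
        times=traj.times,
        positions=np.stack([fr.positions for fr in traj.frames]),
        velocities=np.stack([fr.velocities for fr in traj.frames]),
        species=species,
        region=region,
        frame_interval=np.array(traj.frame_interval),
        box=np.array(traj.box, dtype=float),
    )


def _read_cache(path: Path) -> Trajectory:
    with np.load(path, allow_pickle=False) as data:
        times = data["times"]
        positions = data["positions"]
        velocities = data["velocities"]
        species = data["species"].astype(object)
        region = data["region"].astype(object)
        interval = float(data["frame_interval"])
        box = tuple(tuple(ax) for ax in data["box"])
    frames = [
        ParticleFrame(float(times[k]), positions[k], velocities[k], species, region[k])
        for k in range(len(times))
    ]
    return Trajectory(frames, interval, box)


# ---------------------------------------------------------------------------
# public I/O surface
# ---------------------------------------------------------------------------


def read_trajectory(path: str | Path, format: str = "extxyz") -> Trajectory:
    """Read a trajectory from ``path`` in the named format.

    ``format`` is ``"extxyz"`` (text) or ``"cache"`` (binary npz).  Units are
    the package convention on return: Å, ns, m/s.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "extxyz":
        return _read_extxyz(path)
    if format == "cache":
        return _read_cache(path)
    raise ValueError(f"unknown format {format!r}; expected 'extxyz' or 'cache'")


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "extxyz") -> Path:
    """Write ``traj`` to ``path``; lossless for ``cache``, ~1e-10 relative for text."""
    path = Path(path)
    if format == "extxyz":
        blocks = [_format_frame(fr, traj.box) for fr in traj.frames]
        path.write_text("\n".join(blocks) + "\n")
    elif format == "cache":
        _write_cache(traj, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'extxyz' or 'cache'")
    return path


def select_region(frame: ParticleFrame, region: str) -> ParticleFrame:
    """Return the sub-frame of particles carrying ``region``, order preserved."""
    if region not in REGION_LABELS:
        raise ValueError(
            f"unknown region {region!r}; valid labels: {list(REGION_LABELS)}"
        )
    mask = np.array([r == region for r in frame.region], dtype=bool)
    return ParticleFrame(
        frame.time,
        frame.positions[mask],
        frame.velocities[mask],
        frame.species[mask],
        frame.region[mask],
    )
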