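"""Temporal bulk-velocity series and height-stratified velocity profiles.

The bulk flow velocity of a frame is the arithmetic mean x-velocity over the
region of interest (canonically the ectodomain water); sampled every frame it
gives the instant series, and non-overlapping block means over requested
windows give the smoothed series.  Height profiles slice a span above the
ectodomain height origin (canonically 50 nm into 25 equal bins) and average
the axial velocity of the particles observed in each layer over a time
window (canonically 5 ns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trajectory import RegionSpec, Trajectory, select_region

__all__ = ["BulkVelocitySeries", "HeightProfile", "bulk_velocity_series", "height_profile"]

_WINDOW_TOL = 1e-6


@dataclass
class BulkVelocitySeries:
    """Instant per-frame mean vx plus block-averaged versions.

    ``window_means`` maps window width (ns) to ``(centers, means)`` arrays;
    block means cover complete windows only, aligned to the series start.
    """

    times: np.ndarray  # ns, one per frame
    instant_vx: np.ndarray  # m/s, one per frame
    window_means: dict[float, tuple[np.ndarray, np.ndarray]]
    region: str


@dataclass
class HeightProfile:
    """Mean axial velocity per height bin over one time window."""

    bin_edges: np.ndarray  # Å, n_bins + 1 values
    bin_centers: np.ndarray  # Å
    window_start: float  # ns
    window_end: float  # ns
    mean_vx_per_bin: np.ndarray  # m/s; NaN marks empty bins
    count_per_bin: np.ndarray  # particle-observations per bin


def _frames_per_window(window: float, frame_interval: float, what: str) -> int:
    ratio = window / frame_interval
    k = round(ratio)
    if k < 1 or abs(ratio - k) > _WINDOW_TOL * max(1.0, ratio):
        raise ValueError(
            f"{what} ({window} ns) must be a positive multiple of the "
            f"frame interval ({frame_interval} ns)"
        )
    return k


def bulk_velocity_series(
    traj: Trajectory,
    region: str = "ectodomain",
    windows: list[float] | tuple[float, ...] = (),
) -> BulkVelocitySeries:
    """Per-frame mean x-velocity over ``region`` and block means per window.

    Raises if the region is empty in any frame (the mean would be undefined),
    naming the offending frame.
    """
    instant = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        sub = select_region(frame, region)
        if sub.particle_count == 0:
            raise ValueError(f"region {region!r} is empty in frame {i}")
        instant[i] = sub.velocities[:, 0].mean()
    times = traj.times
    window_means: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for window in windows:
        k = _frames_per_window(window, traj.frame_interval, "window")
        n_blocks = traj.n_frames // k
        means = instant[: n_blocks * k].reshape(n_blocks, k).mean(axis=1)
        centers = times[: n_blocks * k].reshape(n_blocks, k).mean(axis=1)
        window_means[float(window)] = (centers, means)
    return BulkVelocitySeries(times, instant, window_means, region)


def height_profile(
    traj: Trajectory,
    region_spec: RegionSpec,
    n_bins: int = 25,
    span: float = 500.0,
    window: float = 5.0,
    region: str = "ectodomain",
) -> list[HeightProfile]:
    """Stratified mean vx over ``n_bins`` equal z-bins spanning
    ``[z_origin, z_origin + span]``, one profile per complete time window.

    Bin intervals are half-open ``[edge_i, edge_{i+1})`` with the top edge
    inclusive for the last bin; empty bins carry NaN (a missing marker, since
    zero is a legitimate velocity).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    if span <= 0:
        raise ValueError("span must be positive")
    k = _frames_per_window(window, traj.frame_interval, "window")
    edges = region_spec.z_origin + np.linspace(0.0, span, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_windows = traj.n_frames // k
    profiles = []
    for w in range(n_windows):
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=int)
        block = traj.frames[w * k : (w + 1) * k]
        for frame in block:
            sub = select_region(frame, region)
            z = sub.positions[:, 2]
            vx = sub.velocities[:, 0]
            # half-open bins, top edge inclusive for the last bin
            idx = np.floor((z - edges[0]) / (span / n_bins)).astype(int)
            on_top = z == edges[-1]
            idx[on_top] = n_bins - 1
            ok = (idx >= 0) & (idx < n_bins) & ((z < edges[-1]) | on_top)
            np.add.at(sums, idx[ok], vx[ok])
            np.add.at(counts, idx[ok], 1)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        profiles.append(
            HeightProfile(
                bin_edges=edges,
                bin_centers=centers,
                window_start=block[0].time,
                window_end=block[-1].time + traj.frame_interval,
                mean_vx_per_bin=means,
                count_per_bin=counts,
            )
        )
    return profiles
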