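"""End-to-end orchestration: synth → profiles → field → streamlines → compare → regime.

A :class:`RunConfig` (flat TOML file or constructed in code) describes a
roster of cases — each an obstacle count plus a drift schedule, mirroring
the force-on / force-released / reduced-obstacle experiment design — and the
parameters of every analysis stage.  :func:`run_pipeline` executes the
requested stages in dependency order, persists each stage's products as
tab-separated text or JSON under the output directory, and writes a
:class:`RunManifest` recording the config snapshot, package version, output
checksums and timings.  Identical config + seed reproduces every stochastic
stage bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .field import SlabSpec, grid_velocity_field, make_grid, select_slab, vorticity_field
from .profiles import bulk_velocity_series, height_profile
from .regime import BalanceCurve, GeoModel, RegimePoint, classify_regime, geo_number, plot_regime_diagram, reynolds
from .stats import compare_cases, estimate_density
from .streamlines import cell_center_seeds, streamline_lengths, trace_streamlines
from .synth import FlowFieldModel, GeneratorConfig, ObstacleDisc, generate_trajectory
from .trajectory import RegionSpec, write_trajectory
from .units import WATER_SIGMA_310K

logger = logging.getLogger("glycoflow")

ALL_STAGES = ("synth", "profiles", "field", "streamlines", "compare", "regime")


@dataclass
class CaseSpec:
    """One experiment case: obstacle count and drift (external-force) schedule."""

    name: str
    n_chains: int
    force_fN: float = 0.003
    drift_off_time: float | None = None  # ns; force released from here on


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    cases: list[CaseSpec] = field(
        default_factory=lambda: [
            CaseSpec("A", 18),
            CaseSpec("B", 18, drift_off_time=6.0),
            CaseSpec("C", 15),
            CaseSpec("D", 9),
        ]
    )
    # generator; 80 frames at 0.1 ns span 8 ns, so Case B's 6-ns force
    # release is followed by 2 ns of free development
    n_particles: int = 50_000
    n_frames: int = 80
    frame_interval: float = 0.1  # ns
    box: tuple = ((-110.0, 110.0), (-110.0, 110.0), (0.0, 650.0))
    drift_ux: float = 1.0  # m/s
    thermal_sigma: float = WATER_SIGMA_310K
    obstacle_radius: float = 12.0  # Å
    obstacle_attenuation: float = 0.3
    mode: str = "resample"
    # profiles
    z_origin: float = 120.0  # Å; ectodomain height origin
    profile_span: float = 500.0  # Å (50 nm)
    profile_bins: int = 25
    profile_window: float = 1.0  # ns
    bulk_windows: tuple[float, ...] = (0.5, 1.0)
    # field / streamlines
    slab_center: float = 360.0  # Å = z_origin + 24 nm
    slab_halfwidth: float = 10.0  # Å (± 1 nm)
    roi: tuple = ((-88.0, 88.0), (-99.0, 99.0))
    dx: float = 8.0
    dy: float = 9.0
    field_window: float | None = None  # ns; default: the final 1 ns
    # compare / regime
    alpha: float = 0.05
    density_method: str = "kde_gaussian"
    characteristic_length: float = 50e-9  # m, the 50 nm analysis height
    kinematic_viscosity: float = 7.0e-7  # m^2/s, water near 310 K
    balance_tolerance: float = 0.10

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {ALL_STAGES}")
        if not self.cases:
            raise ValueError("at least one case is required")
        if len({c.name for c in self.cases}) != len(self.cases):
            raise ValueError("case names must be unique")
        GeneratorConfig(  # validates the generator parameters eagerly
            n_particles=self.n_particles,
            box=self.box,
            n_frames=self.n_frames,
            frame_interval=self.frame_interval,
            seed=self.seed,
            mode=self.mode,
        )
        make_grid(self.roi, self.dx, self.dy)
        SlabSpec(self.slab_center, self.slab_halfwidth)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        cases = [CaseSpec(**c) for c in raw.pop("cases", [])]
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                value = raw.pop(f.name)
                if f.name in ("stages", "bulk_windows"):
                    value = tuple(value)
                elif f.name in ("box", "roi"):
                    value = tuple(tuple(ax) for ax in value)
                kwargs[f.name] = value
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        if cases:
            kwargs["cases"] = cases
        return cls(**kwargs)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    version: str
    outputs: dict[str, str]  # relative path -> sha256
    timings: dict[str, float]  # stage -> seconds

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _case_model(config: RunConfig, case: CaseSpec, layout_rng: np.random.Generator) -> FlowFieldModel:
    """Obstacle-slowdown field for a case; disc layout is shared across cases
    (a reduced case keeps the first n discs of the full layout)."""
    (x0, x1), (y0, y1) = config.roi
    max_chains = max(c.n_chains for c in config.cases)
    centers = np.column_stack(
        [
            x0 + layout_rng.random(max_chains) * (x1 - x0),
            y0 + layout_rng.random(max_chains) * (y1 - y0),
        ]
    )
    discs = [
        ObstacleDisc((float(cx), float(cy)), config.obstacle_radius, config.obstacle_attenuation)
        for cx, cy in centers[: case.n_chains]
    ]
    base = FlowFieldModel("uniform", {"ux": config.drift_ux, "uy": 0.0}, thermal_sigma=0.0)
    return FlowFieldModel(
        "obstacle_slowdown",
        {"base": base, "discs": discs},
        thermal_sigma=config.thermal_sigma,
        drift_force_fN=case.force_fN,
    )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the requested stages for every case; returns the manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}
    stages = [s for s in ALL_STAGES if s in config.stages]

    def record(path: Path) -> None:
        outputs[str(path.relative_to(out))] = _sha256(path)

    trajectories: dict[str, object] = {}
    fields: dict[str, object] = {}
    length_summaries: dict[str, object] = {}
    vort_summaries: dict[str, object] = {}
    bulk_means: dict[str, float] = {}

    region_spec = RegionSpec(z_origin=config.z_origin, z_extent=config.profile_span)
    needs_traj = {"synth", "profiles", "field", "streamlines", "compare", "regime"}
    if set(stages) & needs_traj:
        t0 = _time.perf_counter()
        for k, case in enumerate(config.cases):
            layout_rng = np.random.default_rng(config.seed + 1000)  # shared layout
            model = _case_model(config, case, layout_rng)
            gen = GeneratorConfig(
                n_particles=config.n_particles,
                box=config.box,
                n_frames=config.n_frames,
                frame_interval=config.frame_interval,
                seed=config.seed + k,
                ectodomain_fraction=1.0 - config.z_origin / (config.box[2][1] - config.box[2][0]),
                mode=config.mode,
                drift_off_time=case.drift_off_time,
            )
            logger.info("generating case %s (%d obstacles)", case.name, case.n_chains)
            trajectories[case.name] = generate_trajectory(model, gen)
        if "synth" in stages:
            for case in config.cases:
                path = out / f"case_{case.name}.extxyz"
                write_trajectory(trajectories[case.name], path, "extxyz")
                record(path)
        timings["synth"] = _time.perf_counter() - t0

    if "profiles" in stages or "regime" in stages:
        t0 = _time.perf_counter()
        for case in config.cases:
            traj = trajectories[case.name]
            series = bulk_velocity_series(traj, "ectodomain", config.bulk_windows)
            # regime placement uses the late-time state (final quarter of the
            # run), so a released force shows its decayed velocity
            tail = max(1, series.instant_vx.size // 4)
            bulk_means[case.name] = float(series.instant_vx[-tail:].mean())
            if "profiles" in stages:
                df = pd.DataFrame({"time_ns": series.times, "instant_vx_mps": series.instant_vx})
                path = out / f"bulk_velocity_{case.name}.tsv"
                df.to_csv(path, sep="\t", index=False)
                record(path)
                profs = height_profile(
                    traj, region_spec, config.profile_bins, config.profile_span, config.profile_window
                )
                rows = []
                for p in profs:
                    for c, m, n in zip(p.bin_centers, p.mean_vx_per_bin, p.count_per_bin):
                        rows.append(
                            {
                                "window_start_ns": p.window_start,
                                "window_end_ns": p.window_end,
                                "z_center_A": c,
                                "mean_vx_mps": m,
                                "count": n,
                            }
                        )
                path = out / f"height_profile_{case.name}.tsv"
                pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
                record(path)
        timings["profiles"] = _time.perf_counter() - t0

    if set(stages) & {"field", "streamlines", "compare"}:
        t0 = _time.perf_counter()
        grid = make_grid(config.roi, config.dx, config.dy)
        slab = SlabSpec(config.slab_center, config.slab_halfwidth)
        for case in config.cases:
            traj = trajectories[case.name]
            t_end = traj.frames[-1].time
            window = config.field_window if config.field_window is not None else 1.0
            obs = select_slab(traj, slab, (max(0.0, t_end - window), t_end))
            fld = grid_velocity_field(obs, grid, time_span=(max(0.0, t_end - window), t_end))
            fields[case.name] = fld
            vort = vorticity_field(fld)
            if "field" in stages:
                header = (
                    f"# case={case.name} grid={grid.nx}x{grid.ny} dx={grid.dx} dy={grid.dy} "
                    f"units=m/s window_ns={fld.time_span}\n"
                )
                for name, arr in (("vx", fld.mean_vx), ("vy", fld.mean_vy), ("vorticity_per_ns", vort.w)):
                    path = out / f"field_{name}_{case.name}.tsv"
                    with open(path, "w") as fh:
                        fh.write(header)
                        np.savetxt(fh, arr, delimiter="\t")
                    record(path)
            if vort.samples().size >= 2:
                vort_summaries[case.name] = estimate_density(
                    vort.samples(), config.density_method, units="1/ns"
                )
        timings["field"] = _time.perf_counter() - t0

    if set(stages) & {"streamlines", "compare"}:
        t0 = _time.perf_counter()
        for case in config.cases:
            fld = fields[case.name]
            seeds = cell_center_seeds(fld)
            sset = trace_streamlines(fld, seeds)
            lengths = streamline_lengths(sset)
            if "streamlines" in stages:
                df = pd.DataFrame(
                    {
                        "seed_x": [s.seed[0] for s in sset.streamlines],
                        "seed_y": [s.seed[1] for s in sset.streamlines],
                        "length_A": [s.length for s in sset.streamlines],
                        "termination": [s.termination for s in sset.streamlines],
                    }
                )
                path = out / f"streamlines_{case.name}.tsv"
                df.to_csv(path, sep="\t", index=False)
                record(path)
            if lengths.size >= 2:
                length_summaries[case.name] = estimate_density(
                    lengths, config.density_method, units="angstrom"
                )
        timings["streamlines"] = _time.perf_counter() - t0

    if "compare" in stages:
        t0 = _time.perf_counter()
        for tag, summaries in (("streamline_length", length_summaries), ("vorticity", vort_summaries)):
            if len(summaries) >= 2:
                report = compare_cases(summaries, alpha=config.alpha)
                path = out / f"compare_{tag}.json"
                path.write_text(json.dumps(report, indent=2, default=str))
                record(path)
        timings["compare"] = _time.perf_counter() - t0

    if "regime" in stages:
        t0 = _time.perf_counter()
        model = GeoModel(a0=1.0)  # count-only score: Geo = N
        ref = config.cases[0]
        curve = BalanceCurve(
            [(geo_number(ref.n_chains, model=model), abs(bulk_means[ref.name])
              * config.characteristic_length / config.kinematic_viscosity)],
            tolerance=config.balance_tolerance,
        )
        points = []
        for case in config.cases:
            geo = geo_number(case.n_chains, model=model)
            re = reynolds(abs(bulk_means[case.name]), config.characteristic_length, config.kinematic_viscosity)
            label = classify_regime((geo, re), curve)
            points.append(RegimePoint(re=re, geo=geo, label=label, case_name=case.name))
        df = pd.DataFrame(
            {
                "case": [p.case_name for p in points],
                "geo": [p.geo for p in points],
                "re": [p.re for p in points],
                "label": [p.label for p in points],
            }
        )
        path = out / "regime_points.tsv"
        df.to_csv(path, sep="\t", index=False)
        record(path)
        path = out / "regime_diagram.png"
        plot_regime_diagram(points, curve, str(path))
        record(path)
        timings["regime"] = _time.perf_counter() - t0

    snapshot = dataclasses.asdict(config)
    snapshot["out_dir"] = str(config.out_dir)
    manifest = RunManifest(config=snapshot, version=__version__, outputs=outputs, timings=timings)
    manifest.write(out / "manifest.json")
    return manifest
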