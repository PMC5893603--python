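# glycoflow

Post-processing for particle-resolved flow simulations over brush-like
surfaces — the kind of nanoscale flow found above the endothelial glycocalyx
layer (EGL), where water driven at bulk velocities of cm/s–m/s threads
through a canopy of flexible sugar chains while every individual molecule
moves at thermal speeds of hundreds of m/s.

Given trajectories of per-particle positions (Å), velocities (m/s) and
region labels, the package computes:

* **Bulk-velocity time series** — per-frame mean axial velocity
  v̄ₓ over the ectodomain, with non-overlapping window averages;
* **Height-stratified velocity profiles** — mean vₓ in 25 equal layers
  over 50 nm of height above the ectodomain origin, per time window;
* **Gridded planar velocity fields** — per-cell mean (vₓ, v_y) on a meshed
  region of interest (ROI), canonically x ∈ [−88, 88] Å, y ∈ [−99, 99] Å at
  8 × 9 Å cells (484 cells), from a horizontal slab of observations;
* **Discrete vorticity** — the z-component of the curl by forward
  differences, w = Δv_y/Δx − Δvₓ/Δy, exact for affine fields;
* **Streamline length distributions** — arc-length-parameterised RK4
  integration through the gridded field, with lengths compared across cases;
* **Two-sample Kolmogorov–Smirnov tests** — pooled-ECDF supremum D with
  asymptotic or exact (enumerated permutation) p-values, plus Gaussian-KDE /
  histogram density summaries;
* **Flow-regime classification** — Reynolds number Re = vL/ν against a
  geometric hindrance score Geo = a₀N + Σ aᵢxᵢ (count-only Geo = N by
  default), classified relative to a balance curve into *velocity-dominant*,
  *obstacle-dominant* or *balance* regimes.

Because production molecular-dynamics trajectories are huge and rarely
shareable, a synthetic generator (`glycoflow.synth`) produces ensembles with
known ground truth: an analytic drift field (uniform, shear, rigid rotation,
vortex lattice, or obstacle-attenuated) plus Maxwell–Boltzmann thermal noise
(σ = √(k_BT/m) ≈ 378 m/s for water at 310 K). Every estimator in the
package is validated against fields the generator drew from.

## Worked example

```python
import numpy as np
from glycoflow import (FlowFieldModel, GeneratorConfig, Observations, make_grid,
                       sample_frame, grid_velocity_field, vorticity_field,
                       trace_streamline, ks_two_sample)

# mesh the canonical ROI
grid = make_grid(((-88.0, 88.0), (-99.0, 99.0)), 8.0, 9.0)
print("cells:", grid.n_cells)

# sample 200k particles from a noise-free rigid rotation (omega = 0.05 rad/ns)
rotation = FlowFieldModel("rigid_rotation", {"omega": 0.05, "center": (0.0, 0.0)},
                          thermal_sigma=0.0)
cfg = GeneratorConfig(n_particles=200_000, box=((-88, 88), (-99, 99), (0, 20)), seed=1)
frame = sample_frame(rotation, cfg)
obs = Observations(frame.positions[:, 0], frame.positions[:, 1],
                   frame.velocities[:, 0], frame.velocities[:, 1])
fld = grid_velocity_field(obs, grid)
vort = vorticity_field(fld)
print(f"mean vorticity: {np.nanmean(vort.w):.4f} 1/ns (expect 2*omega = 0.1000)")

s = trace_streamline(fld, (-88.0, 0.0))
print(f"streamline from (-88, 0): {s.termination}, length {s.length:.1f} A")

rng = np.random.default_rng(0)
res = ks_two_sample(rng.normal(size=300), rng.normal(0.5, 1.0, size=300))
print(f"K-S: D = {res.statistic_D:.3f}, p = {res.p_value:.2e}")
```

prints

```
cells: 484
mean vorticity: 0.1000 1/ns (expect 2*omega = 0.1000)
streamline from (-88, 0): exited_roi, length 274.6 A
K-S: D = 0.253, p = 8.70e-09
```

The recovered mean vorticity equals the analytic curl of a rigid rotation
(2ω); the streamline seeded on the left ROI boundary spirals with the
rotation until it leaves the ROI; and the K-S test flags the half-σ shift
between the two Gaussian samples as highly significant.

A full config-driven pipeline — four cases with 18/18/15/9 obstacle discs,
force applied throughout or released after 6 ns, then profiles, fields,
streamlines, pairwise K-S comparisons, and a labelled (Geo, Re) regime
diagram — runs with:

```sh
glycoflow run --out-dir demo_run --seed 2
```

Each subcommand (`synth`, `profile`, `field`, `streamlines`, `compare`,
`regime`) is also available standalone; see `glycoflow --help`.

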