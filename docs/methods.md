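# Methods

This note records the models, conventions and numerical choices behind
glycoflow, and what the synthetic-data validation does and does not show
about real molecular-dynamics (MD) data.

## Units and conventions

Internally, lengths are ångström, times nanoseconds, velocities m/s and
vorticity 1/ns. The two unit systems meet only through the constants in
`glycoflow.units`: 1 m/s = 10 Å/ns, so a velocity gradient of 1 (m/s)/Å is
10 /ns (equivalently 10¹⁰ /s). Analytic fields parameterised by rates in
1/ns (shear γ, rotation ω) return velocities in m/s via the same 0.1
(m/s)/(Å/ns) factor, which is why a rigid rotation of ω rad/ns has discrete
vorticity exactly 2ω 1/ns.

## Synthetic particle ensembles

The generator emulates the *statistical* structure of a thermostatted water
ensemble, not its dynamics. Per frame, positions are uniform over the box
(or advected by the local drift between frames, wrapped periodically) and
each velocity is the analytic drift field at the particle position plus
i.i.d. Gaussian noise per component. The default noise scale is the
Maxwell–Boltzmann per-component σ = √(k_B·T/m) for water (18 amu) at 310 K,
≈ 378 m/s, so the defining regime of the application — bulk drift of
cm/s–m/s buried three to four orders of magnitude beneath thermal motion —
is the default test condition. Obstacles are static discs that multiply the
base drift by an attenuation factor in [0, 1]; they stand in for the mean
steric effect of flexible sugar chains at the field level only.

What this validates: that the estimators (means, profiles, gridded fields,
vorticity, streamline statistics) recover a known signal at the correct
σ/√n convergence rate, and that distribution-level comparisons behave as
calibrated hypothesis tests. What it does not validate: hydrodynamic
correlations, excluded volume, chain conformational dynamics, periodic-image
effects of a hexagonal cell, or any force–velocity relation; the external
force in fN is carried as metadata, while drift magnitude and noise are set
independently.

## Temporal and spatial averaging

The instant bulk velocity is the arithmetic mean vₓ over the region's
particles, one value per frame (canonically every 0.1 ns). Window averages
are *non-overlapping block means* aligned to the series start, covering
complete blocks only — the simplest convention consistent with presenting
one smoothed point per window. Height profiles slice a span (default 50 nm
= 500 Å, 25 equal 20 Å bins) above a user-supplied height origin — the
origin is a required parameter, since it depends on where the bilayer sits
in a given system. Bins are half-open [lower, upper) with the top edge
inclusive for the last bin; empty bins carry NaN, never zero, because zero
is a legitimate velocity.

## Gridded fields and discrete vorticity

Planar observations are all (particle, frame) pairs inside a z-slab
(inclusive half-width) and time window (inclusive ends). The ROI mesh
requires its extents to divide exactly by the cell sides; the canonical ROI
x ∈ [−88, 88] Å, y ∈ [−99, 99] Å at 8 × 9 Å gives 22 × 22 = 484 cells.
Cells are half-open, so an observation exactly on the upper ROI boundary is
discarded (and counted). All observations in the window are pooled into a
single gridding (one field per window); a per-frame-then-average mode can
be composed from the same primitives but pooling is the canonical mode,
since per-cell counts at nanoscale are too sparse to grid single frames
reliably.

Vorticity uses the forward-difference stencil
w[i,j] = (v_y[i+1,j] − v_y[i,j])/Δx − (vₓ[i,j+1] − vₓ[i,j])/Δy
on the (nx−1) × (ny−1) interior lattice, with no boundary extrapolation.
Forward differences are exact for fields affine in (x, y) evaluated at cell
centres — the basis of the machine-precision acceptance checks (uniform →
0, rotation ω → 2ω, shear γ → −γ). Missing cells propagate: a stencil that
touches an unoccupied cell yields NaN rather than a fabricated zero. No
smoothing is applied before differencing.

## Streamlines

Cell means are treated as point values at cell centres and interpolated
bilinearly; a cell with zero bilinear weight is not a "contributor", so a
query exactly at an occupied centre returns that cell's mean even next to a
hole. Within half a cell of the ROI boundary the query clamps onto the
centre lattice, i.e. nearest-cell in the normal direction.

Integration is classical RK4 on dX/ds = v/|v| with fixed arc-length step —
the analysed quantity is geometric length, and arc-length stepping makes it
invariant under rescaling v → αv. Defaults: step = min(Δx, Δy)/4 (resolves
cell-scale curvature), max_steps = 10 × perimeter/step (caps closed
orbits), stagnation threshold 10⁻⁶ × the RMS speed of occupied cells.
A trace ends by ROI exit (final point clipped to the boundary along the
last segment), stagnation (|v| at or below threshold, including at RK4
substeps), missing data (a distinct category, not an error — sparse
occupancy is expected), or the step cap. Measured behaviour at these
settings: a uniform-field trace across the ROI reproduces the 176 Å extent
to < 10⁻⁶ Å, and a rigid-rotation orbit of radius 60 Å at step 1 Å drifts
in radius by ~10⁻⁹ % over a revolution.

Seeding is one seed per occupied cell centre by default (uniform random
seeding is available). This makes the streamline count
configuration-independent and comparable across cases; since any seeding
rule changes the length distribution, absolute length statistics are only
comparable between runs using the same rule.

## Distribution comparison

Density summaries default to a Gaussian KDE with Silverman bandwidth
(recorded in the output, along with the method, for auditability); the
histogram mode doubles each bin edge in its output curve so the trapezoidal
integral reproduces the exact histogram mass. The two-sample K-S statistic
D is the supremum of the ECDF difference over pooled points
(right-continuous, ties handled at unique values). The default p-value is
the asymptotic Kolmogorov distribution at effective size n₁n₂/(n₁+n₂);
measured null rejection at α = 0.05 with n = 100 per sample is ≈ 0.04 —
slightly conservative, as expected of the uncorrected asymptotic form. For
pooled sizes ≤ 12 an exact mode enumerates every permutation split.
One-sided alternatives (exp(−2·en·D²) tail) exist for directional questions
such as "do obstacles shorten streamlines?"; the default remains two-sided.
Raw samples, never density curves, are tested. No multiple-testing
correction is applied to pairwise reports — a documented limitation.

## Regime diagram

Re = vL/ν and Geo = a₀N + Σ aᵢxᵢ. The characteristic length L and
kinematic viscosity ν are required inputs with no baked-in defaults (the
pipeline's config supplies L = 50 nm, the analysis height, and ν = 7×10⁻⁷
m²/s, water near 310 K). The balance curve is piecewise-linear through
user-supplied (geo, re) calibration points with constant extrapolation and
a relative tolerance band (default 10%) labelled "balance"; above is
velocity-dominant, below obstacle-dominant. Classification is monotone in
re at fixed geo by construction. Only the count-only Geo = N case is
exercised by the built-in pipeline; feature weights are user-specified and
never fitted.

## Pipeline problem sizes

The default end-to-end demo generates 50,000 particles for 80 frames of
0.1 ns per case (8 ns, so the force-released case has 2 ns of free decay),
with full water-level thermal noise. At these sizes the late-window mean
drift carries a standard error of ~0.4 m/s against a 1 m/s drift, so regime
placements of individual cases are indicative rather than sharp — the
package's quantitative validation lives in the test suite and acceptance
script, which use noise and sample sizes chosen per check. The acceptance
script's estimator-recovery checks use 10⁶ particles; its obstacle-contrast
check uses 200,000 particles, matched generator seeds, σ = 1 m/s against a
1 m/s drift, nine full-blockage discs of radius 20 Å and a 0.2 m/s
stagnation threshold (well above the ~0.05 m/s cell-mean noise, well below
the drift).

## Known limitations

* The generator's frames are temporally uncorrelated apart from mean-drift
  advection; autocorrelation-dependent quantities (e.g. effective sample
  size of window means) are not representative of MD output.
* Streamline length distributions depend on the seeding rule, integration
  step and termination thresholds; only like-for-like comparisons are
  meaningful.
* The vorticity stencil is one-sided, so a uniformly translating vortex
  pattern registers identically to a centred-difference estimate only on
  affine fields; on curved fields it carries O(Δ) bias.
* Rectangular boxes only; hexagonal periodic cells are out of scope.
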