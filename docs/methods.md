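# Methods

This note records the models, conventions and numerical choices behind
`flow4d`, and what the synthetic phantoms do and do not establish about
real 4D-flow data.

## Units and coordinate conventions

All numerics run in CGS (cm, s, g, erg, poise): blood density
ρ = 1.06 g/cm³, dynamic viscosity μ = 0.04 poise, velocities in cm/s.
Grid spacings are user-facing in millimetres (the scanner convention) and
converted at the `GridSpec` boundary.  Voxel index (0-based) × spacing is
the physical position of the voxel centre; velocity components are ordered
(x, y, z) to match the spatial axes.  Frame times are uniform,
t_k = k·RR/n_frames.  The dimensionless indices are unit-system invariant
by construction; the test suite re-runs a phantom in SI to confirm this to
round-off.

## Field operators

Velocity gradients are centred finite differences using only in-mask
neighbours; where exactly one axial neighbour is inside the mask a
first-order one-sided difference is used, and voxels with no in-mask
neighbour along some axis are excluded from all gradient-based
reductions.  Zero-padding outside the chamber is deliberately avoided: a
wall of zeros would manufacture shear at the boundary.  Centred
differences are exact for linear fields (so the phantom's linear base flow
has exactly zero discrete vorticity) and second-order accurate otherwise;
the Taylor–Green convergence test confirms the interior error drops 4×
when the spacing halves.  A periodic-wrap mode exists for analytic fields
spanning exact periods.

Reductions inside the mask: sums weight voxels by the voxel volume, means
divide by the contributing voxel count.  Kinetic energy reduces over the
whole mask; vorticity, strain and dissipation reduce over the
gradient-valid subset.  The single end-diastolic mask is applied to all
frames; a time-resolved-mask mode exists solely to demonstrate the known
direction of the resulting bias (the static mask can only overestimate
peak systolic KE, since it integrates a non-negative density over a
superset of the instantaneous chamber).

## Biomarkers

Dimensional report: KE at peak systole and peak diastole and cycle-summed
dissipation (rectangle rule, matching a per-frame sum; trapezoid would
differ only through the periodic endpoints), each normalised by stroke
volume; vorticity as the cycle mean of the mask-mean |ω|.  The
systole/diastole split is taken from the sign of the volume-series
derivative, with an explicit override for field data without volumes.

Dimensionless indices use characteristic scales built from CO and EDV
(L = EDV^⅓, U = CO/EDV^⅔): KE* divides the mask-mean KE *density* by
ρ·CO²·EDV^(-4/3) (that scale is an energy density), while the
stroke-volume-indexed report uses the mask-total KE; both are emitted and
labelled.  BSA uses the Kelley allometric formula for swine,
BSA(m²) = 0.0734·kg^0.656 — stated prominently because indexed volumes
depend on it.  The septal curvature index is EDV^⅓/r (curvature-like:
larger = more curved), with a flat septum mapping to 0.

## The dissipation-mechanism percentage

The percentage of dissipation attributable to vorticity is defined as the
ratio of the reported biomarkers,

    pct = 100 · ⟨|ω|⟩² / ⟨2S²⟩,

with means over mask and cycle.  The ratio of mask *integrals*
100·Σω²/Σ2S² is deliberately not the default: for any isolated vortex
contained in the evaluation region it is pinned near 100% by the vector
identity ∫|ω|² = ∫2S² (valid for decaying divergence-free fields), which
makes it useless as a mechanism discriminant.  It remains available as
`convention="integral"` and the test suite demonstrates both its drift
toward 100% with domain growth and the biomarker ratio's dilution.  For
uniform fields the two conventions coincide: plane shear gives 100%,
extensional flow 0%.

## Vortex-ring theory oracle

The diastolic inflow jet is idealised as a Gaussian-core (thin-ring)
vortex ring: azimuthal vorticity ω_φ = Γ/(πa²)·exp(−d²/a²) at meridional
distance d from a centreline of radius R, core radius a = 0.2R by
default.  Velocity is recovered by a spectral vector-potential solve
(∇²A = −ω, u = ∇×A) on a periodic box of 3R half-width; the construction
is divergence-free by gauge, and the discrete centred-difference
divergence stays below 1% of the largest gradient component at the default
resolution of 5 voxels per core radius.  The Reynolds number Re = Γ/ν
(900 by default) sets the circulation scale; the percentage is invariant
to it and to uniform spatial rescaling, both verified in tests.

The theory is realised through the same discrete operators as the
measurement pipeline rather than symbolic integrals, making the oracle a
self-consistency reference.

**Evaluation-region convention (the one genuinely free choice).**  The
percentage depends on the region over which the biomarker means are
taken, and theory references do not document their convention.  The
default here is the *vortex region itself*: all voxels within 3 core
radii of the ring centreline (a solid torus; the Gaussian vorticity there
has decayed to e⁻⁹ ≈ 0.01% of its peak).  This choice is fixed once; its
sensitivity, measured with the package at 4 voxels per core radius:

| region (padding in core radii)  | 2.0  | 2.5  | 3.0  | 4.0  |
|---------------------------------|------|------|------|------|
| solid torus around centreline   | 91.3 | 46.3 | **28.4** | 14.2 |
| padded bounding box of the ring | 36.8 | 22.3 | 15.2 | 8.4  |

At the default resolution (5 voxels per core radius) the default region
gives 27.9%; the value moves by < 1 point between 4 and 6 voxels per core
radius and < 1.5 points for core ratios 0.15–0.25.  A chamber-sized box
(3 ring radii half-width) dilutes ⟨|ω|⟩ and drives the biomarker ratio
below 1%, while the integral ratio there is 100.0% — neither is a usable
mechanism reference, which is why the region follows the vortex.

## Phantoms and cohorts

The beating ventricle is a prolate ellipsoid (long/short axis 1.6) whose
volume follows a raised-cosine systole/diastole waveform between EDV and
ESV; the systolic fraction defaults to 0.35 of the cycle, with the end of
systole snapped to the nearest frame so the sampled series attains ESV
exactly.  The interior velocity is a wall-motion-consistent linear base
flow u = (V̇/3V)·(x − centre) — irrotational, pure strain — plus a
Gaussian-core inflow ring near the chamber base whose circulation follows
the diastolic filling rate scaled by `flow_scale`.  Because all vorticity
comes from the ring, the vorticity biomarkers are exactly linear in
`flow_scale`, which lets the cohort generator calibrate each subject's
ω* to its drawn target with a single probe evaluation.  The ring geometry
scales with the chamber but keeps an absolute core floor of 0.5 cm so the
phantom is independent of the voxel grid (grid convergence of ω* under
spacing halving is < 2%, tested at 5%).

Velocity noise follows the standard phase-contrast relation
σ = VENC·√2/(π·SNR) per component, with VENC = 150 cm/s; aliasing wrap
into (−VENC, VENC] exists as an opt-in transform only (unwrapping is out
of scope).  All generators are pure functions of parameters and seed.

Cohort defaults encode the study structure the statistics stage assumes:
groups sham/PAS/intervention with n = 4/4/10, non-dimensional vorticity
targets (RV 82±47, 120±47, 59±12; LV 57±5, 78±15, 41±7) and indexed
volumetrics per group; Gaussian draws are floored at loose physiological
bounds and ESV is capped at 0.9·EDV so ejection fractions stay positive.

What the phantom does *not* emulate: valve geometry, trabeculation,
myocardial texture, turbulence, k-space acquisition, eddy currents or
phase offsets.  Passing tests therefore establish the correctness of the
operators, conventions and statistics on fields with known structure —
not the fidelity of any scanner's measurement chain.

## Statistics

Per metric, a Shapiro–Wilk gate at α = 0.05 on every group routes to
one-way ANOVA with Tukey HSD (parametric) or Kruskal–Wallis with
Bonferroni-corrected pairwise Mann-Whitney tests (nonparametric; Dunn's z
test available by option).  Groups with n < 3 cannot be tested for
normality and force the nonparametric route.  The gate is evaluated per
metric, all three contrasts are always reported, and constant metrics are
flagged degenerate with p = 1.  Monte-Carlo checks in the acceptance
suite: under an all-null design (n = 4/4/10) the family of pairwise
contrasts rejects in ≈ 5% of replicates, and the power to detect the
sham-vs-PAS LV ω* difference is tracked as a frozen regression value
(0.64 over 500 replicates).

## Problem sizes

Default analyses run at deliberately modest sizes chosen for desk-scale
reproducibility: the ring oracle at 5 voxels per core radius (150³ grid),
phantoms at 2–2.5 mm spacing on 40³–56³ grids with 8–20 frames, and
Monte-Carlo statistics at 500 replicates.  All are package defaults, not
algorithmic limits; every stage accepts finer grids.
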