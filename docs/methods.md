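# Methods

This note documents the physical models, numerical choices and known
limitations of `gelprint`.

## Rheology

**Power-law fit.**  Flow-sweep data (γ̇, η) are log-transformed and fitted
by ordinary least squares; the slope is n − 1 and the intercept log K.
No weighting is applied — the multiplicative (lognormal) noise of
rotational rheometry is homoscedastic in log space, so OLS on the logs is
the maximum-likelihood estimator.  R² below 0.95 triggers a warning, not
an error: a poor fit usually means the window includes the yield-stress
plateau, and the user should restrict `fit_range`.  The default window is
the full measured range (0.01–2000 1/s for the reference sweeps).

**Kelvin–Voigt conversion.**  The isotropic relation between shear and
tensile moduli is E = 2(1 + ν)G₀′, which at ν = 0.49 gives E = 2.98 G₀′.
The reference lumped-parameter sets shipped with the package, however,
all satisfy E = 2 G₀′ exactly.  Both conventions are exposed
(`convention="poisson"` / `"table3"`); the default is `"table3"` so that
simulations driven by the shipped fixtures reproduce the as-published
stiffnesses.  Which convention is "right" depends on how the original
characterisation treated ν; the factor-1.49 ambiguity only rescales E.

**Yield stress.**  τ_y comes from an unbounded Herschel–Bulkley
least-squares fit (scipy `curve_fit`) of the stress–rate curve, requiring
at least 5 points below 1 1/s so the plateau is actually resolved.  A
negative fitted τ_y (possible for pure power-law data) is clamped to zero
with a warning.  The estimate is a convenience: materials whose yield
stress is read off a plot should treat it as approximate.

## Extrusion flow

Flow in every segment is steady, laminar, fully developed and inertialess
(generalised Reynolds numbers for these gels are ≪ 1; a Metzner–Reed
number is available for sanity checks).  Entrance and contraction effects
are **not** modelled, so absolute pressure drops are approximate at the
segment junctions; wall shear stress and plug fraction in the needle,
which depend only on the local fully developed solution, are unaffected.

* Pressure gradient in a cylinder: dp/dz = 2τ_w/R with
  τ_w = K[(3n+1)/(4n) · 4Q/(πR³)]ⁿ (power law) or the Hagen–Poiseuille
  8μV/R² (Newtonian variants).
* Cones use the lubrication approximation — the locally fully developed
  gradient integrated axially by composite Simpson with 400 sub-slices by
  default (doubling the slice count changes the reference taper's Δp by
  < 1e-4 %).
* The plug region is defined as the radial span where u ≥ 95% of the
  centreline velocity, giving the closed form (1 − 0.95)^(n/(n+1)).  The
  threshold is a modelling choice (velocity profiles flatten continuously);
  95% keeps the plug extent above 70% of the section for every
  strongly-shear-thinning reference gel (n ≤ 0.12).
* The "average-shear Newtonian" comparison model evaluates the power-law
  viscosity at the needle's apparent rate 8V/D and applies that single
  viscosity to the whole train.  In the needle its pressure-gradient
  error relative to the power law has the closed form
  −(1 − (4n/(3n+1))ⁿ)·100%, between −5% and −12% for n in 0.02–0.12; the
  magnitude peaks near n ≈ 0.25 and vanishes in the Newtonian limit.
* `radial_quadrature_oracle` provides an independent route (adaptive
  quadrature of the inverted constitutive law) used by the tests to
  verify the closed forms to < 0.1%.

**Geometry defaults.**  The shipped train is a 5-ml-syringe class
geometry: 60 mm × R 6 mm barrel, 10 mm conical taper, 16 mm needle.  The
taper and needle lengths are representative (manufacturers vary); they
shift the absolute pressure drop (kPa scale for all reference gels) but
not wall stress or plug fraction.  All geometry is configurable.

## Hardware capacity

A stepper at stall torque T through a lead screw of pitch p converts to
axial force F = η_screw · 2πT/p; with T = 0.40 N·m, p = 0.8 mm and
η_screw = 0.5 this is 1570.8 N.  The literal η·T/p form (250 N for the
same numbers) is selectable but is not the standard screw conversion.
Service force is de-rated by a duty fraction (default 0.8 → 1257 N), and
the available pressure is that force over the piston area (≈ 11 MPa on a
12 mm bore, i.e. ~10 MPa at one significant figure) — three to four
orders of magnitude above what these gels need, hence every reference
combination is extrudable.

## Collapse finite elements

**Constitutive model.**  Each subdomain (gel, support) is a Kelvin–Voigt
solid: σ = C(E, ν)ε + τ_r C(E, ν)ε̇ with retardation time τ_r = η₀/E.
Building the viscous operator as a scalar multiple of the elastic one is
a deliberate choice: it gives the whole structure the same single
retardation time as the 1-D Kelvin–Voigt creep law
ε(t) = (σ/E)(1 − e^(−Et/η₀)), so the lumped parameters keep their
familiar meaning.  A Newtonian (deviatoric) viscous operator would make
the time constant mode-dependent without better data to calibrate it.

**Discretisation.**  Linear (constant-strain) triangles on a structured
grid snapped to the material boundaries; plane strain with configurable
out-of-plane thickness (default 1 mm); gravity as a consistent body load;
bottom edge fixed, lateral edges symmetric (zero normal displacement),
top free.  Backward Euler with dt = 0.5 s over 0–200 s by default; the
system matrix K + B/dt is factorised once (sparse LU).  Because the load
is constant and the model linear, the solution relaxes exponentially to
the elastic equilibrium; halving dt changes the final displacement by
≪ 1%.

**Validation oracles.**  (1) Self-weight compression of a laterally
confined column: the FE top displacement matches ρgH²/(2M) within 2%,
where M = E(1−ν)/((1+ν)(1−2ν)) is the constrained (oedometric) modulus —
equal to E at ν = 0, where the familiar ρgH²/(2E) form holds (for
E = 30 Pa, H = 3.3 mm: 1.78 mm).  (2) A single square element under
constant top traction reproduces the 1-D creep law within 1% at every
output time (run at ν = 0, where the constraint-state modulus equals E
and the closed form is exact).  Confined compression is volumetrically
benign, so constant-strain triangles pass the ν = 0.49 column test
without locking treatment; void-dominated bending at ν → 0.5 is stiffer
than a locking-free element would be, which makes the absolute collapse
of the lattice conservative (under-predicted) — one reason the results
below are trends, not absolute displacements.

**Unit cell.**  The wood-pile cross-section alternates full-width bars
(strands along the cut) with half strand cross-sections on the symmetry
boundaries (strands across the cut).  Defaults follow the slicing
parameters of the reference scaffold: strand width 0.77 mm, layer height
0.55 mm, inter-fiber distance 2.57 mm, 6 layers (3.3 mm tall).  The
monitored "point A" is the upper outer corner node of the top strand.
Default element sizes put the meshes at ~600 (gel only) and ~500 (with
support) triangles, the scale of physics-controlled reference meshes for
this cell.

**Interpretation.**  Small-strain linear kinematics are retained even
though the softest gel reaches ~50% strain; such results are flagged
"beyond linear validity" and should be read as "the structure collapses",
not as a converged large-deformation answer.  Contact, self-contact,
fluidisation of the support during nozzle travel, and geometric
nonlinearity are out of scope.  What the model does support, robustly:
final strain scales as ρg/E (so stiffness ordering across formulations is
exact), the support bath reduces the softest gel's collapse by well over
an order of magnitude, and equilibrium is reached within seconds to tens
of seconds (τ_r = 1.5–21 s for the reference materials).

## Printability report

Thresholds: cell-safety boundary at 80 Pa wall stress (inclusive), from
the published damage criterion for extruded cells; collapse
acceptability at 5% final strain — the reference data show ~4% for the
best unsupported case and ≤ 3.5% described as negligible with support, so
5% separates the two regimes.  Both are configurable.  The
recommendation is a pure function of the numeric fields: not extrudable
when required pressure exceeds available; direct print when the
unsupported strain is within the cutoff; bioplotting otherwise (with a
note if even the supported strain exceeds the cutoff).

**Line width.**  Piston-driven extrusion with volumetric slicing imposes
width = flow-multiplier × nozzle diameter, independent of print speed
(the slicer rescales the feed to keep the deposited cross-section
constant).  Correlation analysis is stratified: width vs nozzle at each
fixed speed on per-condition means, width vs speed at each fixed nozzle
both on means (3 points — the published convention, but statistically
fragile: the Pearson r of 3 noise-only points follows the arcsine null
density regardless of noise level) and on the individual replicates (the
stable form used in the property tests).

## Synthetic data

Flow sweeps: Herschel–Bulkley backbone on a log-spaced grid inside the
measurable span 0.01–2000 1/s, multiplied by unit-mean lognormal noise
(default CV 2%, typical of rotational rheometry repeatability).  Width
tables: full factorial nozzle × speed × replicates (default 3 × 3 × 15)
with lognormal noise (default CV 5%, typical of image-based width
measurement).  Generators are seed-deterministic.  What they do **not**
emulate: thixotropy/recovery, temperature drift, wall slip in the
rheometer, die swell of the printed line — so passing recovery tests
demonstrates estimator correctness under the stated noise model, not
robustness to those real-world artefacts.

## Problem sizes

Default analyses are desk-scale: flow solutions are closed forms plus a
400-slice quadrature; collapse meshes are 500–600 elements × 400 implicit
steps (sub-second per solve).  The parameter-recovery studies use 200
seeded sweeps and the correlation null study 500 seeded campaigns.
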