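# Methods

## Model

`cryosim` simulates percutaneous multi-probe cryoablation: needle-like
cryoprobes cooled by Joule–Thomson expansion of argon are inserted into soft
tissue and held at cryogenic temperature, growing a composite "ice ball"
whose cold core kills tissue. The thermal model is the Pennes bioheat
equation with liquid/mushy/solid phase change,

    (ρC)_eff ∂T/∂t = ∇·(k(T) ∇T) + w_b ρ_b c_b (T_b − T) + Q_m [+ Q_d],

where `w_b` is the blood perfusion rate, `ρ_b`, `c_b`, `T_b` the blood
density, specific heat, and arterial temperature, and `Q_m` the metabolic
volumetric heat. An advective term `u·∇T` is part of the general damage-
kinetics formulation but the bulk tissue velocity `u` is identically zero
(rigid tissue, no flow field), so it is carried as an inert constant.

Phase change uses the effective heat capacity method. Tissue is liquid above
the upper phase-transition temperature `T_mu = −1 °C`, fully frozen below
`T_ml = −8 °C`, and a solid–liquid mixture in between. Conductivity,
density, and specific heat are three-branch piecewise constants (liquid
value / arithmetic mean / frozen value), and the volumetric heat capacity
adds the latent heat smeared uniformly across the mushy interval,
`Q_lf/(T_mu − T_ml)`. The latent heat is tabulated per unit volume
(`Q_lf = 250 MJ/m³`), so the solver works throughout in volumetric heat
capacity ρc (J/(m³·°C)); integrating the effective capacity across the mushy
interval recovers the mean sensible heat plus exactly `Q_lf`.

The frozen fraction ramps linearly across the mushy interval — the shape
consistent with the constant effective-capacity plateau. By default,
perfusion and metabolism scale with the local liquid fraction (frozen tissue
neither perfuses nor metabolizes); `frozen_shutdown=false` restores the
strict Pennes source everywhere. The difference at the default perfusion
rate is small (a few percent of ice-ball size).

Cell death is a threshold/time clock: wherever `T < T_dc = −20 °C`, a raw
damage accumulator grows at rate `1/t_dc` with `t_dc = 60 s`, and the damage
fraction is `θ_d = min(α, 1)`. The necrosis temperature `T_nc = −50 °C` and
damage enthalpy `L_dc = 250 kJ/kg` are carried with the damage parameter
set; the damage-enthalpy heat source `ρ L_dc ∂θ_d/∂t` is OFF by default
because the same latent heat already enters through the effective capacity —
enabling both would release it twice. Damage-weighted mixing of frozen-phase
properties into damaged tissue is available (`damage_property_mixing`) but
OFF by default: the damaged-tissue property values are not independently
tabulated, so the default maps damage to bookkeeping only.

## Discretization and solver

Cell-centered finite volumes on uniform structured grids: 3-D Cartesian
(production), axisymmetric (r,z) for a single on-axis probe, and 1-D planar
for verification. Face conductivities are harmonic means, giving a symmetric
M-matrix and a discrete maximum principle. Time integration is backward
Euler with nonlinear coefficient iteration, default `dt = 0.5 s`.

The nonlinear iteration is a conservative enthalpy linearization: each
iterate solves the backward-Euler system with the diagonal capacity taken as
the chord slope of the volumetric enthalpy between the previous time level
and the current iterate, and the residual written so that at convergence the
step satisfies `H(T_new) − H(T_old) = Δt (∇·k∇T_new + sources)` exactly.
This is what lets a time step carry a cell across the entire mushy interval
(even one collapsed to 0.2 °C for the Stefan benchmark) without losing
latent heat. Cells whose successive updates flip sign are oscillating across
an enthalpy kink and are damped per-cell by halving (floor 1/64); cells
advancing monotonically keep full steps. Convergence is declared when the
capacity-weighted temperature change drops below `picard_tol` (default
10⁻³ °C, weighted by C/ρ_u c_u so mushy cells settle proportionally tighter
in temperature), capped at 25 iterations. The linear systems are solved
directly (sparse LU) up to 6000 unknowns, and by Jacobi-preconditioned
conjugate gradients (relative tolerance 10⁻¹⁰) above.

Actively cooled probe cells are hard Dirichlet nodes following the shared
load curve; non-cooling shaft cells and all outer boundaries are zero-flux.
An optional conjugate mode instead resolves shaft cells thermally with the
probe material constants (nitinol 21.9 W/(m·K), 4506 kg/m³, 522 J/(kg·K);
polyurethane 0.18, 930, 1900). An explicit (forward-Euler) mode exists for
cross-checking and refuses time steps above its stability limit.

The per-step energy report sums `H(T_new) − H(T_old)` over solved cells and
compares it with the time-integrated sources, probe-face fluxes, and
Dirichlet-wall fluxes; the residual is normalized by the gross per-cell
enthalpy traffic. Insulated source-free runs balance at machine level;
probe runs balance to well under 1% per step.

Probe rasterization marks cells whose centers fall inside a probe cylinder.
A probe thinner than the cell size (0.85 mm radius on a ≥2 mm grid) would
capture no centers; by default it snaps to the single nearest cell column
(deterministic tie-break), keeping coarse multi-probe grids usable, with a
strict rejection mode available. On a 1 mm grid the snapped column gives the
probe an effective radius of ~1 mm, a conservative (slightly enlarging)
approximation.

## Geometry and scenarios

Right-handed coordinates, SI meters internally; probes enter the specimen
surface (z = 0) along −z to a depth of 2 cm; the whole inserted length cools
by default (the active length is configurable — the hardware's true active
segment is not published). Probe radius defaults to 0.85 mm (17-gauge
convention). Layouts: single; five = center + 4 probes on an annulus of
radius `spacing`; seven = center + hexagon of circumradius `spacing`
("plum-blossom"); nine = 3×3 lattice with nearest-neighbor distance
`spacing`; default spacing 1 cm. The load curve is a three-segment
piecewise-linear stand-in for the measured probe-surface trace: 60 s ramp
from the start temperature to a −150 °C plateau, hold to the end of the
freeze, then a linear thaw ramp. Only the shape, not the hardware's real
trace, is published; the plateau value is the model's largest uncertainty
(see Limitations). Scenario presets: `phantom-*` start at 25 °C (bench
phantom at room temperature), `liver-nine` at 37 °C (body core); all freeze
for 900 s.

Lattice-aligned Cartesian grids (`SimulationGrid.centered`) use odd lateral
cell counts so a cell center sits on the array axis; when the probe spacing
is a multiple of the grid spacing, every probe lands exactly on a cell
center and the discrete field inherits the array's symmetry group to solver
tolerance.

## Morphometrics

The ice ball is the region at or below 0 °C (the operational convention);
lethal-zone levels 0/−20/−40/−50 °C are all reported because the damage
literature uses −40 °C for irreversible injury while the necrosis
temperature here is −50 °C — both are exposed rather than silently chosen.
Extents mimic bench calipers: longitudinal = span of the largest connected
component along the probe axis; transverse = the maximal caliper width in
any perpendicular direction (diameter of the projection of the marching-
cubes isosurface onto the plane normal to the axis). Axisymmetric snapshots
use sub-cell contour interpolation, extending spans to the wall when the
region genuinely reaches a boundary; components touching a boundary are
flagged as clipped (unreliable absolute size). Warm-zone volume counts cells
inside the convex hull of the 0 °C region that remain above the lethal
level — the interstitial pockets that risk incomplete ablation. Merge
tracking counts connected 0 °C components per snapshot; strict decreases
are fusion events.

## Verification oracles

Without any external dataset the solver is checked against closed forms of
the same physics:

* **Two-phase Neumann/Stefan front.** Planar freezing from a −150 °C wall
  into tissue at 25 °C with the mushy interval collapsed to 0.2 °C and
  perfusion off. The similarity root λ (front at `2λ√(κ_f t)`) is found by
  bracketed Brent iteration to 10⁻¹⁰ and independently confirmed by a fine
  sign-change scan and by the classical one-phase limit. The solver front at
  t = 600 s agrees within 2% on the finest tested grid (0.75% at 1 mm,
  0.09% at 0.5 mm), with error decreasing under refinement.
* **Lumped perfusion relaxation.** With k → 0 every cell follows
  `T_ss + (T₀ − T_ss) exp(−w_b ρ_b c_b t/ρc)`,
  `T_ss = T_b + Q_m/(w_b ρ_b c_b) = 39.33 °C` for the default table; the
  solver matches within 0.05 °C at all output times.
* **Mesh convergence.** A reduced axisymmetric domain run at 2.4/1.2/0.6 mm
  reports the temperature 4.8 mm axially beyond the probe tip (the axial
  interpretation of the probe-relative monitor, and the grid-commensurate
  offset, are documented choices); successive differences shrink
  monotonically. The harness fixes the probe radius at 2.4 mm — exactly
  representable on every grid of the ladder — because a thin probe snapped
  to a single cell column would change its effective radius with the
  spacing, masking mesh convergence behind a geometry artifact.

## Verification problem sizes

Chosen once as the package's verification defaults: single-probe replication
on a 1 mm axisymmetric grid, 4 cm radius × 5 cm depth, dt = 0.5 s;
nine-probe merge dynamics on a lattice-aligned 2 mm grid (6.5 cm lateral,
4 cm deep), dt = 2 s, 120 s of freezing (fusion completes near 60 s);
layout ranking (five/seven/nine) on a 2.5 mm lattice-aligned grid, 10 cm
lateral × 6 cm deep, dt = 2.5 s, full 900 s; Stefan verification at
0.5 mm/0.25 s on an 8 cm bar.

## Known limitations

* **The load-curve plateau dominates absolute ice-ball size.** The probe
  surface trace is published only as a graph; the packaged default assumes a
  −150 °C plateau over the whole inserted length. Under that assumption the
  model — verified independently against the Neumann front and a hand-rolled
  explicit cylindrical enthalpy solver — produces a single-probe 0 °C region
  of ≈2.9 cm longitudinal × 3.4 cm transverse at 900 s, roughly ellipsoidal
  scaled up from the benchtop report of 2.5 × 1.2 cm. A 1.2 cm transverse
  ice ball implies a freeze margin of only a few millimetres in 15 minutes,
  which no plateau near −150 °C can produce with these tissue constants; the
  real hardware's surface-average temperature must be substantially milder.
  Relative and structural predictions (merge dynamics, symmetry, coverage
  ranking, convergence, conservation) are unaffected; absolute dimensions
  should be trusted only after calibrating the load curve to the actual
  console.
* For the same reason, at 900 s the −40 °C front has swallowed the
  interstitial pockets in every multi-probe layout, so the warm-zone volume
  is dominated by the outer sub-0 °C shell and grows with probe count
  instead of shrinking; with a calibrated (milder) curve the expected
  five > seven > nine pocket ordering would re-emerge during and at the end
  of the freeze.
* Homogeneous isotropic tissue; no vasculature or heat-sink effect; ex vivo
  perfusion defaults are a modelling convention, not a measurement.
* The damage clock is a threshold/time model; it reproduces a sharp
  predicted boundary, whereas real lesions show a diffuse transition zone —
  absolute lethal-margin predictions carry that structural uncertainty.
* Single freeze(-thaw) cycle only; the load curve supports one thaw ramp.
* Cell-centered uniform grids: the probe is resolved to at best one cell
  column; near-probe gradients within ~1 mm of the shaft are not converged.
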