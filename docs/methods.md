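# Methods

This note records the models, numerical choices and limitations behind
`chipflow`, in the order the pipeline uses them.

## Scope and model summary

A chip is a user-supplied decomposition (a *netlist*) into rectangular
channel segments and T/+ intersections on an x-y plane (y northward, SI
units).  Channel flow is modeled with the hydraulic resistance of a
rectangular duct; junction flow with planar incompressible Stokes flow;
particles as massless streamline tracers with a finite-size wall-freeze
rule.  The working fluid defaults to water (η = 1.0e-3 Pa·s,
ρ = 998 kg/m³).

Validity envelope (set by the pre-simulated library): 200 µm channel
widths, T- or cross-shaped junctions, 90° turns, drive speeds ≤ 2 cm/s,
particle diameters 1–20 µm.  At this operating point Re = ρUw/η ≲ 4 and
the particle Stokes relaxation time d²ρ_p/(18η) ≤ 2.3e-5 s, the two facts
the whole method rests on.

## Hydraulic network

Each segment carries `R_h = 12 η L / (w h³ F)`, with the form factor

    F(h, w) = 1 − (192/π⁵)(h/w) Σ_{n odd} n⁻⁵ tanh(nπw/(2h)),

evaluated with the shorter side in the series argument (making F symmetric
in (h, w)) and truncated at n = 99 (truncation < 2e-9).  Limits: F → 1 for
parallel plates, F ≈ 0.4217 for a square duct.

Pressures are solved by sparse nodal analysis: pressure-specified terminals
are Dirichlet nodes, velocity-specified terminals inject Q = u·w·h as
sources, and a network with no pressure reference (balanced sources) pins
one node to 0 Pa.  The loop law holds identically because a single-valued
pressure potential is solved; the node law holds to solver precision
(measured residuals ~1e-15 relative).  Channel height h is a required
netlist field; fixtures default to h = 100 µm (w = 200 µm), a typical
soft-lithography aspect ratio.  Only relative geometry enters particle
routing, so this choice affects absolute flow rates, not streamline
positions, in uniform-height chips.

## Unit-intersection flow solver

The junction prototype is a 1.6 × 1.6 mm footprint with 200 µm arms
meeting at its center; unused arms are omitted from the mask (the junction
is T-shaped exactly as in the physical chip).  The solver treats the flow
as planar (depth-averaged) stationary Stokes flow:

* staggered MAC grid (u on vertical faces, v on horizontal, p in cells),
  second-order centered differences; tangential no-slip enters through
  ghost-value reflection across walls, which for plane Poiseuille flow
  gives a uniform error of exactly C·h²/4 — hence clean second-order
  convergence, verified by the mesh-refinement test (error ratio ≈ 4 per
  halving, the mesh-independence check);
* inlet and all-but-one outlet arms carry prescribed fully developed
  parabolic profiles u(t) = (3/2)·ū·[1 − (2t/w − 1)²] (the arms are 3.5
  widths long, far beyond the entrance length at Re ≈ 1, so hand-off at
  the arm mouths assumes developed flow);
* the remaining outlet (largest outflow; ties broken N < E < S < W) is an
  *open* mouth: zero normal-velocity gradient with the boundary pressure
  fixed at 0 — this both absorbs the discrete mass balance and anchors the
  pressure level.  A side effect is that nominally symmetric
  configurations are discretized slightly asymmetrically; fields are
  mirror-symmetric only to truncation level (~h² relative), which the
  symmetry tests reflect;
* the momentum rows are scaled by h²/η and pressure by h/η so the
  saddle-point system is O(1), then factorized with SuperLU.

Inertia is neglected by default, keeping the problem linear; linearity is
what lets one stored field represent every uniform speed-scaling of its
boundary conditions, and it is verified (solve(2v) = 2·solve(v) to 1e-10).
A Picard-iterated convective correction exists behind the
`convective=True` flag for parity experiments and is off for library
builds.  Grid spacings must divide 100 µm (arm-edge alignment); library
builds default to 4 µm, coarse tests use 10–25 µm, and the direct
whole-chip oracle runs the same solver on the rasterized chip polygon.

Discrete incompressibility is asserted at max |div u| < 1e-8·max|u|/h
(measured ~1e-11 1/s, i.e. orders below the bound).

## Particle tracing

Massless advection dX/dt = u(X) by RK4 with bilinear interpolation on the
staggered grid; adaptive steps bounded to half a cell per step, hard cap
10⁷ steps, stagnation (speed < 1e-9 of the field peak) is an error rather
than a silent perturbation.  One layer of faces beyond each mouth is
filled by zero-gradient extrapolation so RK4 substeps that peek past an
open boundary see sensible velocities; wall ghosts reflect (no-slip).

Finite particle size enters only twice: releases are inset one radius from
the walls, and a particle freezes permanently when its center comes within
one radius of a wall (center-to-wall distance, recorded in trajectory
provenance; wall distance is interpolated from the Euclidean distance
transform of the mask, exact for flat walls and O(h) near corners — the
only practical consequence is that the most extreme wall-hugging releases
can freeze at junction corners).  No lift, Brownian motion or inertial
migration is modeled: the relaxation-time bound above (asserted at
configuration time for the massless mode) makes streamline-following the
appropriate model at these scales.

The cumulative-flow coordinate `q(y) = ∫u dy / ∫u dy |_w = s²(3 − 2s)`,
s = y/w (parabolic profile), labels streamlines from the right-hand wall
(looking downstream).  Because the right wall stays the right wall through
straight channels and 90° turns, q is conserved along a particle's path
between junctions; measured |Δq| is ≲ 4e-4 through a 90° turn at 10 µm
spacing.  q is evaluated analytically at channel cross sections and arm
mouths, and numerically (by tracing) inside junctions.

## Intersection library

Random instances follow the population scheme: a configuration uniform
over the 14 feasible inlet/outlet patterns (16 minus all-in and all-out;
arms optionally degraded to unused), inflows uniform on (0, 2] cm/s, N−1
of N outlets uniform on (0, 2] cm/s, the last outlet balancing; draws
whose balance is non-positive are rejected (bounded at 10³ attempts).
Each record stores the solved field, provenance, and a bank of 10
uniformly spaced releases per inlet arm per configured diameter.

Matching reduces specs to canonical form under the 8 square symmetries
plus normalization by total inflow (both exact invariances of Stokes
flow), then requires *exact* canonical configuration equality and ranks by
L2 distance between normalized velocity 4-vectors, ties by record id.
Configuration mismatches change the topology of the streamline split and
cannot be interpolated, hence the exact-equality rule; it is recorded in
match provenance.  The returned transform (rotation/reflection + velocity
scale) maps the stored record onto the query; reflections flip q → 1 − q.
Normalization collapses the magnitude dimension of the stored ensemble;
`normalize=False` restores magnitude-keyed lookup for compatibility with
much larger libraries.

Retrieval offers two modes.  Mode A (default) re-traces the query particle
on the retrieved field from its actual entry position — no flow solve, one
cheap streamline integration, strictly more accurate at equal cost.  Mode
B is pure lookup: the exit flow fraction is linearly interpolated between
the two stored releases bracketing the entry position; when the brackets
disagree on exit arm or fate, the nearer release wins (ties toward the
smaller entry position), with the decision recorded in provenance.

Storage is a single HDF5 file (schema-versioned; gzip-compressed arrays;
`records/<id>` groups with a `traj/<diameter-nm>/<arm>/<k>` tree), so no
database server is needed.  Libraries here are built on demand at desk
scale (tens of records, or exact-match records for a specific chip via
`specs=`); production-scale ensembles are a matter of build time, not
design.

## Whole-chip stitching

For each released particle: network solve → entry q at its terminal →
alternate channel propagation (q constant; the path is the centerline
offset to the flow-fraction position, corners displaced by
offset·(left₁ + left₂)) and intersection traversal (library retrieval,
entry/exit mapped through the match transform) until a terminal is reached
or the particle freezes inside a junction (no re-entrainment).  Channel
polylines are trimmed half a footprint (0.8 mm) where they enter a
junction, so segments between two junctions must be ≥ 1.6 mm and terminal
segments ≥ 0.8 mm; stitched pieces join on the mouth planes with zero gap
by construction (asserted < grid spacing).

Dividing-streamline ties inside a junction are resolved by the
deterministic tracer (and, in mode B, by the snap rule above): determinism
over realism at a measure-zero event.

The envelope is enforced where the user can violate it: non-200 µm widths
abort, terminal drive speeds above 2 cm/s abort, releases at outflow
terminals abort.  Derived interior arm speeds may exceed 2 cm/s (merged
streams do, already in the canonical H example); normalization makes the
library applicable there by linearity.

`compare_with_direct` is the built-in oracle: the same particles traced on
a direct whole-chip Stokes solve, reported as a per-particle lateral
exit-position discrepancy table.  On the three-T cascade at 4 µm spacing
with an exact-match library the discrepancies are 0.019/0.006/0.027 µm;
on the H chip (20 µm library vs 10 µm direct solve) ≤ 0.7 µm.

## Problem sizes used by the test suite

Unit tests solve on 10–25 µm grids (seconds); the end-to-end cascade
check builds its exact-match library and direct solve at 4 µm (~10⁵ fluid
cells, ~3·10⁵ unknowns, tens of seconds).  These sizes were chosen so the
full suite runs comfortably on a single CPU while staying in the
asymptotic (second-order) regime the convergence test establishes.

## Known limitations

* Planar (2D) flow: the depth dimension enters only through the network
  resistances.  Out-of-plane (h-direction) particle migration and the
  depth-dependence of the in-plane profile are not modeled; the
  decomposition and its oracle share this assumption, so the agreement
  tests validate the decomposition, not the 2D idealization itself.
* Synthetic fixtures (H chip, cascade, random grid chips) exercise exactly
  the library envelope; real devices with tapered channels, non-90°
  angles or non-rectangular cross sections are out of scope by design.
* The freeze rule uses center-to-wall distance with an EDT-based distance
  field; sub-cell freeze decisions near corners are first-order accurate.
* Solute concentration fields, transients, compliance, Brownian motion and
  particle–particle interactions are not simulated.
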