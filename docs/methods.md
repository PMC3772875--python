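# Methods

## Problem and model

`graftflow` simulates pulsatile blood flow through an idealized end-to-side
anastomosis between a bypass graft (saphenous-vein type) and its host
coronary artery, and quantifies the wall hemodynamic environment through
three indices: time-averaged wall shear stress (TAWSS), oscillatory shear
index (OSI), and the wall shear stress spatial gradient (WSSG).  The
scientific question it is built around is how a focal *anastomotic
stenosis* — mild narrowing (40–60% by area) at the junction — reshapes
those indices inside and around the anastomosis.

Blood is treated as an incompressible Newtonian fluid (valid in vessels
wider than ~1 mm), with dynamic viscosity mu = 0.04 P (4.0 cp) and density
rho = 1.06 g/cm^3, matching ~45% hematocrit.  Walls are rigid and
impermeable; fluid–structure interaction is deliberately out of scope (the
compliance mismatch of an arterialized vein graft is small and further
reduced by wall thickening).  The governing equations are the continuity
and Navier–Stokes equations,

    div u = 0,
    rho du/dt + rho (u . grad) u = -grad p + mu lap u,

in CGS units throughout (cm, s, g, dyne, Poise).

At the default operating point the cycle-mean inlet Reynolds number is
~95 (band of interest 80–110), the peak inlet Reynolds number ~190
(< 250), and the Womersley number ~2.1 (band 2–2.8); the flow is laminar
and strongly pulsatile but inertially moderate, so no turbulence model is
used or needed.

## Synthetic geometry

The host artery is a straight cylinder of radius r_a (default 0.15 cm,
i.e. a 3 mm coronary) along z with the junction at the origin.  The graft
is a straight cylinder of radius r_g = r_a sqrt(CSA ratio) whose
centerline meets the host centerline at the graft angle theta (default
45 deg; 85 deg models a steep take-off).  The proximal host is occluded —
a capped stub with no-slip walls — so the entire graft flow leaves through
the distal host, the configuration that motivates the bypass in the first
place.  The junction orifice is the analytic cylinder–cylinder
intersection curve; toe (distal lip), heel (proximal lip) and floor
(opposite wall) landmarks are recorded during construction.

Default conduit lengths are: distal host 0.9 cm, proximal stub 0.6 cm,
graft 0.7 cm.  These give at least two host diameters of development room
on each open end while keeping desk-tier runs small.

### Stenosis

Focal stenosis is a *radial warp of space*: within an axial band of
half-length E centered on z0, radii scale by

    f(z) = sqrt(1 - (pct/100) * w(z)),    w(z) = (1 + cos(pi (z-z0)/E))/2,

so a plain-tube cross-section loses exactly `pct` percent of its area at
the throat.  The displacement fades smoothly (cosine) to zero between one
and two host radii from the host axis, which lets the warp narrow the
junction region without disturbing the graft conduit away from it.  The
same warp is applied to surface vertices and to volume-mesh lattice points
(before triangulation), so surface and volume representations are always
consistent, and the measured-area round trip on straight tubes is exact.

Defaults: the band is centered on the junction (z0 = 0) with E = 1.5 host
diameters, i.e. an anastomotic stenosis spanning the junction orifice.  A
shorter focal lesion is available through `stenosis.extent_diameters`.
Severity classes follow the clinical bands used for these lesions:
< 20% "small", 40–60% "mild" (boundaries closed on the left), > 60%
"severe"; the 20–40% range carries no named class.

### Inlet waveform

The measured graft velocity waveform is represented by a two-harmonic
Fourier series

    v(t) = V (1 + a1 cos(2 pi t/T + phi1) + a2 cos(4 pi t/T + phi2)),

with defaults V = 12 cm/s, T = 0.84095 s (121 steps of 0.00695 s),
a = (0.8, 0.35), phi = (pi, pi/2).  These were chosen once to give a
strongly pulsatile but non-reversing graft inflow (peak/mean ~2.0, minimum
~0.3% of the mean) with the cycle-mean and peak Reynolds numbers inside
the bands above.  Synthesis rejects (rather than clips) parameter
combinations that would drive the inlet velocity negative.

## Meshing

Two built-in backends produce linear tetrahedral meshes; the mesh contract
(positive volumes, watertight tagged boundary, median edge near target) is
normative, not the backend.

* **Swept tube mesher** — a structured triangulated disk extruded along z;
  each prism splits into three tetrahedra with a globally consistent
  diagonal rule.  Used for all straight-tube validation fixtures.
* **Lattice-Delaunay junction mesher** — structured section rings along
  host and graft axes (alternate layers rotated by half the angular pitch
  to avoid the cospherical degeneracies of straight extrusion), the
  analytic orifice curve, a small deterministic jitter on interior points,
  two Laplacian relaxation passes, scipy Delaunay, and a point-membership
  filter keeping tetrahedra whose centroid lies inside the lumen union.
  Flat boundary slivers (all nodes on the surface lattice) are stripped;
  their removal moves the discrete boundary by less than the faceting
  error.

Patch tags travel as integer cell data with the fixed legend {1 inlet,
2 outlet, 3 wall, 4 occluded cap} in both supported file formats (Gmsh
MSH 4.1 and VTK legacy unstructured, ASCII).

Mesh dependency is assessed the standard way: steady solves at the
cycle-mean inlet velocity across successive refinements, converged when
the peak velocity changes by < 1% between levels.

## Flow solver

Equal-order linear (P1–P1) velocity/pressure elements with SUPG/PSPG
stabilization; backward-Euler time integration; Picard (lagged-convection)
linearization.  Choices that matter:

* **Stabilization parameter.** Per element,
  tau/rho = [ (2 rho |a| / h)^2 + (12 mu / h^2)^2 ]^(-1/2) with h the rms
  edge length and `a` the element-mean advection velocity.  The time-step
  term often added to tau is deliberately omitted: including it makes the
  transient operator inconsistent with the steady one in the steady limit
  (the classic small-time-step PSPG pathology), and the constant-inflow
  transient then fails to converge to the steady solution.  The form above
  is finite for rho = 0, which gives a clean Stokes/creeping-flow path.
* **Boundary conditions.** No-slip on wall and occluded cap.  Blunt (plug)
  inlet: a uniform velocity on interior inlet nodes with the no-slip rim
  prevailing; the plug value is scaled so the *discrete* inflow integral
  equals (mean velocity) x (inlet area) — without this the rim removes
  20–30% of the flux at desk resolutions and neither the Poiseuille nor
  the Womersley oracle can be met.  Stress-free outlet: the homogeneous
  natural condition of the Laplacian (pseudo-traction) form.
* **Linear solves.** Sparse LU with defect-correction reuse: a
  factorization is kept across Picard iterations and time steps, each
  iteration applying one correction x += LU^-1 (b - A x) with the freshly
  assembled matrix; refactorization happens only when the contraction
  stalls.  This cuts transient runtimes ~6x with bitwise-identical
  converged results (the stopping test is on the assembled system, not on
  the stale factorization).
* **Time stepping.** From rest; the reference temporal resolution is
  dt = 0.00695 s, 121 steps per cycle, three cycles, with the first
  cycle(s) acting as burn-in.  The desk tier runs two cycles and reports
  the cycle-to-cycle periodicity metric (relative L2 difference of
  matching snapshots; ~2% at desk tier) as a guard.  Only the final cycle
  (steps_per_cycle + 1 closed snapshots) is retained.

Discrete mass conservation is monitored per snapshot (inlet/outlet flux
imbalance; machine-precision in practice because the stress-free outlet
makes the system globally conservative).

## Wall shear recovery and indices

Wall traction is recovered by **consistent-flux (variational reaction)
extraction**: for each wall node the assembled momentum residual of the
discrete solution — viscous, pressure, convection and (in transient)
backward-difference inertia terms integrated against that node's basis
function — equals the boundary integral of the pseudo-traction.  Dividing
by the lumped boundary mass and negating (the residual integrates the
traction on the fluid) gives the nodal wall traction; projection onto the
tangent plane of the area-weighted nodal normal removes the pressure part
and yields the wall shear vector.  This recovery is exact for fields
linear over an element (Couette fixture, to machine precision) and roughly
one order more accurate than raw P1 gradients: the developed-tube wall
shear at a 0.04 cm edge is within ~1.5% of 4 mu V / r, where raw gradients
err by ~13%.

Indices over the closed final cycle (trapezoidal integration):

* TAWSS = (1/T) int |tau| dt.
* OSI = 0.5 (1 - |int tau dt| / int |tau| dt), clamped to [0, 0.5] and
  defined as 0 where the shear vanishes identically (no flow = no
  oscillation).
* WSSG: per wall triangle and snapshot, a local tangent frame (m, n) with
  m along the instantaneous face-mean shear direction (cycle-mean
  direction when degenerate); the P1 surface gradients of tau.m and tau.n
  give sqrt((d tau_m/dm)^2 + (d tau_n/dn)^2), which is time-averaged and
  area-weighted to nodes.  Exact for shear fields linear over a flat
  strip.

Nodes whose one-ring touches an inlet/outlet rim are flagged and excluded
from regional statistics to avoid boundary gradient artifacts.

## Regions and statistics

Regions A–D follow the toe/heel/floor nomenclature: A = host-artery toe,
B = graft toe, C = heel, D = floor (host wall opposite the orifice).  Each
is the set of wall nodes within geodesic distance 0.75 r_a of its landmark
(Dijkstra on the wall edge graph), restricted to its own vessel; because
the source protocol for drawing these regions is not quantitative, the
radius factor is exposed in configuration, and on coarse meshes a disk
grows geometrically (capped at 2 r_a) until it holds at least 6 nodes so
that regional statistics and t tests are well posed.  A and C are made
disjoint by assigning contested nodes to the closer landmark.  Axial bands
(stenotic / proximal / distal) are one host diameter wide, centered on the
throat and one diameter up/downstream, restricted to the host wall.

Regional summaries are node-unweighted mean ± sample SD (area-weighted
means recorded alongside).  Comparisons use the two-sided two-sample
Student's t test with pooled variance — the spreadsheet default the source
analysis used — with Welch's form behind a flag; significance at p < 0.05,
no multiple-testing correction (none was applied in the source analysis).

## Tiers and problem sizes

Two tiers formalize the gap between reference resolution and desk-scale
runs; all shipped analyses and acceptance checks use the desk tier.

| tier | edge (cm) | cycles | junction mesh | one pulsatile case |
|------|-----------|--------|---------------|--------------------|
| desk | 0.06 | 2 | ~0.9k nodes / ~3.9k tets | ~1–2 min on one CPU |
| production | 0.03 | 3 | ~6k nodes / ~30k tets | tens of minutes |

Validation fixtures use finer straight-tube meshes (0.04 cm edge) where
the analytic oracles demand it.

## What the synthetic generator does and does not emulate

It emulates: the end-to-side topology with occluded proximal host, graft
angle and CSA-ratio variants, focal area stenosis of controllable
severity, and a pulsatile non-reversing graft inflow with the reported
Reynolds/Womersley characteristics.

It does not emulate: patient-specific lumen shape — in real CTA-derived
anastomoses the junction region is locally much wider (bulbous), so toe-
and heel-region WSS can fall below 4 dyne/cm^2 while the compact
two-cylinder idealization carries its whole flux at a developed-flow WSS
floor of 4 mu V / r_a ~ 13 dyne/cm^2.  Threshold claims that depend on
that local widening (peri-stenotic and toe/heel WSS depression below
4 dyne/cm^2) therefore do not transfer to this geometry, while claims
driven by the stenosis itself (band TAWSS elevation, OSI suppression by
inertia) do.  Likewise, desk-tier meshes under-resolve the thin toe
separation bubble that amplifies OSI and WSSG contrasts between geometry
variants; the 2x2 sweep reproduces directions driven by flux but not the
large OSI/WSSG amplification factors.

## Numerical choices and degenerate inputs

* Picard tolerance 1e-4 (relative velocity increment), max 20 iterations;
  2–3 suffice per time step in practice.
* Zero inlet speed short-circuits to the exact rest state.
* OSI denominator zero maps to OSI = 0; WSSG frame falls back to the
  cycle-mean shear direction when the instantaneous shear is < 1e-12.
* Stenosis of 0% is an exact identity; bands overlapping inlet/outlet
  planes are rejected rather than clipped.
* Mesher randomness (interior lattice jitter) is fully determined by the
  case seed; identical configurations give byte-identical reports.
* The area-stenosis measurement slices perpendicular to the host axis,
  skips open sections (slices through the orifice) and refines around the
  coarse minimum; the reference section is the most distal closed slice so
  surface faceting cancels in the ratio.

## Known limitations

* Rigid walls, Newtonian rheology, laminar flow — appropriate for this
  regime but untested outside it.
* The lattice-Delaunay junction mesh has a jagged seam at the orifice at
  the element scale; regional statistics near the seam carry
  resolution-level noise (mitigated, not removed, by consistent-flux
  recovery).
* Backward Euler is first-order in time; at 121 steps/cycle the Womersley
  fixture shows ~2% L2 velocity error, but stronger harmonics would
  need more steps.
* Geodesic region disks approximate a protocol that was never specified
  quantitatively; absolute region areas are not comparable quantities.
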