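# Methods

This note documents the model implemented by `astral_mikado`, the
numerical choices behind it, and what the package's tests do and do not
establish.  Units are um, pN and s throughout.

## Network generation

An astral network is parameterized by the astral number `a_n` (filaments
per aster), filament length `ell` (default 1 um), domain side `s`
(default 10 um) and either the aster count `N_n` or the density
`rho = a_n N_n ell / s^2` (default 7.5 /um, the average filament length
per unit area).  When `rho` is prescribed, `N_n` is the nearest integer
to `rho s^2 / (a_n ell)` — nearest-integer rounding keeps the realized
density (which is recomputed and stored) closest to the target.

Aster centers are i.i.d. uniform on `[0, s]^2` and filament orientations
i.i.d. uniform on `[0, 2*pi)`.  Boundaries are open and non-periodic;
filaments may protrude outside the domain — the spanning criterion
relies on such protrusion.  With `a_n = 1` the aster center is simply
one end of the filament and the model reduces to a classical Mikado
(random stick) network.

Crosslinks are the pairwise intersections of filaments from *distinct*
asters (same-aster filaments only meet at the center).  Intersections
are found exactly: a KD-tree radius query on segment midpoints prunes
candidate pairs (two intersecting length-`ell` segments have midpoints
at most `ell` apart, so the pruning is lossless), then the standard
cross-product parametric test decides each pair, with an on-segment
tolerance of 1e-9 um.  Collinear overlaps are rejected; they have
probability zero under continuous sampling.

## Connectivity and percolation

The crosslink graph has one vertex per aster and one edge per
crosslinked aster pair (parallel crosslinks collapse).  Components are
found with `scipy.sparse.csgraph.connected_components`.  Two percolation
modes:

- **Spanning**: some component owns crosslink/boundary-crossing points
  with `y >= s` *and* with `y <= 0`.  Crossings of the full lines
  `y = 0` and `y = s` count here (and only here — they do not enter the
  dangling-end or node statistics).
- **Connectivity**: the component count equals one.  Isolated asters
  count as components (strict uniqueness).

Monte Carlo percolation probabilities carry Wilson 95% intervals.  The
critical density `rho_c` is where a smoothing spline fitted to the
probability curve crosses 0.5; the smoothing parameter is selected by
generalized cross-validation (`scipy.interpolate.make_smoothing_spline`,
overridable), the upward crossing nearest the empirical 50% point is
bracketed on a fine grid and located by bisection to 1e-4 /um.  Curves
with fewer than five points fall back to linear interpolation.

A consequence of strict uniqueness with open boundaries worth knowing:
for `a_n = 1`, a filament hugging an edge or corner can stay crosslink
free with non-negligible probability at *any* practical density, so
`rho_c_conn(1)` is far above `rho_c_conn(2)` — an aster with two or more
arms is exponentially harder to isolate.  This is the mechanism behind
the minimum of `rho_c(a_n)` at low but nonzero astral number, and it
also means "dense enough" connectivity checks must use `a_n >= 2`.

## Dangling ends and productive segments

A filament interval is *productive* when bounded at both ends by a
connection; connections are inter-aster crosslinks and, for
`a_n >= 2`, the astral center (arc coordinate 0), since filament ends
meeting at a center are linked to each other precisely at their ends.
For `a_n = 1` both filament ends are free.  Everything not productive is
a dangling end; a filament with no connections at all is a *single*
dangling end of length `ell` (not two half-ends), which is what creates
the point mass at `ell` and the bimodal dangling-length histograms of
crowded astral networks.  The use-fraction is
`1 - total dangling / total filament length`.

Mechanical nodes are crosslinks (2-4 incident productive half-segments)
and astral centers (one incident productive segment per filament that
carries at least one crosslink).  Nodes with zero incident productive
segments — isolated aster centers, crosslinks between two otherwise
bare filaments — are not mechanical nodes and are excluded from the
mean.  Under these conventions the pooled mean at the reference
conditions is ~3.11 segments per node for `a_n = 1` rising to ~3.93 at
`a_n = 24` (computed by `scripts/acceptance.py`).

## Mechanics

The mechanical model is a deliberately minimal overdamped (Brownian
dynamics without inertia) simulation of the same networks:

- **Filaments**: inextensible chains, segmentation 0.2 um (6 vertices
  for `ell = 1`), discrete bending elasticity with energy
  `kappa/(2 h^3) * sum |x_{i+1} - 2 x_i + x_{i-1}|^2`, `kappa = 20 pN um^2`.
- **Asters**: a rigid body (position + angle) per aster.  Spring #1
  (1000 pN/um) ties each filament's first vertex to the body center;
  spring #2 (500 pN/um) ties the filament point 0.3 um from the center
  to the body-frame anchor 0.3 um along the filament's reference
  direction, resisting rotation about the center.  The body angle
  carries no inertia and relaxes much faster than filament positions,
  so it is updated quasi-statically each step to its torque-balance
  value (closed form from the rotated-reference projections); body
  translation is a regular degree of freedom with isotropic drag.
- **Crosslinkers**: point particles, diffusivity 10 um^2/s, binding
  range 0.01 um, binding rate 10 /s, no unbinding, stiffness 100 pN/um,
  zero rest length, seeded uniformly at 30 per filament (225 /um^2 at
  the reference density) plus 10 per um of boundary near each boundary
  filament.  A particle first binds the nearest filament in range, then
  a second, distinct filament (attachment at the projection of the
  first attachment point); doubly bound particles become Hookean
  springs between the two arc positions and never detach.
- **Boundary filaments**: chains at `y = 0` and `y = s`, segmentation
  0.5 um, bending rigidity 1e3 (shear) or 1e6 (tensile) pN um^2,
  pinned by 1e3 pN/um anchors spaced 1 um (both boundaries during
  crosslinking, bottom only during loading).
- **Drag**: viscosity 0.01 pN s/um^2, applied as drag per unit filament
  length (end vertices carry half shares), so a unit filament has total
  drag `0.01 pN s/um`.  Aster bodies get a fixed small drag
  (`viscosity * 0.1`); drags only set relaxation rates, not the steady
  states the moduli are read from.
- **Integration**: semi-implicit Euler, dt = 0.01 s.  Every isotropic
  quadratic force term (bending, crosslink springs, anchors, aster
  springs) is treated implicitly; because each such term is a scalar
  stiffness times the 2x2 identity, the system matrix is one scalar
  sparse matrix applied to the x and y coordinate columns.  It is
  factorized (`scipy.sparse.linalg.factorized`) once per topology
  (binding/anchor configuration) and reused, which is what makes long
  force phases cheap.  Applied forces, thermal noise (optional, off by
  default; kT = 0.0042 pN um when on) and binding are explicit.
- **Inextensibility**: restored after each step by constraint
  projection — Newton iteration on the segment-length constraints,
  solving the drag-weighted tridiagonal system `J W J^T lambda = -c`
  per chain (Thomas algorithm, vectorized across chains) to tolerance
  1e-9 um, with an error raised after 50 iterations.  Pinned vertices
  get zero constraint weight; fully pinned segments are skipped.

### Experiment protocol

Phase 1 (0-5 s): both boundary filaments anchored, no external force;
crosslinkers diffuse and bind.  With thermal noise off, filaments carry
no force until springs form and the spring strains are bounded by the
binding range (0.01 um), so filament geometry is held fixed while
binding is simulated — binding events are then scheduled exactly
(exponential waiting times against a static geometry) — and the
residual crosslink strain is relaxed quasi-statically at the end of the
phase.  Binding is not continued into the force phase: at a 10 /s rate
against a static geometry the binding process has saturated well within
5 s, and freezing topology at the phase boundary preserves the
"same seed, same network" property that lets one network be swept over
several forces.

Phase 2 (5-45 s): top anchors removed; constant force on the top
boundary filament (full `F` rightward on its right end for shear,
`F/2` upward on each end for tension).  The response is the network
center-of-mass displacement (boundary filaments excluded) between the
phase-1 and phase-2 endpoints, taken along the loading direction.
Because the noiseless dynamics is autonomous, the force phase exits
early once the per-step displacement stays below a steady tolerance
(1e-9 um by default; ensemble studies use 1e-5 um, which bounds the
displacement error by ~1e-3 um against signals of order 0.1-1 um).
Releasing the top anchors lets the crosslinked network settle slightly
even at `F = 0`; this release transient (~1e-2 um) is the irreducible
"zero-force displacement" of the protocol.

### Moduli

The modulus is the zero-intercept least-squares slope of `F` against
displacement, `sum(F d) / sum(d^2)`, in pN/um — equivalent to a
stress-strain slope since stress is `F/s` and strain `d/s`.  All pairs
enter the fit even when curved; fractured networks produce huge
displacements and hence near-zero moduli; a negative slope is assigned
modulus 0; all-zero displacements under load return inf (flagging a
rigid-anchored artifact).  The weak-network fraction uses the
lower-median convention for even sample sizes.  The
distance-to-criticality analysis correlates `log10(modulus)` with
`log10(rho - rho_c_conn(a_n))` by default (zero moduli and non-positive
distances excluded and counted); a linear-x variant is computed
alongside.

## Scaled-down study conditions

The full-scale study (10 um domain, thousands of Monte Carlo samples,
30-100 networks per condition, 4-6 forces each) is cluster-scale.  The
package's tests reproduce the qualitative results at desk scale, with
sizes chosen as the package's own defaults for quick verification:

- Percolation: 5 um domain, 150 samples per density, per-`a_n` density
  grids bracketing each 50% crossing.
- Mechanics ensembles: 5 um domain, working density 10.5 /um, 6-8
  networks per condition, 3 forces per network, 20 s force phase with
  early exit.  On the smaller domain the finite-size percolation
  thresholds sit higher than at 10 um, so the working density is chosen
  to occupy the same position relative to the thresholds
  (`rho_c_span(1) ~ 6`, `rho_c_conn(4) ~ 8`, `rho_c_conn(16) ~ 11` at
  5 um) as the reference density does at full scale; at 7.5 /um on a
  5 um domain nearly every `a_n = 16` network fractures and the
  variance structure degenerates.

What the scaled tests show: the modulus peak at intermediate `a_n` (in
both loading modes), variance growth with `a_n`, threshold minima at
low nonzero `a_n`, and a positive modulus/distance-to-threshold
correlation.  What they do not show: the full-scale values of the
thresholds and moduli, the 30-40% weak fraction at high `a_n`, or full-scale
correlation coefficients — those require the cluster-scale ensembles; the weak-fraction check at reduced N is therefore a
binomial-CI consistency test, not a point estimate.

## Known limitations

- Monodisperse `a_n` and `ell` only; no polydispersity.
- No motors or active contractility; passive response only.
- No steric interactions, filament turnover, growth or fracture.
- The synthetic generator's uniform placement has no spatial
  correlations between asters, so real-network features like bundling
  or density gradients are out of scope.
- Crosslinker binding uses a straight-filament geometry cache and stops
  at the loading phase; under strong thermal motion during crosslinking
  this approximation would need revisiting.
- 2D only; the spanning/connectivity definitions are tied to the two
  horizontal boundaries.
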