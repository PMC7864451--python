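# Model and methods

## The physical picture

Early holoblastic embryos partition a fixed egg volume into blastomeres
whose mutual contacts (the packing topology) decide cell-fate signalling.
`blastopack` represents each blastomere as a particle of radius `R` moving
in an overdamped, noisy environment, interacting with contacting neighbours
through a short-ranged adhesive/repulsive potential, optionally confined by
a rigid axisymmetric ellipsoidal shell, and dividing in synchronous rounds.
The questions the package answers are statistical: with what frequency does
a 4-cell embryo end up as a line, T-shape, square, diamond or tetrahedron,
and how long does it take to reach its mechanical equilibrium arrangement.

All quantities are dimensionless: lengths in units of the egg radius `R0`,
energies in units of the cell-cell adhesion scale `U0`, the friction
coefficient `mu = 1`, and time in units of the mechanical relaxation time
`tau_M = mu R0^2 / U0`.

## Equations of motion

Each cell follows the overdamped Langevin equation

    mu dr_i/dt = sum_{j in Omega_i} F_ij + F_i^shell + eta_i,

integrated with the Euler-Maruyama scheme at `dt = 1e-3 tau_M`:

    r_i(t+dt) = r_i(t) - grad U dt + sqrt(2 sigma dt) N(0,1)^3,

with noise magnitude `sigma/U0 = 5e-5`. `Omega_i` is the set of cells in
*contact* with cell `i` (see below) -- forces act only across genuine
contacts, not across every pair within range.

**Adaptive substepping.** An update that would move any cell more than
0.02 `R0` deterministically is advanced in shorter partial steps, with
forces recomputed after each and noise variance scaled per partial step.
This is purely a stabilization of the same SDE: the divergent shell
boundary layer makes the post-division transient stiff (a daughter can be
placed deep inside it), and a fixed `dt` of `1e-3` would overshoot through
the wall. In quiescent states the step limiter never engages.

## Cell-cell potential

`U_c(r) = S(r) U_p(r)` with a smooth support function
`S(r) = 1/(1 + exp[(r - (Ri+Rj))/a])`, `a = 0.01 (Ri+Rj)`, cutting the
interaction off at the cell size, and a Mie-type part
`U_p = A/r^alpha - B/r^beta` with `alpha = 4`, `beta = 3`. `A` and `B` are
fixed analytically so the global minimum is exactly `-U0` at the
equilibrium distance

    r*_ij = (Ri + Rj) cos(theta),

where `theta` is the cell-cell contact angle: the single parameter encoding
the adhesion / cortical-tension balance. Forces are analytic derivatives;
finite differences appear only as test oracles.

## Confining shell

The shell is the level set `x^2/a^2 + (y^2+z^2)/b^2 = 1`. Both shell
potentials are written in the **local physical gap**

    s = (1 - sqrt(c)) / |grad sqrt(c)|,

which is exactly the distance to the wall for spheres (`s = b - r`) and
first-order accurate for ellipsoids. The level gap `(1 - sqrt(c))` alone is
not a length; using it directly would squeeze cells toward the centre along
the major axis of elongated shells with forces of order 40 `U0/R0` at
positions nowhere near the wall, which suppresses the linear packings that
elongated shells are known to produce. Both potentials are active while
the wall is within the cell's reach (`s <= R`; the boundary itself counts
as active, i.e. the Heaviside step takes the value 1 at 0):

* repulsive: `U_s = A / s`, `A = 10`, diverging at the wall;
* sticky: the same Mie shape as the pair potential written in `s`, with
  equilibrium gap `r_i* = R_i cos(theta)` and depth `-Us0`.

The shell force is `-dU/ds` along the local outward normal
(`grad sqrt(c)` direction). For spheres this is the exact gradient; for
ellipsoids the correction from the spatially varying normal is second
order and neglected -- the force field is then not exactly curl-free, a
deliberate approximation documented here and tested as such.

## Contact topology

Distance cutoffs misidentify neighbours under tight confinement, so
contacts come from a bounded, radius-weighted Voronoi construction: each
cell owns a regular dodecahedron (fixed canonical orientation, the standard
`(0, +-1, +-phi)` vertex frame) whose inscribed sphere has the cell's
volume-corrected radius `R'`. For every other cell, the polyhedron is
clipped by the plane perpendicular to the centre line at distance
`d_i = r_ij R_i/(R_i + R_k)` from cell `i` (proportional split by base
radii; the midplane for equal radii). Cells `i, j` are in contact when

1. `r_ij < R_i + R_j`, and
2. the mutual plane carries a face of both clipped polyhedra.

The face test is solved exactly: all constraints are intersected in 2D on
the mutual plane by convex polygon clipping; a face counts only if its
area exceeds `1e-10 R0^2` (ties break toward "no contact", which makes
exact-square diagonals contactless -- the degenerate-square rule). A fast
path accepts faces that contain a disc of radius `1e-4` around the axis
point without clipping.

4-cell graphs are classified by isomorphism against the five reference
graphs (path, star, 4-cycle, 4-cycle plus one diagonal, complete graph);
the compiled integrator uses an equivalent edge-count/degree-sequence rule,
and the two classifiers are verified against each other on all 64 possible
4-node graphs.

## Divisions and volume correction

Divisions are synchronous every `tau_D`, first round at `t = tau_D`. Each
mother keeps its position (daughter 1); daughter 2 is placed one daughter
radius away along the division axis. Radii follow `R_n = R0 / 2^(n/3)`
(total volume conserved exactly). Ordered mode divides along `+x`, then
`+y` (each round perpendicular to the previous); when the `+` side would
put a daughter centre on or through the shell wall (closer than 0.02 `R0`),
the daughter goes on the `-` side -- the rule fixes the axis, not its sign.
Random mode draws the axis uniformly on the sphere and redraws (up to 100
times) if the daughter would sit within `0.5 (R_n + R_k)` of any
pre-existing cell other than its mother, or within half a daughter radius
of the shell wall.

Because contacting cells interpenetrate, every step each cell's radius is
corrected to absorb its overlap volume: `R'^3 = R^3 + 3 V_o/(4 pi)` with
`V_o` the sum of pairwise lens volumes with current contact neighbours
(triple overlaps neglected -- a leading-order correction). `R'` scales the
Voronoi dodecahedra; the pair potential and the contact distance cutoff
use the base radii.

## Initialization

Unconfined runs start with the egg at the origin. Confined runs draw the
egg position from an isotropic Gaussian of per-component variance `b/10`
(in `R0^2`), truncated so the egg centre keeps a physical gap of at least
`R/2` to the shell: an untruncated draw can land inside the divergent
boundary layer where no stable first step exists at `dt = 1e-3`.

## Experiments and their defaults

* **Packing frequencies**: `n_runs` seeded simulations per grid point, each
  ending one timestep before the 8-cell division (`t = 3 tau_D - dt`);
  final contact-graph labels are tabulated. Production numbers use 100-500
  runs per condition (the published campaigns used 500-10^4; the scaled-down
  counts give binomial standard errors below 0.05, enough for the >= 0.95
  dominance checks and the reported percentages).
* **Time to equilibrium**: first passage from the birth of the 4-cell stage
  (the second division) to the first contact graph classifying as the
  target; a single frame suffices (no persistence window). Censored runs
  carry `t = T_cap` and are flagged, never dropped.
* **Topology time course**: per-run time rescaled by its own `t_E`; labels
  evaluated at bin right-edges so the final bin sits exactly at `t_E`.
* **Angular MSD**: three cells of 4-cell radius immobilized in an
  equilateral triangle with side `r*`; a mobile cell starts on the rim at
  zero elevation, `r*` from the two nearest cells. `theta(t)` is its
  elevation angle about the triangle plane. The MSD is the time-and-
  ensemble averaged squared angular displacement over lag times (the
  angular walk has stationary increments, so sliding-origin averaging is
  unbiased and far less noisy than fixed-origin averaging at 8 runs);
  the log-log slope is fitted over lags in `[5, t_max/4]` with
  `t_max = 2000 tau_M`.

**Contact angles.** `theta = 30 deg` is the package-wide default. The
ordered-unconfined diamond experiment uses `theta = 45 deg`: for
`theta < 37.5 deg` (`cos theta > 2^(-1/3)`) the two mother-daughter pairs
after the second ordered division are born outside each other's interaction
range (the 2-cell equilibrium distance exceeds the 4-cell cutoff) and the
embryo splits into two non-interacting dimers, so the diamond route only
exists above that bound.

**Seeding.** One base seed spawns per-run child seeds through
`numpy.random.SeedSequence`, so every table is bit-reproducible and sweeps
cannot collide.

## What the generator emulates, and what it does not

The synthetic embryos capture: volume-conserving cleavage, adhesion
(contact angle), rigid repulsive or adhesive confinement, division-axis
rules, and thermal-scale positional noise. They do not capture: cell-shape
deformation (forces are central and isotropic), asynchronous or
size-asymmetric divisions, shell elasticity or plastic remodelling, or
yolk attachment. Passing tests therefore validate the particle-model
mechanism -- confinement geometry selecting packing topologies -- not any
particular species' full morphology.

## Known limitations

* Under ellipsoidal confinement a minority of runs (roughly a quarter to a
  third at `theta = 30 deg`, `V_s/V_c = 1.52`, `a/b = 2-3`) end in
  frustrated jammed states: flickering-contact local minima in which shell
  squeeze and pair repulsion balance with order-10 residual forces. They
  persist beyond 500 `tau_M`, so the aspect-ratio selection of diamond and
  line packings is dominant (~0.65-0.8) rather than exclusive.
* In the sticky spherical shell at `V_s/V_c <= 1.5` and `theta = 30 deg`,
  the pair equilibrium distance exceeds the diameter of the sphere on which
  shell-adhered cells sit; no relaxed 4-cell ring exists and every ordered-
  division pathway folds into the dense 6-contact packing (tetrahedron).
  Adhesion-stabilized square rings do occur in this implementation, but
  only in the ring-commensurate zone near `V_s/V_c ~ 1.6`,
  `theta ~ 42 deg`, and there they coexist with the 5-contact spherical
  rhombus (labelled diamond) rather than with the tetrahedron.
* The ellipsoidal shell force is directed along the local normal with
  magnitude `|dU/ds|`; it is the exact gradient only for spheres.
* First-passage detection has no persistence window, so a transiently
  complete contact graph at the instant of division counts as
  tetrahedral -- confined relaxation times are therefore often exactly 0.
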