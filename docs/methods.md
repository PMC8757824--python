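# Methods

`fmvsd` predicts the deployed 3D configuration of a (fenestrated) aortic
stent-graft from a single calibrated intraoperative X-ray view, a
registered vessel surface with centerline, and a parametric device
description. It is a hybrid of image constraints and a simplified
structural model: the image fixes what a single projection can fix, and a
corotational beam finite-element model fills in the rest. This note records
the model, the numerical choices, and what the synthetic validation does
and does not demonstrate.

## Two-stage procedure

**Stage 1 — global approximation.** The device is reduced to its
centerline: one cylindrical corotational beam per stent, consecutive beams
coupled in translation but free in rotation (the fabric sews stents
together without transmitting bending moments). The chain is initialized
straight and fully deployed, then relaxed to equilibrium under two
penalty fields:

- a spring (10 N/mm) from each beam midpoint to the back-projection ray of
  that stent's observed 2D barycenter — the in-plane evidence;
- a smooth wall confinement: a node carrying a stent of radius `r_s` moves
  freely within `max(r_vessel − r_s, 0)` of the vessel centerline and is
  pushed back radially beyond it (100 N/mm). Where the vessel is narrower
  than the stent the clearance collapses and the field becomes a centering
  spring — the wall compresses the stent symmetrically, so its axis rides
  the vessel centerline.

Depth along the viewing axis is unobservable in one view; each midpoint is
initialized at the point of its barycenter ray closest to the vessel
centerline, which is the natural prior and the dominant residual error
source (errors concentrate along the projection axis).

Each stent is then reconstructed geometrically: every rest-cloud vector
from the stent barycenter is scaled radially by the ratio of measured to
nominal deployment diameter, interpolated linearly from the proximal to
the distal end. Apparent diameters are measured in pixels perpendicular to
the projected device axis within the proximal/distal 20% axial bands of
the stent's silhouette, corrected for the wire width and converted to mm
by the local cone-beam magnification at the estimated barycenter depth
(without this correction all diameters would carry the f/z bias).

**Stage 2 — per-stent refinement.** First the axial rotation Φ is
recovered by minimizing the mean nearest-neighbour pixel distance d(Φ)
between the projected reconstructed stent and the target pixel set.
Z-stents are axisymmetric with period θ = 2π/n_peaks, so only Φ mod θ is
observable; stents carrying radiopaque markers minimize the marker-only
distance d_RM (minimum-cost pairing of projected spec markers to detected
dots), which pins Φ uniquely. The optimizer is differential evolution
(population 20, seeded, tol 1e-3) combined with a deterministic 0.5°
coarse scan — d(Φ) for a zig-zag ring has a narrow true minimum and a
deceptive half-period mirror basin that stochastic search alone can latch
onto — followed by a bounded golden-section polish.

Second, each selected stent's full strut lattice (Z-ring of 316L steel
wire, 0.125 mm diameter, corotational Euler-Bernoulli beams, limbs meshed
coarsely and rounded apices finely) is deployed individually inside its
rigid *deployment box*: the Boolean intersection of the back-projection
polyhedron of the stent's 2D convex hull with the vessel volume. The
lattice is posed at (B_3D, triad, Φ), crimped to the launcher diameter
(6 mm default) by a radial penalty ramped over 5 increments, released, and
relaxed against the box through spring-dashpot penalty contact. The time
step is reduced once (×0.1) at first contact.

## Corotational beam model

Each 2-node element carries the standard 12×12 Timoshenko stiffness in
local coordinates (axial EA/l, torsion GJ/l, bending blocks
12EI/(l³(1+Φ)), (4±Φ)EI/(l(1+Φ)); Φ_y = 12EIz/(G·Asy·l²) and symmetrically
for Φ_z; shear areas unset gives the Euler-Bernoulli limit Φ=0, the mode
used for stent struts). A floating frame follows the deformed element: the
chord fixes the local x-axis and the mean of the two end-frame y-axes
fixes the roll. Local deformations are the axial stretch and the end
rotations relative to this frame; local forces K·u are rotated back to the
global frame. Internal forces vanish identically under rigid-body maps
(verified to 1e-6 N), and the small-strain limit reproduces K·u to 0.1%.
Geometric stiffness terms are omitted — equilibria are found by
relaxation, not by Newton continuation, so only the residual needs to be
exact.

Rotational state is stored as rotation vectors and composed through
quaternions.

## Equilibrium solver

Static equilibria are found by damped explicit dynamic relaxation with
fictitious lumped masses: each translational/rotational DOF receives
`mass_margin · dt² · k` where `k` is the stiffness attached to it
(including constraint and contact stiffness). This makes the sweep
unconditionally stable at the chosen step; only the structure's stiffness
*contrast* governs the iteration count. Two deliberate choices follow:

- **Kinetic damping** (velocities zeroed at kinetic-energy peaks) is the
  default rather than a per-node viscous coefficient. A viscous damper
  sized to the local (stiff) frequency overdamps the slow structural modes
  that dominate stent expansion by orders of magnitude; kinetic damping is
  parameter-free and robust through the strongly nonlinear crimp/release
  path. A viscous damping-ratio mode remains available (and, with ratio 0,
  gives the energy-conserving integrator used in the drift test).
- **Axial-stiffness relaxation** (`axial_scale`, default 1, set to 1e-3
  for strut lattices): thin-wire stents have EA/EI contrasts around 1e6
  that would make explicit relaxation intractable. Equilibrium shapes are
  bending-dominated; the axial force scale in deployments (~1e-3 N) gives
  strains of order 1e-4 even with EA reduced a thousandfold, so the
  equilibrium is unaffected to well below every tolerance used. The
  elementary stiffness matrix itself is never altered.

Convergence requires max nodal residual force < `tol_force` (torques
compared against `tol_force × mean element length`) *and* kinetic energy
< `tol_ke`. Defaults: 1e-4 N / 1e-8 N·mm; Stage-2 deployments use 1e-3 N,
which changes D_PC by < 0.1 mm while roughly halving run time. Because
masses are fictitious and rebuilt as `m ∝ dt²` when the step changes, the
post-contact step reduction is stability-neutral in this scheme; it is
kept as stated behaviour (and matters whenever masses are physical).

A dense damped-Newton path (`solve_static_newton`, incremental loading +
backtracking) exists for small contact-free verification studies — e.g.
the mesh-refinement test, where the explicit step count would otherwise be
dominated by the l⁻³ growth of element bending stiffness rather than by
the discretization error under test.

Joints merge translational DOFs exactly (union-find, shared position,
summed mass and force) — no penalty, no drift. Contact follows
`max(0, k·d + c·v)` per node against a signed-distance source (analytic
tube, convex-polyhedron planes, voxel grid, or exact mesh queries), with
the wire radius as surface offset.

## Geometry and imaging

- **Devices.** Z-stents are built in the developed (unrolled) plane: 2n
  straight limbs joined by circular apex arcs of radius 2× wire diameter,
  mapped onto a (possibly tapering) cylinder with the wire centerline at
  the nominal radius. Apices are meshed at the fine size, limbs at the
  coarse size; the point cloud resamples the wire at the fine spacing.
  Fenestration rims are circles in the plane tangent to the stent cylinder
  at the rim centroid; rims and markers ride rigidly with their host stent
  through every pose change. The Stage-1 centerline beams use E = 10 MPa,
  ν = 0.3 (robustness-tuned values for the reduced model) and a 2 mm
  cylindrical section — chosen so the chain is compliant relative to the
  ray springs and wall field; a stent-diameter solid section would let
  chain bending stiffness overpower the image evidence.
- **Projection.** A calibrated 3×4 matrix; pixels have origin top-left,
  x = columns. Back-projection rays, viewing depths, and local
  magnifications all derive from it. The bundled C-arm constructor uses
  source–isocenter 700 mm, source–detector 1100 mm.
- **Segmentation.** Frangi vesselness (scales 1–4 px, bright polarity for
  the synthetic renders) thresholded at Otsu's level, small components
  dropped, then dilated back to the strut width with an intensity floor;
  components are grouped into stents by interval overlap along the device
  direction. Exact per-stent masks (synthetic labels or user input) take
  precedence and are the only way to split stents whose silhouettes touch.
  Markers are local maxima above the 99th intensity percentile inside the
  dilated stent mask.
- **Deployment boxes.** No exact mesh-Boolean kernel is assumed: the
  intersection is evaluated on a 0.5–0.75 mm voxel signed-distance grid
  (pointwise max of vessel and polyhedron fields) and re-meshed by
  marching cubes; the same grid serves as the contact environment. When
  the polyhedron lies entirely inside the vessel the intersection is the
  polyhedron itself and is returned exactly. The polyhedron is clipped to
  the vessel's viewing-depth interval padded by 10%.

## Synthetic study conditions

The generator emulates the two validation settings the method targets:

- vessels are watertight tubes of revolution around a straight or bowed
  centerline (parallel-transported frames), healthy radius 10–12.5 mm,
  with an optional fusiform sac (Gaussian radius bump, up to 27 mm — an
  oversized rigid phantom — or 20 mm — a patient-like aneurysm);
- devices follow the bundled synthetic fixtures: 28→13 and 28→20 tapered
  main bodies (7 and 6 Z-stents) and a fenestrated 28 mm device whose
  proximal stent carries right-renal, mesenteric and left-renal
  fenestrations with two radiopaque markers each;
- ground truth deploys every strut lattice against the true vessel at its
  true pose (seeded per-stent Φ). Deployment starts from the nominal ring
  rather than from a crimped state: the model is purely elastic, so the
  equilibrium is path-independent and the crimp phase adds only cost.
  In the sac-phantom scene the device path bows 2.5 mm out-of-plane inside
  the sac, emulating the unconstrained positioning of a stent-graft in an
  oversized rigid sac — precisely the region where a single view has no
  depth evidence;
- targets are forward renders: strut clouds splatted at the magnified wire
  width, markers as bright Gaussian dots, optional blur and additive
  noise, bright-metal-on-dark polarity; per-stent pixel labels are kept
  and the noiseless labels define the reference observations.

Everything derives from one seed; identical specs give byte-identical
scenes.

**What passing does and does not show.** The synthetic suite shares its
contact model, elastic model and projection model between ground truth and
method, so it isolates the errors the *procedure* introduces — single-view
depth ambiguity, barycenter/diameter measurement, rotation recovery,
box-vs-vessel confinement — under exactly known conditions. It does not
exercise fabric coupling between stents (absent from both truth and
method), wall deformability, segmentation of real fluoroscopy (markers
and struts are rendered cleanly), calibration error, or commercial strut
layouts. Bounds met here are necessary, not sufficient, for clinical
accuracy.

## Problem sizes and tolerances (reference suite)

The five-scene evaluation suite (`fmvsd.evaluation`) uses 512² renders at
0.6 mm detector pixels, strut meshes with 1.5 mm limbs / 0.4 mm apices
(~150 elements, ~1900 cloud points per stent), 0.75 mm box grids, Stage-2
release tolerance 1e-3 N, and deterministic per-scene seeds fanned out
from one master seed. The full device meshing range (2 → 0.1 mm) is
exercised by the device unit tests. A full five-case run takes a few
minutes on one CPU; Stage 1 alone is sub-second per case.

## Error metrics

D_B is the distance between simulated and target cloud barycenters; D_PC
is the *directed* mean nearest-neighbour distance simulated → target (not
symmetrized). Quality classes: excellent < 3 mm, good < 5 mm,
insufficient ≥ 5 mm; the boundary values 3 and 5 are assigned upward,
since the defining inequalities leave them open. Fenestration error is
the Euclidean distance between rim centroids. Synthetic target clouds are
strut-centerline samples (not surface voxels); both sides of every
comparison use the same convention.

## Known limitations

- No fabric membrane, stent-to-stent contact, or strut self-contact; no
  plasticity or superelastic laws — the wire is linear elastic 316L
  (E = 193 GPa, ν = 0.30).
- The tube signed-distance field treats the radius as locally constant;
  for the gentle tapers and sacs generated here the error is far below
  contact tolerances, but steep radius gradients would need the exact
  mesh path.
- Stents whose silhouettes overlap in projection cannot be separated
  without masks; such stents should be excluded from evaluation, and the
  metrics container carries an `excluded` flag for exactly that.
- Depth (out-of-plane) error is bounded by the quality of the
  ray–centerline prior and wall confinement, not by the optimizer: in a
  wide sac the single view simply contains no depth information.
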