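# Methods

## Model overview

`pelvifem` simulates the quasi-static mechanics of the female pelvic
system under a straining (Valsalva/defecation-phase) load, before and
after posterior sacrospinous ligament fixation (SSF).  The model is a
*membrane–truss idealisation*: hollow organs, the pelvic floor and the
fasciae are thin shells without bending stiffness; ligaments, sutures and
fascial couplings are one-dimensional filaments.  All lengths are in mm,
stresses and moduli in MPa, forces in N (MPa·mm² = N).  The coordinate
frame is x lateral (patient-right positive), y anterior, z superior, with
the midsagittal plane at x = 0.

## Geometry

No individual anatomy is shipped; a procedural generator builds a
stand-in that preserves the topology, the attachment pattern and the
landmark relations the mechanics depend on:

| structure | primitive | role |
|---|---|---|
| vagina | flattened elliptic tube, closed apex | vault; carries the C point |
| bladder | ellipsoid shell | anterior compartment; Ba point |
| rectum | curved capped tube | posterior compartment; Bp point |
| pelvic floor | elliptic basin membrane, rim fixed | levator plate |
| pubocervical / endopelvic fascia | bowed ruled sheets | organ spacing |
| ligaments | polylines → truss chains | suspension and anchorage |

Key defaults (all config-exposed, chosen as representative adult female
pelvimetry, not as claims about any patient): inter-spine width 100 mm,
pubococcygeal-line length 100 mm, sacrospinous ligament length 45 mm,
organ semi-axes of ~20–30 mm, membrane thickness 3 mm for organ walls,
2 mm for the pelvic floor, 1 mm for fasciae.  The pathological vault is
placed low, near the ischial-spine plane, as in a stage-III apical
prolapse; this matters mechanically, because a fixation can only restrain
an apex that descends *away from* the ligament anchor.

The generic variant is strictly mirror-symmetric: surface tessellations
use an even azimuthal count with the quad-split diagonal chosen by the
sign of the quad centre's x coordinate, and vertex positions are
symmetrised to exact mirror pairs.  Nearest-node link construction adds
*all* tied-distance candidates, so the link topology is symmetric too.
The patient-like variant shifts the bladder laterally by the asymmetry
amplitude (default 5 mm) and adds seeded smooth in-plane perturbations of
the organ positions; it is post-hysterectomy (no uterus), while the
generic variant keeps a uterine body linked to the vaginal apex.

The "pathological" support condition disables the broad and round
ligament groups (they contribute no stiffness downstream); the
uterosacral and cardinal ligaments remain active.

## Constitutive models

Hollow organs use the two-term Yeoh solid,
`W = C0(I1−3) + C1(I1−3)²`, with the incompressible plane-stress
reduction for membranes: thickness stretch `λ3 = 1/(λ1 λ2)`,
`I1 = λ1² + λ2² + 1/(λ1λ2)²`, and in-plane second Piola–Kirchhoff stress
`S = 2 W'(I1) (I − C⁻¹/det C)`.  Coefficients (MPa): vagina
(0.111, 0.27), bladder (0.0375, 0.07), rectum (0.085, 0.056).  Supporting
structures are St. Venant–Kirchhoff plane-stress membranes: pelvic floor
E = 0.1, fasciae E = 0.18, ν = 0.45 (the Poisson ratio applies to the
linear-elastic structures only; the hyperelastic membranes are treated as
incompressible).

Filaments carry `N = EA(λ−1)` along the current axis.  Sutures
(E 3000 MPa — polypropylene range; A 0.2 mm²) and the slender suspension
ligaments (E 5 MPa, A 10 mm²) are tension-only.  The sacrospinous
ligament is a broad band embedded in the coccygeus/sidewall complex, so
its chain carries both signs and every interior chain node is coupled to
fixed sidewall anchors through an elastic "ligament bed" (E 3 MPa links in
two independent directions).  Without that transverse anchorage a truss
chain behaves as a slack string and a suture simply drags the anchor off
the ligament line, which suppresses the entire surgical effect.

Membranes additionally carry a small isotropic resting tone (surface
tension, default 2·10⁻³ N/mm ≈ a few percent of the organ moduli at the
default thicknesses).  Tissue tone is physical, and it is also what gives
an unpressurised membrane model its transverse stiffness; a perfectly
stress-free membrane is singular.

## Loads, boundary conditions, surgery

Encastre (fully fixed) supports: the pelvic-floor border, the
sacrum/coccyx region (including the sacral ligament insertions), the bony
anchor points, and the ischial-spine bone nodes.  Three dead surface
tractions, converted to nodal loads by reference tributary areas: on the
upper vaginal surface pointing inferiorly; on the bladder dome at 45° from
the sagittal axis in the anteroposterior direction; and on the distal
rectal wall pointing inferiorly (the posterior-compartment drive).

A fixation configuration adds, per side, two tension-only suture trusses
from two distinct midsagittal apex nodes (5 mm apart; the filament
position on the vagina is not a studied variable) to a single anchor node
on the sacrospinous chain at the configured arc-length distance from the
ischial spine (default 20 mm).  Attachment is by shared nodes — the
discrete equivalent of a tie constraint at both ends.  The stress-free
length is the as-built, gap-closed length (the tied, tightened state);
an optional pre-tension strain shortens it.

## Solver

Total-Lagrangian assembly; the residual is the analytic gradient of the
total potential energy, and the tangent is assembled from central finite
differences of the batched element force kernels (consistent by
construction, half-step 10⁻⁵ mm).  Each load increment is solved by
damped Newton iteration with an Armijo line search on the energy and
adaptive Levenberg regularisation when the tangent is indefinite;
convergence is declared on the residual 2-norm only (default tolerance
10⁻⁷ N in the pipeline).  A diverging increment is bisected up to five
times; failures are returned as structured results with the full residual
history.

The desk-scale membrane model is severely ill-conditioned (wrinkling
modes, slack filament chains), so the solver adds three conditioning
devices, all documented model/numerics parameters:

* **grounding springs** (default 10⁻⁶ MPa/mm, weighted by nodal tributary
  area so the foundation is invariant under mesh refinement; area-less
  truss nodes get the median weight).  Besides conditioning, the
  foundation stands for the residual connective-tissue embedding of the
  organs.  The reported descents do depend on this parameter at the
  ~5 %/half-decade level — it is part of the model definition, and the
  calibration step pins the clinically meaningful quantities regardless;
* a **stabilization continuation ladder**: cold increments are first
  solved at 100× and 10× the grounding stiffness, then relaxed;
* a **C²-smoothed tension-only law** (smoothing width 10⁻³ strain), which
  removes slack/taut chattering of the Newton tangent; the public
  `truss_force` evaluation keeps the exact kink.

An L-BFGS energy-minimisation pre-phase carries very soft modes near
equilibrium before Newton polishes the residual when an increment starts
far from equilibrium.  The pipeline default is 2 load increments with up
to 150 Newton iterations each; warm-started re-solves (calibration steps,
surgery variants) use a single increment.  With the soft-mode stiffness
of order 10⁻⁵–10⁻⁴ N/mm per dof, a residual norm of 10⁻⁷ N resolves the
equilibrium to a few micrometres — descent differences below ~0.01 mm are
below the model's resolution.

Tie links are master–slave displacement sharing (union-find over pairs,
reduced unknowns); fixed nodes have exactly zero displacement by
construction; reactions are the residuals of the unconstrained equations
at the supports and balance the applied loads to the Newton tolerance.

## Calibration

The traction magnitudes are unknown; imaging provides displacement
setpoints.  Each driven setpoint (default: apical C = 7 mm via the
vaginal traction, posterior Bp = 6 mm via the rectal traction; the
bladder traction is not driven and the anterior point Ba is reported
passively) is solved as a scalar root-find — damped secant with factor-4
step clamping and bracket bisection — with outer fixed-point sweeps (max
5) over the weakly coupled loads.  Every evaluation re-equilibrates from
the same baseline state, which makes the magnitude → displacement map a
consistent function; monotonicity of that map is *checked* from the
sampled points (violations beyond a noise floor of 0.2× the calibration
tolerance abort with the full trace).  Default tolerance 0.1 mm.

The posterior compartment exhibits loading/unloading hysteresis: wrinkling
rearrangements of the membranes make the state reached by unloading from a
higher rectal traction differ by up to ~0.5 mm in Bp from the state
reached by loading upward.  The inverse problem is therefore conditioned
along the *loading* branch — which is the branch the calibration operates
on, since initial magnitudes default below the setpoint response — and
magnitude recovery from overshooting initial guesses is only accurate to
the hysteresis width (~20 % for the rectal load).  The rectal wall is
given a tauter resting tone than the other organs (10⁻² N/mm; its
contents keep it from going slack) and the rectal load acts on the
inferior-facing distal wall; both choices remove an outright posterior
snap-through that otherwise makes the response non-monotone.

Identifiability: the driving vaginal traction is recoverable from its C
setpoint to well under 1 %.  The joint two-load inverse problem is
conditioned only to the wrinkling-branch width — the secondary
(bladder/rectal) magnitude is identifiable to roughly 10 % — because its
setpoint response is shallow and coupled at the ~0.03 mm equilibrium
noise level.  The calibrated displacements themselves are always matched
to the stated tolerance; it is the secondary magnitudes, not the
mobilities, that carry this uncertainty.

## Descent measurement

The pubococcygeal line runs from the inferior border of the pubic
symphysis to the last coccygeal joint, both projected to the midsagittal
plane; both landmarks are fixed bone nodes, so the line is identical at
rest and under load.  The descent of a reference point is the change of
its signed perpendicular distance to that line from the rest state (the
converged zero-traction state, which includes the small tone-induced
offset) to the final converged load step, positive toward the caudal
side.  The report also carries the Euclidean ("total") displacement of
each point, and Ba is flagged not evaluable when more than a configurable
fraction (default 50 %) of its motion is out-of-plane — the asymmetric
bladder rule.

## Study protocol

`run_study` calibrates once on the no-surgery model, freezes the
magnitudes, and reuses them for every row of the surgery matrix
({none, left, right, bilateral} at 20 mm plus the 10/30 mm anchor sweep
for the bilateral and left-sided variants), so descent differences are
attributable to the repair alone.  Outputs: descent report (CSV + JSON),
VTK snapshot per configuration, and a manifest with the config hash, seed
and artifact checksums; reruns are bit-identical.

## What the synthetic data can and cannot show

The generator emulates the topology and support logic of the pelvic
system, not any individual anatomy: organ shapes are analytic primitives,
contact is replaced by fascial link elements, and bending stiffness is
neglected.  Passing tests therefore demonstrate the *method* — correct
constitutive behaviour, a consistent solver, a calibration loop that
reproduces prescribed pre-operative mobilities, and the qualitative
surgical trends (bilateral fixation restrains the apex more than
unilateral; left and right are equivalent on a symmetric pelvis; the
anchorage distance has a comparatively small effect) — on a model of
realistic scale and connectivity.  They do not validate patient-specific
absolute post-operative displacements, which depend on the true geometry;
on this synthetic anatomy the surgical effect sizes (≈1 mm of 7.5 mm
apical descent removed by bilateral fixation) are smaller than the
clinical-imaging values reported for real pelves, chiefly because the
synthetic pre-operative state is calibrated to a moderate 7 mm apical
descent.

## Numerical choices and limitations

* Constant-strain triangles; no bending, no frictional contact, no
  dynamic effects, no fibre anisotropy, no cavity-pressure (fluid fill)
  behaviour of bladder/rectum.
* Degenerate/inverted elements are flagged (det C ≤ 10⁻¹²) and drive
  load-step bisection rather than raising.
* Mesh scale: default target edge length 6 mm gives ≈2500–3000 elements
  (desk scale); refinement to 3 mm (~11 000 elements) changes the apical
  descent by ≈0.5 % at fixed loads.
* Determinism: geometry is a pure function of (params, seed); the solver
  and calibration are deterministic given the model; reports are
  byte-stable across reruns.
* Left/right equivalence on the symmetric model holds to ≈0.1 mm — the
  soft-mode resolution of the equilibrium — which is an order of
  magnitude below the bilateral-fixation effect.
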