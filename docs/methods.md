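# Methods

## Model

All kinematics are 2D, in the sagittal plane, with +x anterior (the
skull faces right), +y dorsal, lengths in millimetres and user-facing
angles in degrees.  Internally angles are counterclockwise-positive
radians; a "ventral" rotation of the anterior-facing skull is therefore
clockwise and carries a negative internal sign.  Public interfaces
accept positive "ventral"/"anterior" degrees and flip the sign
internally, so the convention cannot be misused.

The skull–neck–mandible system is an articulated chain of named point
landmarks:

* **neck**: `CAUDAL_NECK → MID_NECK → AOJ`, laid along +x ("fully
  extended" = collinear), plus `NECK_FORCE_POINT`, the caudal
  application point of the forelimb-extension force;
* **cranium**: rigid body hinged at the atlantooccipital joint (`AOJ`),
  carrying the jaw joint (`TMJ`), the upper toothrow
  (`UPPER_INCISOR_TIP`), the maxillary canine (`UPPER_CANINE_BASE`,
  `_MID`, `_TIP`), the canine-curvature centre (`VIRTUAL_POINT`) and a
  temporalis attachment point;
* **mandible**: rigid body hinged at the `TMJ`, carrying
  `LOWER_INCISOR_TIP`, `LOWER_CANINE_TIP` and `CORONOID_PROCESS`.

Soft tissue, joint surfaces, forces as functions of time and all 3D
effects are out of scope; the arguments made are purely kinematic and
lever-geometric.

## Synthetic generator

No landmark coordinates of the digitized replica are published, so the
generator (`saberbite.skull.generate`) builds configurations from
explicit parameters.  The angular parameters are the documented study
conditions: maximum gape 90° (measured at the TMJ between the incisor
tips), cranial extension +36° at the AOJ, ventral test arc 15°.  The
linear dimensions are **arbitrary, documented plumbing** — neck segments
120 + 120 mm, AOJ→TMJ 90 mm, toothrows 180/160 mm, canine curvature
radius 110 mm, virtual point (+15, −20) mm from the TMJ — chosen to be
anatomically proportioned for a large felid skull of roughly 300 mm
condylobasal length.  Every kinematic property asserted by the test
suite is quantified over randomized valid parameter sets, so no
conclusion depends on these defaults.

Construction details:

* extension is an *absolute* parameter: 0° means the cranial axis
  (AOJ→TMJ) is parallel to the neck.  The replica's neutral pose is not
  published, so the +36° study value is simply the default absolute
  extension.
* the upper toothrow sits at a fixed anatomical angle
  (`upper_jaw_offset_deg`, default −36°) below the cranial axis.  With
  the defaults this makes the toothrow horizontal, and hence the
  90°-gape mandible exactly vertical, in the bulldogging preset — the
  posture in which the mandible pins the prey.
* the maxillary canine base is placed where the curvature circle
  (centre = virtual point, radius = canine radius) intersects the
  toothrow line; the tip lies `canine_span_deg` (default 35°) further
  clockwise along the same circle, with a mid-arc landmark between
  them.  Base, mid and tip are therefore exactly concyclic, and
  `fit_circle` on them recovers the virtual point and radius — the
  round-trip the tests exercise.
* optional digitization noise is isotropic Gaussian per landmark
  coordinate, applied after exact construction and seeded
  (`numpy.random.default_rng(seed)`).  Noisy configurations are real
  data emulations and are *not* required to satisfy the exact
  invariants.

What the generator does not emulate: real digitization has correlated,
landmark-dependent error, the real canine is only approximately
circular, and a real atlantooccipital joint is not a point hinge.
Passing tests therefore demonstrate the internal consistency of the
kinematic argument, not anatomical accuracy of any particular specimen.

Presets: `bulldogging` (gape 90°, extension 36°, noise 0) is the
experimental starting posture; `shear_bite_start` is the same posture
under the name of the competing hypothesis; `strike_end` is full
closure (gape 0°).  Gape is validated in [0°, 180°): 0° is the
legitimate closed posture.

## Rotation experiment

`apply_trial` rotates every landmark rostral to the chosen pivot
ventrally through the arc; the pivot and everything caudal to it stay
fixed.  The original experiment rotated a whole image; rotating only the
rostral sub-chain differs from that by a global rigid motion of the
fixed part, so all relative quantities (TMJ displacement, mandible
orientation change, gape) are identical, and the articulated-chain
reading is the physically meaningful one.

Mandible policies:

* **fixed**: mandible carried with the cranium.  Gape is exactly
  preserved — whole-unit rotation is rigid, so neck-powered rotation
  cannot close the jaws.
* **free**: after the rotation the mandible is re-rotated about the
  displaced TMJ until its axis (TMJ→`LOWER_INCISOR_TIP`) is vertical
  again.  The return rotation equals the trial arc at every pivot
  (rotation changes the mandible's orientation by exactly the arc;
  translation never does).  Note the TMJ angle between the toothrows
  necessarily shrinks by the arc in this policy — but this is not jaw
  closure on the prey, since the whole dentition was displaced along
  the chord; the mandible merely recovered its orientation elsewhere.
* **stationary**: the mandible is left untouched and the trial is
  feasible only if the TMJ stayed within tolerance.  "Remained
  stationary" is a visual judgement in the source experiment; here it
  is a numeric threshold, `1e-6 ×` the configuration's characteristic
  length (largest pairwise landmark distance), configurable.  Since the
  smallest pivot–TMJ distance in any valid configuration produces a
  chord four orders of magnitude above that threshold at a 1° arc, the
  verdict is robustly arc-independent on (0°, 360°); a full 360° turn
  is the identity and is documented as the degenerate feasible edge
  case.

## Lever mechanics

A lever system is a fulcrum plus effort and resistance lines of action
(point + direction; magnitudes are out of scope).  MA = in-lever /
out-lever, both perpendicular distances to the fulcrum.  Classification
projects fulcrum and the two application points onto the line through
the application points and names the middle element: fulcrum → Class 1,
resistance → Class 2, effort → Class 3; coincident projections (within
`1e-9 ×` scale) raise an ambiguity error rather than guessing.

Named mechanisms (`build_named_lever`):

* `shear_bite`: fulcrum AOJ; ventral neck flexors modelled at the
  AOJ→TMJ midpoint (configurable), pulling along the neck's ventral
  perpendicular; resistance at the upper canine tip.
* `c1lm`: fulcrum TMJ; forelimb extension applied at
  `NECK_FORCE_POINT`, directed along the neck's dorsal perpendicular.
* `mandibular_bite`: fulcrum TMJ; temporalis only, applied at the
  coronoid process toward a cranial attachment landmark.  The coronoid
  and attachment defaults are plumbing, chosen so the temporalis lever
  is the classical Class 3 jaw lever with a much shorter in-lever than
  the neck; only the *ordering* MA(c1lm) > MA(mandibular_bite) is a
  substantive claim, and it follows from any anatomically plausible
  coronoid geometry because the neck is an order of magnitude longer.

Force directions are expressed relative to the configuration's own axes
(not the world frame) so that levers rebuilt on a rigidly moved
configuration have identical MA — the invariance the tests assert.

The resistance line is modelled perpendicular to the fulcrum→bite-point
segment, making the out-lever equal to the fulcrum-to-bite-point
distance, which is how the out-lever was defined for both mechanisms in
the source comparison.  The bite point defaults to the upper canine tip
with a switch for more posterior teeth (the compressive point may have
been further back in the mouth); moving it posteriorly shortens the
shared out-lever and raises both MAs equally, leaving the ratio
identity untouched.  Because `c1lm` and `mandibular_bite` share fulcrum
and resistance line, MA(c1lm)/MA(mandibular) = in(c1lm)/in(mandibular)
is an algebraic identity; the tests assert it to 1e-12 relative over
random anatomies.

Absolute MA values and lever lengths are **not reproducible** — no
measurements are published — and are reported only as properties of the
synthetic defaults.

`convert_pressure_mmHg_to_N_per_mm2` uses 1 mm Hg = 133.322 Pa; the
carotid-collapse figure of 120 mm Hg converts to 0.016 N/mm² at two
significant figures.

## Strike model

The strike narrative contains two simultaneous rotations — the cranium
anteriorly at the TMJ, and the TMJ anteriorly about the virtual point.
The unique rigid interpretation consistent with both, and with the
requirement that the canines traverse the prey along their own circular
long axis, is a **single rotation of the neck-and-cranium about the
fixed virtual point**, with the mandible translating (orientation
locked) so that its TMJ attachment tracks the cranium's TMJ.  The two
elementary descriptions advance 1:1 — no coupling ratio is stated in
the narrative, and 1:1 is the only choice under which the relative
cranium–mandible rotation (the gape change) equals the cranial rotation
— so a strike progress of φ closes the gape by exactly φ and the full
90°-gape strike terminates at closure.

Each trajectory state is computed as one exact rotation from the start
(not by accumulating steps), so endpoints are independent of step
count.  Withdrawal is the same motion with the opposite sign;
strike-then-withdrawal restores the start to machine precision.

Strike progress is parameterized by angle.  Whether forelimb extension
distance would be the better driving variable is unknowable without
force data; angle is the variable the geometry determines.

Diagnostics: `tip_tangency_error` measures the worst angle between the
finite-difference canine-tip velocity and the local circle tangent (for
exact circular motion it equals half the per-step arc, so it vanishes
under refinement — the convergence the tests check);
`penetration_depth` is the signed perpendicular distance of the canine
tip past a straight prey-hide line (curvature of the neck surface is
out of scope).  The default hide line passes through the starting tip,
oriented so the interior of the prey lies on its left; depth is then
zero at φ = 0 and non-decreasing over the default 90° strike.

## File formats and CLI

Landmark I/O: named JSON, CSV (`name,x_mm,y_mm,segment`) and plain TPS
(`LM=n` header, whitespace-separated coordinate lines, optional `ID=`
trailer).  TPS is positional: the 12 required landmarks map in the
canonical order defined (and versioned) in
`saberbite.skull.REQUIRED_LANDMARKS`.  Coordinates are written with
`repr`, the shortest exact float representation, so read∘write is
bit-exact in all three formats.  SVG export writes the scene directly
as XML (layer groups per configuration, one marker per landmark, pivot
and TMJ markers, panels for the four-pivot superposition, frame overlay
plus tip trace for strikes), mirroring the superimposed-image
methodology of the original experiment.

The CLI (`saberbite`) is a thin shell over the library: subcommands
`generate`, `gape`, `rotate`, `feasibility`, `lever`, `strike`,
`convert-pressure`; YAML parameter files mirror `SkullParams` with
flags taking precedence; outputs are deterministic given a seed; exit
codes are 0 (success), 1 (validation/domain error), 2 (usage error).

## Numerical choices

* Degeneracy tolerances scale with the characteristic length (largest
  pairwise distance) of the object at hand; the default relative
  tolerance is 1e-9, overridable per call.
* Angles are normalized to (−180°, 180°]; gape is reported unsigned in
  [0°, 180°].  Vertex angles use `atan2(cross, dot)`, which is stable
  for nearly collinear rays where an `acos` form loses digits.
* Circle fitting: exact circumcircle (linear solve) for 3 points;
  algebraic Kåsa least squares (`numpy.linalg.lstsq`) for more, with
  collinearity detected via the point cloud's smallest singular value.
  The Kåsa fit minimizes algebraic, not geometric, distance; for the
  low-noise arcs used here the two agree well inside the noise scale
  (the suite cross-checks against a geometric fit via
  `scipy.optimize.least_squares`).
* Rigid transforms are stored as rotation matrix + translation, so
  composition and inversion are closed-form and associative to machine
  precision.

## Known limitations

* Strictly sagittal: head yaw/roll during bulldogging, condyle
  translation at the TMJ and bilateral asymmetry are not representable.
* No forces or tissue mechanics: feasibility verdicts are kinematic;
  nothing here estimates bite force in newtons, and the lever
  comparison is geometry only.
* The prey-neck surface is a straight line in projection.
* Default dimensions are plausible plumbing, not specimen data; any
  quantitative statement about a real skull requires re-running with
  measured landmarks (the JSON/CSV/TPS readers exist for exactly that).
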