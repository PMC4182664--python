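# saberbite

Planar rigid-body kinematics and lever mechanics for sabertooth jaw
function.

`saberbite` asks a purely geometric question about *Smilodon fatalis*:
can ventral rotation of the neck-and-skull unit — the "canine
shear-bite" hypothesis, in which the ventral neck flexors are supposed
to help close the jaws — actually close the jaws?  The package models
the neck, cranium and mandible as an articulated planar chain of named
landmarks in the sagittal plane and rotates the chain ventrally about
four candidate pivots (caudal neck, mid-neck, atlantooccipital joint,
temporomandibular joint).  Whenever the pivot is not the jaw joint
itself, the jaw joint is displaced along a chord

    d = 2 r sin(θ / 2)

(r = pivot-to-TMJ distance, θ = arc of rotation), so a mandible pinned
against the prey cannot remain articulated: neck-powered biting is
kinematically infeasible.  The package then models the alternative, a
**Class 1 lever mechanism**: the mandible is immobilized vertically
against the prey's neck, a dorsally directed force from forelimb
extension rotates the cranium anteriorly at the TMJ, and the maxillary
canines — whose long axis is circular, with its centre (a *virtual
point* of rotation) slightly anteroventral to the TMJ — sweep into the
prey along their own curvature.

The lever comparison uses the standard mechanical advantage

    MA = in-lever / out-lever,

where the in-lever (out-lever) is the perpendicular distance from the
line of action of the effort (resistance) to the fulcrum.  The
forelimb-powered mechanism and the conventional temporalis bite share
their fulcrum (the TMJ) and resistance line, so the ratio of their MAs
equals the ratio of their in-levers — and the neck-length in-lever of
the forelimb mechanism dwarfs the coronoid in-lever of the temporalis.

No landmark measurements of the original digitized replica are
published, so all geometry is synthetic and parametric
(`saberbite.skull.SkullParams`); every kinematic claim the package
makes holds for any valid parameter set, not just the documented
defaults.  It is aimed at comparative biomechanists and functional
morphologists who want the kinematic argument as runnable, testable
code.

## Worked example

The core falsification, on the maximum-gape "bulldogging" preset
(gape 90°, cranium extended 36° at the atlantooccipital joint, mandible
exactly vertical), with a 15° ventral arc and the mandible required to
stay stationary:

```sh
$ saberbite feasibility --preset bulldogging --arc-deg 15
pivot,policy,arc_deg,tmj_dx_mm,tmj_dy_mm,tmj_disp_mm,mandible_return_deg,gape_after_deg,feasible
CAUDAL_NECK,stationary,15.0,3.0329072003792703,-82.76412807185054,82.81968015864219,0.0,77.24874196545692,False
MID_NECK,stationary,15.0,7.121808045691068,-51.705842659548054,52.194006504325856,0.0,78.76255584822506,False
AOJ,stationary,15.0,11.210708891002866,-20.647557247245565,23.49471459960928,0.0,79.59945976750865,False
TMJ,stationary,15.0,0.0,-7.105427357601002e-15,7.105427357601002e-15,0.0,75.0,True
```

Read: rotating the neck-and-skull at the caudal neck drags the jaw
joint 82.8 mm ventrally (`tmj_disp_mm`), at the mid-neck 52.2 mm, at the
atlantooccipital joint 23.5 mm — in every case far too much for a
stationary mandible to stay articulated (`feasible = False`).  Only
rotation at the TMJ itself leaves the joint in place (displacement at
machine precision), and that rotation closes the gape from 90° to 75°
(`gape_after_deg`): jaw closure and a pinned mandible coexist only at
the jaw joint.

If the mandible is instead carried with the cranium and then allowed to
swing freely back to vertical, the return rotation always equals the
arc:

```sh
$ saberbite rotate --pivot CAUDAL_NECK --arc-deg 15 --policy free
...
mandible_return_deg = 15.0
```

The lever comparison on the same preset:

```sh
$ saberbite lever
label,lever_class,in_lever_mm,out_lever_mm,mechanical_advantage
shear_bite,3,36.40576474687265,188.3205534400206,0.19331806370496754
c1lm,1,312.8115294937453,132.49015267803853,2.3610172014361086
mandibular_bite,3,27.440304244481382,132.49015267803853,0.20711202825136352
```

The neck-powered shear bite is a Class 3 lever (effort between fulcrum
and resistance); the forelimb-powered mechanism (`c1lm`) is a Class 1
lever whose in-lever is the whole neck.  `c1lm` and `mandibular_bite`
share fulcrum and out-lever (132.5 mm here), so their MA ratio
(2.361 / 0.207 ≈ 11.4) is exactly their in-lever ratio
(312.8 / 27.4).  Absolute millimetre values are properties of the
synthetic default geometry; the classifications, the shared-out-lever
identity and the ordering are the substantive results.

The strike itself:

```sh
$ saberbite strike --total-deg 90 --steps 90 --svg strike.svg
```

emits the per-step trajectory (gape falls linearly from 90° to 0°; the
canine tip stays on its curvature circle to 1e-9 relative) and an SVG
of superimposed frames with the canine-tip trace.

And the unit conversion for the carotid-collapse pressure discussed in
the predation context:

```sh
$ saberbite convert-pressure 120
{"mmHg": 120.0, "N_per_mm2": 0.015999}
```

## Layout

| module                | contents                                               |
| --------------------- | ------------------------------------------------------ |
| `saberbite.geometry`  | points, rigid transforms, angles, chords, circle fits  |
| `saberbite.skull`     | synthetic landmark generator, presets, measurements    |
| `saberbite.rotation`  | four-pivot ventral-rotation experiment and feasibility |
| `saberbite.levers`    | lever systems, MA, classification, pressure conversion |
| `saberbite.strike`    | virtual-point strike/withdrawal kinematics             |
| `saberbite.io` / `.cli` | JSON/CSV/TPS landmark files, SVG export, CLI        |

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
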