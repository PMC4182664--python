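"""Ventral rotation experiments on the neck-and-skull unit.

The core falsification experiment: rotate the neck-and-skull ventrally
through a small arc about each of four hypothesized pivots — caudal
neck, mid-neck, atlantooccipital joint (AOJ) and temporomandibular
joint (TMJ) — and track what the jaw joint and the mandible do.

Three mandible policies are modelled:

``FIXED_TO_CRANIUM``
    the mandible is carried rigidly with the cranium (jaws stay open at
    the same gape, the whole head pitches ventrally);
``FREE_RETURN_TO_VERTICAL``
    after the rotation the mandible is re-rotated about the displaced
    TMJ until its axis is vertical again — the rotation needed always
    equals the trial arc, because neck rotation translates the mandible
    along with the cranium but the *return* must undo the full pitch;
``STATIONARY_MANDIBLE``
    the mandible is left untouched and the trial is scored feasible only
    if the TMJ did not move: a mandible pinned against the prey cannot
    stay articulated to a jaw joint that translated away.

Under any pivot other than the TMJ itself, the TMJ is displaced along a
chord of length 2 d sin(arc/2) (d = pivot-to-TMJ distance), so the
stationary-mandible requirement is satisfiable only when the pivot *is*
the TMJ.  That kinematic fact is what rules out neck-powered jaw
closure at the AOJ and upstream pivots.

The experiment rotates the articulated chain rostral to the pivot
(landmarks caudal to the pivot stay put) rather than the whole image;
the two readings differ only by a global rigid motion of the fixed
part, so every relative quantity reported here is identical.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd

from .geometry import RigidTransform, Vec2, chord_displacement
from .skull import (
    CRANIUM,
    MANDIBLE,
    LandmarkError,
    SkullConfiguration,
    ValidationError,
    mandible_angle_from_vertical,
    measure_gape,
)

#: the four hypothesized pivots, caudal to rostral
PIVOTS = ("CAUDAL_NECK", "MID_NECK", "AOJ", "TMJ")

#: neck landmarks that move when the chain is rotated at each pivot
#: (cranium and mandible landmarks are resolved by segment tag)
_ROSTRAL_NECK = {
    "CAUDAL_NECK": ("NECK_FORCE_POINT", "MID_NECK", "AOJ"),
    "MID_NECK": ("AOJ",),
    "AOJ": (),
    "TMJ": (),
}

#: relative tolerance for "the TMJ remained stationary", scaled by the
#: configuration's characteristic length
STATIONARITY_TOL_REL = 1e-6


class MandiblePolicy(enum.Enum):
    FIXED_TO_CRANIUM = "fixed"
    FREE_RETURN_TO_VERTICAL = "free"
    STATIONARY_MANDIBLE = "stationary"

    @classmethod
    def parse(cls, value: "str | MandiblePolicy") -> "MandiblePolicy":
        if isinstance(value, cls):
            return value
        for member in cls:
            if value in (member.value, member.name):
                return member
        raise ValidationError(
            f"unknown mandible policy {value!r}; expected one of "
            + ", ".join(m.value for m in cls)
        )


@dataclass(frozen=True)
class RotationTrial:
    """One (pivot, arc, policy) trial.  ``arc_deg`` is positive ventral
    degrees; the internal clockwise sign is handled here."""

    pivot: str
    arc_deg: float = 15.0
    policy: MandiblePolicy = MandiblePolicy.FIXED_TO_CRANIUM

    def __post_init__(self) -> None:
        if self.pivot not in PIVOTS:
            raise ValidationError(
                f"pivot must be one of {PIVOTS}, got {self.pivot!r}")
        if not (self.arc_deg > 0.0) or not math.isfinite(self.arc_deg):
            raise ValidationError(f"arc_deg must be > 0, got {self.arc_deg}")
        object.__setattr__(self, "policy", MandiblePolicy.parse(self.policy))


@dataclass(frozen=True)
class ExperimentResult:
    """Outcome of one rotation trial."""

    trial: RotationTrial
    transformed: SkullConfiguration
    tmj_displacement: Vec2
    tmj_displacement_mm: float
    mandible_return_rotation_deg: float
    mandible_orientation_after_deg: float
    feasible: bool
    infeasibility_reason: str = ""


def apply_trial(config: SkullConfiguration, trial: RotationTrial,
                stationarity_tol_rel: float = STATIONARITY_TOL_REL
                ) -> ExperimentResult:
    """Rotate the chain rostral to ``trial.pivot`` ventrally by
    ``trial.arc_deg`` and resolve the mandible per policy."""
    pivot_pt = config[trial.pivot]
    tmj0 = config["TMJ"]

    # ventral rotation of the anterior-facing skull = clockwise
    rot = RigidTransform.rotation(pivot_pt, -trial.arc_deg)

    moving = set(_ROSTRAL_NECK[trial.pivot]) | set(config.segment_names(CRANIUM))
    mandible_names = set(config.segment_names(MANDIBLE))

    policy = trial.policy
    if policy is not MandiblePolicy.STATIONARY_MANDIBLE:
        moving |= mandible_names
    out = config.transform(rot, moving)

    tmj1 = out["TMJ"]
    disp = tmj1 - tmj0
    disp_mm = disp.norm

    return_deg = 0.0
    if policy is MandiblePolicy.FREE_RETURN_TO_VERTICAL:
        tilt = mandible_angle_from_vertical(out)
        return_deg = -tilt  # CCW (dorsal) rotation restoring vertical
        out = out.transform(RigidTransform.rotation(tmj1, return_deg),
                            mandible_names)

    feasible = True
    reason = ""
    if policy is MandiblePolicy.STATIONARY_MANDIBLE:
        tol = stationarity_tol_rel * config.characteristic_length()
        feasible = disp_mm <= tol
        if not feasible:
            reason = (
                f"TMJ translated {disp_mm:.3f} mm (chord of the "
                f"{trial.arc_deg:g} deg arc at radius "
                f"{pivot_pt.distance_to(tmj0):.1f} mm); a stationary "
                f"mandible cannot remain articulated"
            )
        # mandible untouched: its orientation is measured about the
        # original attachment, which did not move with the cranium
        orientation_after = mandible_angle_from_vertical(out, attachment=tmj0)
    else:
        orientation_after = mandible_angle_from_vertical(out)

    return ExperimentResult(
        trial=trial,
        transformed=out,
        tmj_displacement=disp,
        tmj_displacement_mm=disp_mm,
        mandible_return_rotation_deg=return_deg,
        mandible_orientation_after_deg=orientation_after,
        feasible=feasible,
        infeasibility_reason=reason,
    )


def gape_after_trial(result: ExperimentResult) -> float:
    """Gape of the transformed configuration, degrees.

    Under FIXED_TO_CRANIUM the gape is exactly preserved: the whole head
    pitches as one rigid unit and the jaws stay open.  Under
    FREE_RETURN_TO_VERTICAL the TMJ angle shrinks by the return arc —
    but this is not jaw closure on the prey, because the entire
    dentition translated ventrally along the chord; the mandible merely
    recovered its orientation somewhere else.  Actual closure against a
    pinned mandible happens only when the cranium rotates at the TMJ
    itself, where the gape decreases by exactly the arc with the teeth
    staying put.
    """
    return measure_gape(result.transformed)


def feasibility_table(config: SkullConfiguration, arc_deg: float = 15.0,
                      stationarity_tol_rel: float = STATIONARITY_TOL_REL
                      ) -> pd.DataFrame:
    """Stationary-mandible feasibility of all four pivots at one arc.

    For any valid configuration with distinct pivots and any arc in
    (0, 360) degrees, only the TMJ row is feasible.
    """
    rows = []
    for pivot in PIVOTS:
        trial = RotationTrial(pivot, arc_deg, MandiblePolicy.STATIONARY_MANDIBLE)
        res = apply_trial(config, trial, stationarity_tol_rel)
        rows.append(_result_row(res))
    return pd.DataFrame(rows)


def experiment_table(config: SkullConfiguration, arc_deg: float = 15.0,
                     policy: "str | MandiblePolicy" = MandiblePolicy.FREE_RETURN_TO_VERTICAL
                     ) -> pd.DataFrame:
    """All four pivots under one mandible policy, as a tidy table."""
    policy = MandiblePolicy.parse(policy)
    rows = []
    for pivot in PIVOTS:
        res = apply_trial(config, RotationTrial(pivot, arc_deg, policy))
        rows.append(_result_row(res))
    return pd.DataFrame(rows)


def _result_row(res: ExperimentResult) -> dict:
    return {
        "pivot": res.trial.pivot,
        "policy": res.trial.policy.value,
        "arc_deg": res.trial.arc_deg,
        "tmj_dx_mm": res.tmj_displacement.x,
        "tmj_dy_mm": res.tmj_displacement.y,
        "tmj_disp_mm": res.tmj_displacement_mm,
        "mandible_return_deg": res.mandible_return_rotation_deg,
        "gape_after_deg": gape_after_trial(res),
        "feasible": res.feasible,
    }


def expected_tmj_chord(config: SkullConfiguration, pivot: str,
                       arc_deg: float) -> float:
    """Closed-form TMJ displacement 2 d sin(arc/2) for a given pivot."""
    if pivot not in PIVOTS:
        raise LandmarkError(f"unknown pivot {pivot!r}")
    d = config[pivot].distance_to(config["TMJ"])
    return chord_displacement(d, arc_deg)
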