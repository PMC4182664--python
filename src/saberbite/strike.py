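"""Strike kinematics of the Class 1 Lever Model.

During the strike the mandible is pinned against the prey while the
cranium (and neck) rotates anteriorly.  Two descriptions appear in the
behavioural narrative — "the cranium rotates anteriorly at the TMJ" and
"the TMJ rotates anteriorly at the virtual point" — and the unique
rigid-body motion consistent with both, and with the canine tips
tracing their own curvature circle, is a single rotation of the cranium
about the fixed virtual point (the centre of canine curvature, slightly
anteroventral to the TMJ) while the mandible *translates* with the
moving TMJ, its orientation locked.

With both elementary rotations advancing together (1:1 coupling), a
strike progress of φ degrees rotates the cranium by φ about the virtual
point and closes the gape by exactly φ.  The canine tip consequently
never leaves its curvature circle: the tooth traverses the prey along
its own long axis, the geometric point of the mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .geometry import (
    GeometryError,
    Line,
    Point2,
    RigidTransform,
    signed_angle_deg,
)
from .skull import (
    CRANIUM,
    MANDIBLE,
    NECK,
    SkullConfiguration,
    ValidationError,
    measure_gape,
)


class OverClosureError(ValidationError):
    """Requested strike angle exceeds the available gape."""


@dataclass(frozen=True)
class StrikeState:
    """Configuration at strike progress ``phi_deg``."""

    phi_deg: float
    configuration: SkullConfiguration
    gape_deg: float

    @property
    def canine_tip(self) -> Point2:
        return self.configuration["UPPER_CANINE_TIP"]


def strike_trajectory(config: SkullConfiguration, total_angle_deg: float,
                      steps: int) -> list[StrikeState]:
    """Sample the strike from φ=0 to φ=``total_angle_deg`` in ``steps``
    equal increments (``steps``+1 states including the start).

    At each φ the neck and cranium are rotated anteriorly (jaw-closing
    direction) about the fixed virtual point; the mandible is translated
    by the TMJ's displacement so the joint stays articulated while the
    mandibular orientation is preserved.  Each state is computed as one
    exact rotation from the start, so the trajectory endpoint does not
    depend on the step count.  Negative φ (withdrawal) reverses the
    strike exactly.
    """
    if steps < 1:
        raise ValidationError(f"steps must be >= 1, got {steps}")
    g0 = measure_gape(config)
    if not (0.0 < total_angle_deg <= g0 + 1e-9):
        raise OverClosureError(
            f"total strike angle {total_angle_deg:g} deg must lie in "
            f"(0, initial gape = {g0:.6g} deg]")
    virtual = config["VIRTUAL_POINT"]
    tmj0 = config["TMJ"]
    rotating = set(config.segment_names(NECK)) | set(config.segment_names(CRANIUM))
    mandible = set(config.segment_names(MANDIBLE))

    states = []
    for k in range(steps + 1):
        phi = total_angle_deg * k / steps
        # anterior (jaw-closing) rotation of the anterior-facing cranium
        # is clockwise, hence the negative internal angle
        rot = RigidTransform.rotation(virtual, -phi)
        out = config.transform(rot, rotating)
        shift = RigidTransform.translation(out["TMJ"] - tmj0)
        out = out.transform(shift, mandible)
        states.append(StrikeState(phi_deg=phi, configuration=out,
                                  gape_deg=measure_gape(out)))
    return states


def withdraw_trajectory(config: SkullConfiguration, total_angle_deg: float,
                        steps: int) -> list[StrikeState]:
    """The withdrawal phase: the strike run in reverse.

    Rotates the neck-and-cranium *posteriorly* about the virtual point
    (the canines back out along their own arc) while the mandible again
    translates with the TMJ.  Withdrawing through the same angle as a
    completed strike restores the starting configuration exactly.
    ``phi_deg`` in the returned states is the (positive) withdrawal
    progress; gape increases linearly with it.
    """
    if steps < 1:
        raise ValidationError(f"steps must be >= 1, got {steps}")
    if not total_angle_deg > 0.0:
        raise ValidationError(
            f"total withdrawal angle must be > 0, got {total_angle_deg:g}")
    virtual = config["VIRTUAL_POINT"]
    tmj0 = config["TMJ"]
    rotating = set(config.segment_names(NECK)) | set(config.segment_names(CRANIUM))
    mandible = set(config.segment_names(MANDIBLE))
    states = []
    for k in range(steps + 1):
        phi = total_angle_deg * k / steps
        rot = RigidTransform.rotation(virtual, phi)  # posterior = CCW
        out = config.transform(rot, rotating)
        out = out.transform(RigidTransform.translation(out["TMJ"] - tmj0),
                            mandible)
        states.append(StrikeState(phi_deg=phi, configuration=out,
                                  gape_deg=measure_gape(out)))
    return states


def tip_tangency_error(states: Sequence[StrikeState]) -> float:
    """Maximum angle (degrees) between the finite-difference canine-tip
    velocity and the local tangent of the curvature circle.

    For motion that truly follows the circle this is the chord-tangent
    angle, half the per-step arc, so it vanishes as the trajectory is
    refined.
    """
    if len(states) < 2:
        raise GeometryError("need at least 2 states for a tangency check")
    virtual = states[0].configuration["VIRTUAL_POINT"]
    worst = 0.0
    for a, b in zip(states[:-1], states[1:]):
        v = b.canine_tip - a.canine_tip
        if v.norm == 0.0:
            continue
        radial = a.canine_tip - virtual
        # clockwise (anterior) tangent
        tangent = -radial.perp()
        worst = max(worst, abs(signed_angle_deg(tangent, v)))
    return worst


def penetration_depth(state: StrikeState, hide_line: Line) -> float:
    """Signed distance (mm) of the upper canine tip past the prey-hide
    entry line, measured perpendicular to the line.

    The hide is modelled as a straight line in the sagittal projection;
    orient its direction so the prey's interior lies to the line's left
    (CCW side), making penetration positive.
    """
    return hide_line.signed_distance(state.canine_tip)


def trajectory_table(states: Sequence[StrikeState],
                     hide_line: Optional[Line] = None) -> pd.DataFrame:
    """Tidy per-step table: φ, gape, canine-tip position and (optionally)
    penetration depth."""
    rows = []
    for s in states:
        row = {
            "phi_deg": s.phi_deg,
            "gape_deg": s.gape_deg,
            "tip_x_mm": s.canine_tip.x,
            "tip_y_mm": s.canine_tip.y,
        }
        if hide_line is not None:
            row["penetration_mm"] = penetration_depth(s, hide_line)
        rows.append(row)
    return pd.DataFrame(rows)


def default_hide_line(config: SkullConfiguration) -> Line:
    """A hide entry line for the default posture: through the starting
    canine tip, oriented so the initial tip velocity points into the
    prey (depth is then zero at φ=0 and grows monotonically over a
    90-degree strike)."""
    tip = config["UPPER_CANINE_TIP"]
    radial = tip - config["VIRTUAL_POINT"]
    initial_velocity = -radial.perp()  # clockwise tangent
    # direction chosen so the left normal == initial velocity direction
    return Line(tip, -initial_velocity.perp())
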