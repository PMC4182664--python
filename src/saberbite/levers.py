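"""Jaw lever mechanics: in-lever, out-lever, mechanical advantage and
lever classification for the competing bite mechanisms.

A lever system is a fulcrum plus two lines of action: the effort force
and the resistance.  The in-lever is the perpendicular distance from the
force line to the fulcrum, the out-lever that of the resistance line,
and the mechanical advantage (MA) their ratio

    MA = in_lever / out_lever.

Classification follows the classical scheme: project the fulcrum and
the two application points onto the lever axis (the line through the
application points); whichever of the three sits between the other two
names the class — fulcrum in the middle is Class 1, resistance Class 2,
effort Class 3.

Three named bite mechanisms are built from a skull configuration:

``shear_bite``
    the canine shear-bite: fulcrum at the atlantooccipital joint, effort
    from the ventral neck flexors applied between the fulcrum and the
    canine tips (ventrally directed), resistance at the upper canine
    tip — a Class 3 lever;
``c1lm``
    the Class 1 Lever Model: fulcrum at the TMJ, effort from the
    forelimb extensors applied dorsally at the caudal neck, resistance
    at the upper canine tip — a Class 1 lever;
``mandibular_bite``
    the conventional jaw-adductor bite (temporalis only): fulcrum at
    the TMJ, effort at the coronoid process along the temporalis line,
    same resistance line as ``c1lm``.

Because ``c1lm`` and ``mandibular_bite`` share the fulcrum and the
resistance line, their out-levers are identical and the ratio of their
MAs collapses algebraically to the ratio of their in-levers.  Only that
ratio identity and the resulting ordering are anchored in the source
anatomy; absolute lever lengths are properties of the synthetic default
geometry, not measured data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .geometry import (
    DegenerateGeometryError,
    GeometryError,
    Line,
    Point2,
    Vec2,
    characteristic_length,
    perpendicular_distance,
)
from .skull import SkullConfiguration, LandmarkError, ValidationError


class AmbiguousLeverError(GeometryError):
    """Fulcrum/effort/resistance projections coincide on the lever axis."""


LEVER_NAMES = ("shear_bite", "c1lm", "mandibular_bite")

#: conversion factor: 1 mm Hg = 133.322 Pa = 133.322e-6 N/mm^2
_MMHG_TO_N_PER_MM2 = 133.322e-6


@dataclass(frozen=True)
class LeverSystem:
    """Fulcrum plus effort and resistance lines of action.

    Force magnitudes are deliberately absent: the comparisons made here
    are purely geometric.
    """

    fulcrum: Point2
    force: Line
    resistance: Line
    label: str = ""

    def __post_init__(self) -> None:
        for line, what in ((self.force, "force"), (self.resistance, "resistance")):
            if line.point.distance_to(self.fulcrum) == 0.0:
                raise ValidationError(
                    f"{what} application point coincides with the fulcrum")


def in_lever(lever: LeverSystem) -> float:
    """Perpendicular distance (mm) from the effort line of action to the
    fulcrum."""
    return perpendicular_distance(lever.fulcrum, lever.force)


def out_lever(lever: LeverSystem) -> float:
    """Perpendicular distance (mm) from the resistance line of action to
    the fulcrum."""
    return perpendicular_distance(lever.fulcrum, lever.resistance)


def mechanical_advantage(lever: LeverSystem) -> float:
    """MA = in-lever / out-lever (dimensionless)."""
    out = out_lever(lever)
    if out == 0.0:
        raise DegenerateGeometryError(
            "resistance line passes through the fulcrum: out-lever is zero")
    return in_lever(lever) / out


def classify_lever(lever: LeverSystem, tol_rel: float = 1e-9) -> int:
    """Lever class in {1, 2, 3} by projection order on the lever axis."""
    f, r = lever.force.point, lever.resistance.point
    axis = r - f
    scale = characteristic_length([lever.fulcrum, f, r])
    if axis.norm <= tol_rel * scale:
        raise AmbiguousLeverError(
            "force and resistance application points coincide")
    u = axis.unit()
    t_force = 0.0
    t_resist = u.dot(r - f)
    t_fulcrum = u.dot(lever.fulcrum - f)
    tol = tol_rel * scale
    if (abs(t_fulcrum - t_force) <= tol or abs(t_fulcrum - t_resist) <= tol):
        raise AmbiguousLeverError(
            "fulcrum projection coincides with an application point")
    ordered = sorted(
        (("fulcrum", t_fulcrum), ("force", t_force), ("resistance", t_resist)),
        key=lambda kv: kv[1],
    )
    middle = ordered[1][0]
    return {"fulcrum": 1, "resistance": 2, "force": 3}[middle]


def build_named_lever(config: SkullConfiguration, name: str,
                      bite_point: str = "UPPER_CANINE_TIP") -> LeverSystem:
    """Construct one of the named bite-mechanism levers.

    ``bite_point`` defaults to the upper canine tip but may name a more
    posterior tooth landmark, since the compressive bite point may have
    sat further back in the toothrow.  The resistance line is modelled
    perpendicular to the fulcrum-to-bite-point segment, so the out-lever
    equals the fulcrum-to-bite-point distance.
    """
    if name not in LEVER_NAMES:
        raise LandmarkError(
            f"unknown lever {name!r}; known levers: {', '.join(LEVER_NAMES)}")
    bite = config[bite_point]

    # force directions are anatomy-intrinsic so that levers rebuilt on a
    # rigidly moved configuration keep their mechanical advantage
    neck_axis = (config["AOJ"] - config["CAUDAL_NECK"]).unit()
    ventral = -neck_axis.perp()  # ventral perpendicular of the neck axis

    if name == "shear_bite":
        fulcrum = config["AOJ"]
        tmj = config["TMJ"]
        # ventral neck flexors modelled midway between the AOJ and the
        # TMJ, pulling ventrally
        mid = Point2((fulcrum.x + tmj.x) / 2.0, (fulcrum.y + tmj.y) / 2.0)
        force = Line(mid, ventral)
    elif name == "c1lm":
        fulcrum = config["TMJ"]
        # forelimb extension: dorsally directed force at the caudal neck
        force = Line(config["NECK_FORCE_POINT"], -ventral)
    else:  # mandibular_bite
        fulcrum = config["TMJ"]
        coronoid = config["CORONOID_PROCESS"]
        attach = (config["TEMPORALIS_ATTACHMENT"]
                  if "TEMPORALIS_ATTACHMENT" in config
                  else fulcrum + Vec2(-30.0, 60.0))
        force = Line(coronoid, attach - coronoid)

    resistance = Line(bite, (bite - fulcrum).perp())
    return LeverSystem(fulcrum=fulcrum, force=force,
                       resistance=resistance, label=name)


def lever_report(config: SkullConfiguration,
                 names: tuple[str, ...] = LEVER_NAMES,
                 bite_point: str = "UPPER_CANINE_TIP") -> pd.DataFrame:
    """Tidy comparison table: label, class, in/out levers, MA."""
    rows = []
    for name in names:
        lever = build_named_lever(config, name, bite_point)
        rows.append({
            "label": name,
            "lever_class": classify_lever(lever),
            "in_lever_mm": in_lever(lever),
            "out_lever_mm": out_lever(lever),
            "mechanical_advantage": mechanical_advantage(lever),
        })
    return pd.DataFrame(rows)


def convert_pressure_mmHg_to_N_per_mm2(p_mmHg: float) -> float:
    """Convert a pressure in mm Hg to N/mm^2 (== MPa).

    120 mm Hg — the approximate collapse pressure of a large ungulate's
    carotid artery — converts to 0.016 N/mm^2 at two significant
    figures.
    """
    if not math.isfinite(p_mmHg) or p_mmHg < 0.0:
        raise GeometryError(f"pressure must be >= 0 mm Hg, got {p_mmHg}")
    return p_mmHg * _MMHG_TO_N_PER_MM2
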