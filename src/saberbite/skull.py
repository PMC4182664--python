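"""Synthetic sabertooth skull-neck-mandible landmark configurations.

No measured landmark coordinates are published for the digitized
*Smilodon fatalis* replica this package models, so every experiment runs
on parametric synthetic geometry.  :func:`generate` builds an exact
configuration from :class:`SkullParams`; all downstream results are
therefore functions of declared, documented parameters rather than of an
image nobody can re-digitize.

The model is an articulated planar chain

    CAUDAL_NECK -> MID_NECK -> AOJ -> cranium (at the TMJ carrying the
    upper toothrow, the maxillary canine and its curvature circle) ->
    mandible (hanging from the TMJ)

with the neck laid along +x, the cranium pitched at the
atlantooccipital joint (AOJ) by the *extension* angle, and the mandible
hung from the temporomandibular joint (TMJ) at the *gape* angle below
the upper toothrow.  In the default "bulldogging" posture (extension
36 degrees, gape 90 degrees) the mandible axis is exactly vertical,
pointing ventrally, which is the posture in which the cat pins the
prey's neck with the lower jaw alone.

The maxillary canine is circular: its base and tip (and a mid-arc
point) lie on a circle whose centre — the *virtual point* — sits
slightly anteroventral to the TMJ.  That centre is the fixed pivot of
the strike model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional

import numpy as np

from .geometry import (
    Point2,
    RigidTransform,
    Vec2,
    angle_at_vertex,
    characteristic_length,
    signed_angle_deg,
)


class ValidationError(ValueError):
    """Parameter set or landmark configuration violates its invariants."""


class LandmarkError(KeyError):
    """A required landmark is missing from a configuration or file."""

    def __str__(self) -> str:  # KeyError quotes its message by default
        return self.args[0] if self.args else ""


NECK = "neck"
CRANIUM = "cranium"
MANDIBLE = "mandible"
DERIVED = "derived"
SEGMENTS = (NECK, CRANIUM, MANDIBLE, DERIVED)

#: landmarks every configuration must contain, in the canonical order
#: used by positional (TPS) files.  The order is part of the file-format
#: contract: see docs/methods.md before changing it.
REQUIRED_LANDMARKS = (
    "CAUDAL_NECK",
    "MID_NECK",
    "AOJ",
    "TMJ",
    "UPPER_INCISOR_TIP",
    "LOWER_INCISOR_TIP",
    "UPPER_CANINE_BASE",
    "UPPER_CANINE_TIP",
    "LOWER_CANINE_TIP",
    "CORONOID_PROCESS",
    "VIRTUAL_POINT",
    "NECK_FORCE_POINT",
)

#: extra landmarks the generator emits; optional on input files
OPTIONAL_LANDMARKS = ("UPPER_CANINE_MID", "TEMPORALIS_ATTACHMENT")

#: default segment membership.  VIRTUAL_POINT is the centre of the
#: canine curvature circle and hence rigidly cranium-fixed.
DEFAULT_SEGMENTS: Dict[str, str] = {
    "CAUDAL_NECK": NECK,
    "MID_NECK": NECK,
    "NECK_FORCE_POINT": NECK,
    "AOJ": NECK,
    "TMJ": CRANIUM,
    "UPPER_INCISOR_TIP": CRANIUM,
    "UPPER_CANINE_BASE": CRANIUM,
    "UPPER_CANINE_MID": CRANIUM,
    "UPPER_CANINE_TIP": CRANIUM,
    "VIRTUAL_POINT": CRANIUM,
    "TEMPORALIS_ATTACHMENT": CRANIUM,
    "LOWER_INCISOR_TIP": MANDIBLE,
    "LOWER_CANINE_TIP": MANDIBLE,
    "CORONOID_PROCESS": MANDIBLE,
}


@dataclass(frozen=True)
class SkullParams:
    """Generator parameters, millimetres and degrees.

    Absolute dimensions are **not** published for the replica; the
    defaults below are arbitrary but anatomically proportioned plumbing,
    and every kinematic property this package asserts holds for any
    valid parameter set, not only the defaults.

    ``extension_deg`` is the absolute pitch of the cranial axis
    (AOJ->TMJ) above the neck axis; the neutral pose of the replica is
    not published, so 0 degrees is simply "cranial axis parallel to the
    neck".  ``upper_jaw_offset_deg`` is the fixed anatomical angle of
    the upper toothrow below the cranial axis; its default (-36) makes
    the toothrow horizontal — and hence the 90-degree-gape mandible
    exactly vertical — at the default extension of 36 degrees.
    """

    caudal_to_mid_mm: float = 120.0
    mid_to_aoj_mm: float = 120.0
    aoj_to_tmj_mm: float = 90.0
    tmj_to_upper_incisor_mm: float = 180.0
    tmj_to_lower_incisor_mm: float = 160.0
    canine_radius_mm: float = 110.0
    virtual_point_anterior_mm: float = 15.0
    virtual_point_ventral_mm: float = 20.0
    gape_deg: float = 90.0
    extension_deg: float = 36.0
    upper_jaw_offset_deg: float = -36.0
    canine_span_deg: float = 35.0
    neck_force_dorsal_mm: float = 30.0
    noise_mm: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name in (
            "caudal_to_mid_mm",
            "mid_to_aoj_mm",
            "aoj_to_tmj_mm",
            "tmj_to_upper_incisor_mm",
            "tmj_to_lower_incisor_mm",
            "canine_radius_mm",
        ):
            if getattr(self, name) <= 0.0:
                problems.append(f"{name} must be > 0 (got {getattr(self, name)})")
        if not (0.0 <= self.gape_deg < 180.0):
            problems.append(f"gape_deg must lie in [0, 180) (got {self.gape_deg})")
        if self.virtual_point_anterior_mm <= 0.0 or self.virtual_point_ventral_mm <= 0.0:
            problems.append("virtual point offsets must be > 0 (anteroventral to the TMJ)")
        if self.canine_radius_mm <= self.virtual_point_ventral_mm:
            problems.append(
                "canine_radius_mm must exceed virtual_point_ventral_mm so the "
                "curvature circle reaches the upper toothrow"
            )
        else:
            base_x = self.virtual_point_anterior_mm + math.sqrt(
                self.canine_radius_mm ** 2 - self.virtual_point_ventral_mm ** 2
            )
            if base_x >= self.tmj_to_upper_incisor_mm:
                problems.append(
                    "canine base would fall rostral to the incisor tip; shrink "
                    "canine_radius_mm or lengthen tmj_to_upper_incisor_mm"
                )
        if not (0.0 < self.canine_span_deg < 120.0):
            problems.append(f"canine_span_deg must lie in (0, 120) (got {self.canine_span_deg})")
        if self.noise_mm < 0.0:
            problems.append(f"noise_mm must be >= 0 (got {self.noise_mm})")
        if problems:
            raise ValidationError("invalid skull parameters: " + "; ".join(problems))


@dataclass(frozen=True)
class SkullConfiguration:
    """A named set of sagittal landmarks with segment membership.

    The unit on which every experiment in this package operates.
    Immutable; kinematic operations return transformed copies.
    """

    landmarks: Mapping[str, Point2]
    segments: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SEGMENTS))

    def __post_init__(self) -> None:
        missing = [n for n in REQUIRED_LANDMARKS if n not in self.landmarks]
        if missing:
            raise LandmarkError(f"missing required landmarks: {', '.join(missing)}")
        for name in self.landmarks:
            seg = self.segments.get(name)
            if seg is None:
                raise ValidationError(f"landmark {name!r} has no segment tag")
            if seg not in SEGMENTS:
                raise ValidationError(f"unknown segment {seg!r} for landmark {name!r}")

    def __getitem__(self, name: str) -> Point2:
        try:
            return self.landmarks[name]
        except KeyError:
            raise LandmarkError(f"landmark {name!r} not in configuration") from None

    def __contains__(self, name: str) -> bool:
        return name in self.landmarks

    def names(self) -> Iterable[str]:
        return self.landmarks.keys()

    def segment_names(self, segment: str) -> list[str]:
        return [n for n in self.landmarks if self.segments[n] == segment]

    def characteristic_length(self) -> float:
        return characteristic_length(list(self.landmarks.values()))

    def transform(self, t: RigidTransform, names: Optional[Iterable[str]] = None
                  ) -> "SkullConfiguration":
        """Apply a rigid transform to ``names`` (default: every landmark)."""
        moved = set(self.landmarks if names is None else names)
        new = {n: (t(p) if n in moved else p) for n, p in self.landmarks.items()}
        return SkullConfiguration(new, dict(self.segments))

    def with_landmark(self, name: str, p: Point2, segment: str) -> "SkullConfiguration":
        lm = dict(self.landmarks)
        lm[name] = p
        seg = dict(self.segments)
        seg[name] = segment
        return SkullConfiguration(lm, seg)

    def validate(self, tol_rel: float = 1e-9) -> None:
        """Check the geometric invariants of an exactly-built configuration.

        Noisy configurations will not satisfy these to ``tol_rel``; pass
        a looser tolerance or skip validation for perturbed data.
        """
        scale = self.characteristic_length()
        tol = tol_rel * scale
        v = self["VIRTUAL_POINT"]
        tmj = self["TMJ"]
        rb = self["UPPER_CANINE_BASE"].distance_to(v)
        rt = self["UPPER_CANINE_TIP"].distance_to(v)
        problems = []
        if abs(rb - rt) > tol:
            problems.append(
                f"canine base and tip are not equidistant from the virtual point "
                f"({rb:.6g} vs {rt:.6g} mm)"
            )
        if not (v.x > tmj.x and v.y < tmj.y):
            problems.append("virtual point is not anteroventral to the TMJ")
        chain = [self["CAUDAL_NECK"], self["MID_NECK"], self["AOJ"]]
        axis = (chain[2] - chain[0])
        if axis.norm <= tol:
            problems.append("neck chain endpoints coincide")
        else:
            u = axis.unit()
            t0, t1, t2 = (u.dot(p - chain[0]) for p in chain)
            if not (t0 < t1 < t2):
                problems.append("neck landmarks are not ordered caudal -> rostral")
        if problems:
            raise ValidationError("invalid configuration: " + "; ".join(problems))


def _jaw_frame(extension_deg: float, upper_jaw_offset_deg: float) -> tuple[Vec2, Vec2]:
    """Unit axes of the cranium's toothrow frame: u along the upper
    toothrow (TMJ -> incisor tip), v its dorsal perpendicular."""
    j = math.radians(extension_deg + upper_jaw_offset_deg)
    u = Vec2(math.cos(j), math.sin(j))
    return u, u.perp()


def generate(params: SkullParams) -> SkullConfiguration:
    """Build a :class:`SkullConfiguration` from exact parameters.

    Construction is deterministic and exact; optional isotropic Gaussian
    landmark noise (``noise_mm``, seeded) is added afterwards, emulating
    digitization error.  With ``noise_mm == 0`` the result satisfies all
    configuration invariants to machine precision and round-trips its
    own parameters (gape, extension, segment lengths, canine radius and
    curvature centre) through the measurement functions below.
    """
    params.validate()
    p = params

    caudal = Point2(0.0, 0.0)
    mid = Point2(p.caudal_to_mid_mm, 0.0)
    aoj = Point2(p.caudal_to_mid_mm + p.mid_to_aoj_mm, 0.0)
    neck_force = Point2(0.0, p.neck_force_dorsal_mm)

    e = math.radians(p.extension_deg)
    tmj = aoj + Vec2(math.cos(e), math.sin(e)) * p.aoj_to_tmj_mm

    u, v = _jaw_frame(p.extension_deg, p.upper_jaw_offset_deg)

    def jaw_local(x: float, y: float) -> Point2:
        return tmj + u * x + v * y

    upper_incisor = jaw_local(p.tmj_to_upper_incisor_mm, 0.0)
    virtual = jaw_local(p.virtual_point_anterior_mm, -p.virtual_point_ventral_mm)

    # canine arc: base where the curvature circle meets the toothrow
    # line (anterior intersection), tip swept canine_span_deg further
    # clockwise (ventrally) along the circle
    psi_base = math.asin(p.virtual_point_ventral_mm / p.canine_radius_mm)
    span = math.radians(p.canine_span_deg)

    def on_canine_circle(psi: float) -> Point2:
        return jaw_local(
            p.virtual_point_anterior_mm + p.canine_radius_mm * math.cos(psi),
            -p.virtual_point_ventral_mm + p.canine_radius_mm * math.sin(psi),
        )

    canine_base = on_canine_circle(psi_base)
    canine_mid = on_canine_circle(psi_base - span / 2.0)
    canine_tip = on_canine_circle(psi_base - span)

    temporalis = jaw_local(-30.0, 60.0)

    # mandible hangs from the TMJ at the gape angle below the toothrow
    m = math.radians(p.extension_deg + p.upper_jaw_offset_deg - p.gape_deg)
    dm = Vec2(math.cos(m), math.sin(m))
    lower_incisor = tmj + dm * p.tmj_to_lower_incisor_mm
    lower_canine = tmj + dm * (0.88 * p.tmj_to_lower_incisor_mm) + dm.perp() * 14.0
    coronoid = tmj + dm * (-15.0) + dm.perp() * 25.0

    landmarks: Dict[str, Point2] = {
        "CAUDAL_NECK": caudal,
        "MID_NECK": mid,
        "NECK_FORCE_POINT": neck_force,
        "AOJ": aoj,
        "TMJ": tmj,
        "UPPER_INCISOR_TIP": upper_incisor,
        "UPPER_CANINE_BASE": canine_base,
        "UPPER_CANINE_MID": canine_mid,
        "UPPER_CANINE_TIP": canine_tip,
        "VIRTUAL_POINT": virtual,
        "TEMPORALIS_ATTACHMENT": temporalis,
        "LOWER_INCISOR_TIP": lower_incisor,
        "LOWER_CANINE_TIP": lower_canine,
        "CORONOID_PROCESS": coronoid,
    }

    if p.noise_mm > 0.0:
        rng = np.random.default_rng(p.seed)
        landmarks = {
            n: Point2(pt.x + rng.normal(0.0, p.noise_mm),
                      pt.y + rng.normal(0.0, p.noise_mm))
            for n, pt in landmarks.items()
        }

    config = SkullConfiguration(landmarks, dict(DEFAULT_SEGMENTS))
    if p.noise_mm == 0.0:
        config.validate()
    return config


_PRESETS = {
    # maximum-gape posture with the mandible vertical against the prey
    "bulldogging": SkullParams(gape_deg=90.0, extension_deg=36.0, noise_mm=0.0),
    # the strike starts from the bulldogging posture
    "shear_bite_start": SkullParams(gape_deg=90.0, extension_deg=36.0, noise_mm=0.0),
    # full closure after a 90-degree strike
    "strike_end": SkullParams(gape_deg=0.0, extension_deg=36.0, noise_mm=0.0),
}


def preset(name: str) -> SkullParams:
    """Named parameter presets for the study postures."""
    try:
        return replace(_PRESETS[name])
    except KeyError:
        known = ", ".join(sorted(_PRESETS))
        raise LandmarkError(f"unknown preset {name!r}; known presets: {known}") from None


def preset_names() -> tuple[str, ...]:
    return tuple(sorted(_PRESETS))


# ---------------------------------------------------------------------------
# measurement functions (the inverse of generate, used in round-trip checks)

def measure_gape(config: SkullConfiguration) -> float:
    """Gape angle in degrees: the angle at the TMJ subtended by the two
    incisor tips, unsigned in [0, 180]."""
    return angle_at_vertex(
        config["TMJ"], config["UPPER_INCISOR_TIP"], config["LOWER_INCISOR_TIP"]
    )


def measure_extension(config: SkullConfiguration) -> float:
    """Signed pitch of the cranial axis (AOJ->TMJ) above the rostral
    neck direction (MID_NECK->AOJ), CCW-positive degrees."""
    neck_dir = config["AOJ"] - config["MID_NECK"]
    cran_dir = config["TMJ"] - config["AOJ"]
    return signed_angle_deg(neck_dir, cran_dir)


def mandible_angle_from_vertical(config: SkullConfiguration,
                                 attachment: Optional[Point2] = None) -> float:
    """Signed angle (degrees, CCW positive) of the mandibular axis from
    the ventral vertical.  The axis runs from the jaw-joint attachment
    (default: the TMJ landmark) to the lower incisor tip; 0 means the
    mandible hangs exactly vertically, the bulldogging posture."""
    origin = config["TMJ"] if attachment is None else attachment
    axis = config["LOWER_INCISOR_TIP"] - origin
    return signed_angle_deg(Vec2(0.0, -1.0), axis)


def measure_canine_radius(config: SkullConfiguration) -> float:
    """Distance from the virtual point to the canine tip (== base by the
    curvature invariant)."""
    return config["UPPER_CANINE_TIP"].distance_to(config["VIRTUAL_POINT"])
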