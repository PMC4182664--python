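"""Planar geometric primitives for landmark-based kinematics.

Everything in this package lives in the sagittal plane with a single
coordinate convention:

* ``+x`` is anterior (the skull faces right), ``+y`` is dorsal;
* angles are counterclockwise-positive and expressed in **degrees** at
  every public interface (radians are used internally only);
* all lengths are **millimetres**.

Under this convention a "ventral" rotation of the anterior-facing skull
is clockwise, i.e. a *negative* internal angle.  User-facing layers
(:mod:`saberbite.rotation`, the CLI) accept positive "ventral degrees"
and handle the sign flip, so the sign convention never leaks to users.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

#: default relative tolerance for degeneracy checks, scaled by a
#: characteristic length of the configuration at hand
TOL_REL = 1e-9


class GeometryError(ValueError):
    """Invalid geometric input (non-finite, negative length, ...)."""


class DegenerateGeometryError(GeometryError):
    """Geometrically degenerate input: coincident points, collinear
    points where a circle is required, zero direction vectors."""


def _check_finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise GeometryError(f"non-finite coordinate: {v!r}")


@dataclass(frozen=True)
class Vec2:
    """Planar displacement vector in millimetres."""

    x: float
    y: float

    def __iter__(self) -> Iterator[float]:
        yield self.x
        yield self.y

    def __add__(self, other: "Vec2") -> "Vec2":
        return Vec2(self.x + other.x, self.y + other.y)

    def __sub__(self, other: "Vec2") -> "Vec2":
        return Vec2(self.x - other.x, self.y - other.y)

    def __mul__(self, s: float) -> "Vec2":
        return Vec2(self.x * s, self.y * s)

    __rmul__ = __mul__

    def __neg__(self) -> "Vec2":
        return Vec2(-self.x, -self.y)

    def dot(self, other: "Vec2") -> float:
        return self.x * other.x + self.y * other.y

    def cross(self, other: "Vec2") -> float:
        """z-component of the 3D cross product (signed parallelogram area)."""
        return self.x * other.y - self.y * other.x

    @property
    def norm(self) -> float:
        return math.hypot(self.x, self.y)

    def unit(self) -> "Vec2":
        n = self.norm
        if n == 0.0:
            raise DegenerateGeometryError("cannot normalise a zero vector")
        return Vec2(self.x / n, self.y / n)

    def perp(self) -> "Vec2":
        """Counterclockwise perpendicular (rotation by +90 degrees)."""
        return Vec2(-self.y, self.x)

    @property
    def angle_deg(self) -> float:
        """Direction angle in degrees, CCW from +x, in (-180, 180]."""
        return normalize_angle_deg(math.degrees(math.atan2(self.y, self.x)))


@dataclass(frozen=True)
class Point2:
    """Planar landmark position: x anterior, y dorsal, millimetres."""

    x: float
    y: float

    def __post_init__(self) -> None:
        _check_finite(self.x, self.y)

    def __iter__(self) -> Iterator[float]:
        yield self.x
        yield self.y

    def __sub__(self, other: "Point2") -> Vec2:
        return Vec2(self.x - other.x, self.y - other.y)

    def __add__(self, v: Vec2) -> "Point2":
        return Point2(self.x + v.x, self.y + v.y)

    def distance_to(self, other: "Point2") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class Line:
    """Infinite line given as an application point and a direction.

    Used for lever lines of action (force, resistance) and the prey-hide
    entry surface.  The direction need not be unit length but must be
    nonzero.
    """

    point: Point2
    direction: Vec2

    def __post_init__(self) -> None:
        if self.direction.norm == 0.0:
            raise DegenerateGeometryError("line direction must be nonzero")

    def unit_direction(self) -> Vec2:
        return self.direction.unit()

    def signed_distance(self, p: Point2) -> float:
        """Signed perpendicular distance; positive to the *left* of the
        direction vector (CCW side)."""
        return self.unit_direction().cross(p - self.point)


@dataclass(frozen=True)
class Circle:
    center: Point2
    radius: float

    def __post_init__(self) -> None:
        _check_finite(self.radius)
        if self.radius <= 0.0:
            raise GeometryError(f"circle radius must be > 0, got {self.radius}")


def normalize_angle_deg(angle: float) -> float:
    """Reduce an angle to the interval (-180, 180]."""
    a = math.fmod(angle, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class RigidTransform:
    """Proper planar rigid motion p' = R(angle) p + t.

    Stored in rotation-matrix-plus-translation form so composition and
    inversion are exact up to floating point.  Build instances with
    :meth:`rotation`, :meth:`translation` or :meth:`identity`.
    """

    cos_a: float = 1.0
    sin_a: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def rotation(cls, center: Point2, angle_deg: float) -> "RigidTransform":
        """Rotation by ``angle_deg`` (CCW positive) about ``center``."""
        _check_finite(angle_deg)
        a = math.radians(angle_deg)
        c, s = math.cos(a), math.sin(a)
        # t = center - R * center
        tx = center.x - (c * center.x - s * center.y)
        ty = center.y - (s * center.x + c * center.y)
        return cls(c, s, tx, ty)

    @classmethod
    def translation(cls, v: Vec2) -> "RigidTransform":
        return cls(1.0, 0.0, v.x, v.y)

    @property
    def angle_deg(self) -> float:
        """Net rotation angle in (-180, 180]."""
        return math.degrees(math.atan2(self.sin_a, self.cos_a))

    @property
    def translation_vec(self) -> Vec2:
        return Vec2(self.tx, self.ty)

    def __call__(self, p: Point2) -> Point2:
        return Point2(
            self.cos_a * p.x - self.sin_a * p.y + self.tx,
            self.sin_a * p.x + self.cos_a * p.y + self.ty,
        )

    def apply_vec(self, v: Vec2) -> Vec2:
        """Rotate a free vector (translation does not apply)."""
        return Vec2(self.cos_a * v.x - self.sin_a * v.y,
                    self.sin_a * v.x + self.cos_a * v.y)

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Return self ∘ first (``first`` applied first)."""
        c = self.cos_a * first.cos_a - self.sin_a * first.sin_a
        s = self.sin_a * first.cos_a + self.cos_a * first.sin_a
        tx = self.cos_a * first.tx - self.sin_a * first.ty + self.tx
        ty = self.sin_a * first.tx + self.cos_a * first.ty + self.ty
        return RigidTransform(c, s, tx, ty)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        c, s = self.cos_a, -self.sin_a
        tx = -(c * self.tx - s * self.ty)
        ty = -(s * self.tx + c * self.ty)
        return RigidTransform(c, s, tx, ty)


def rotate_about(p: Point2, center: Point2, angle_deg: float) -> Point2:
    """Rotate ``p`` about ``center`` by ``angle_deg`` (CCW positive)."""
    return RigidTransform.rotation(center, angle_deg)(p)


def chord_displacement(radius: float, angle_deg: float) -> float:
    """Chord length swept by a point at ``radius`` under a rotation.

    A point at distance *r* from a pivot, rotated through an arc θ,
    is displaced by the chord ``2 r sin(θ/2)``.  This is the law that
    makes the jaw joint translate whenever the neck-and-skull unit is
    rotated about any pivot other than the joint itself.
    """
    _check_finite(radius, angle_deg)
    if radius < 0.0:
        raise GeometryError(f"radius must be >= 0, got {radius}")
    half = math.radians(math.fmod(abs(angle_deg), 360.0)) / 2.0
    return 2.0 * radius * abs(math.sin(half))


def angle_at_vertex(vertex: Point2, a: Point2, b: Point2) -> float:
    """Unsigned angle in [0, 180] degrees between rays vertex->a and vertex->b.

    Computed through atan2 of the cross/dot pair, which stays accurate
    for nearly collinear rays (where an acos formulation loses digits).
    """
    u = a - vertex
    v = b - vertex
    if u.norm == 0.0 or v.norm == 0.0:
        raise DegenerateGeometryError("ray endpoint coincides with vertex")
    return abs(math.degrees(math.atan2(u.cross(v), u.dot(v))))


def signed_angle_deg(u: Vec2, v: Vec2) -> float:
    """Signed CCW angle from u to v, in (-180, 180] degrees."""
    if u.norm == 0.0 or v.norm == 0.0:
        raise DegenerateGeometryError("signed angle of a zero vector")
    return math.degrees(math.atan2(u.cross(v), u.dot(v)))


def perpendicular_distance(point: Point2, line: Line) -> float:
    """Unsigned shortest distance from ``point`` to the infinite ``line``."""
    return abs(line.signed_distance(point))


def characteristic_length(points: Sequence[Point2]) -> float:
    """Largest pairwise distance; the scale for relative tolerances."""
    pts = list(points)
    if len(pts) < 2:
        return 1.0
    arr = np.array([[p.x, p.y] for p in pts])
    # O(n^2) but n is a dozen landmarks
    d = arr[:, None, :] - arr[None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).max())


def fit_circle(points: Sequence[Point2], tol_rel: float = TOL_REL) -> Circle:
    """Fit a circle to >= 3 planar points.

    For exactly three points the circumcircle is returned (the linear
    system is solved exactly); for more, the algebraic (Kasa) least
    squares circle, i.e. the minimiser of sum((|p-c|^2 - r^2)^2) in the
    linearised parameters.  Raises :class:`DegenerateGeometryError` when
    the points are collinear to within ``tol_rel`` times the
    configuration's characteristic length.
    """
    pts = list(points)
    if len(pts) < 3:
        raise GeometryError(f"need at least 3 points to fit a circle, got {len(pts)}")
    scale = characteristic_length(pts)
    arr = np.array([[p.x, p.y] for p in pts], dtype=float)
    # collinearity check against the span of the point cloud
    rel = arr - arr.mean(axis=0)
    # second singular value measures thickness orthogonal to the best line
    sv = np.linalg.svd(rel, compute_uv=False)
    if sv[-1] <= tol_rel * scale * max(1.0, len(pts) ** 0.5):
        raise DegenerateGeometryError("points are collinear: no circle exists")
    # Kasa system: 2*cx*x + 2*cy*y + (r^2 - cx^2 - cy^2) = x^2 + y^2
    A = np.column_stack([2.0 * arr[:, 0], 2.0 * arr[:, 1], np.ones(len(pts))])
    b = (arr ** 2).sum(axis=1)
    if len(pts) == 3:
        sol = np.linalg.solve(A, b)
    else:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0.0:
        raise DegenerateGeometryError("degenerate circle fit (non-positive radius)")
    return Circle(Point2(float(cx), float(cy)), float(math.sqrt(r2)))


def circle_residuals(circle: Circle, points: Sequence[Point2]) -> np.ndarray:
    """Geometric residuals |p - center| - radius, one per point."""
    return np.array([p.distance_to(circle.center) - circle.radius for p in points])
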