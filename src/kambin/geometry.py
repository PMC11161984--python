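"""Coordinate-free 3D geometric primitives.

All lengths are millimetres; angles are degrees at the API surface and
radians internally.  Points are exposed both as a small :class:`Point3`
record and as plain length-3 numpy arrays — every operation accepts either.

Case frame convention (used by the measurement pipeline, not enforced
here): x lateral toward the measured side, y posterior, z superior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Tuple, Union

import numpy as np

from .errors import (
    IntersectionBehindRayError,
    InvalidGeometryError,
    NoIntersectionError,
    ProjectionDegenerateError,
)

#: absolute tolerance for geometric identity checks, in mm
GEOM_TOL = 1e-9

#: permitted deviation of the triangle's right angle, in degrees
RIGHT_ANGLE_TOL_DEG = 2.0

PointLike = Union["Point3", Iterable[float], np.ndarray]


@dataclass(frozen=True)
class Point3:
    """A point in the case frame, coordinates in mm."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in (self.x, self.y, self.z)):
            raise InvalidGeometryError(f"non-finite coordinates: {self}")

    @classmethod
    def from_array(cls, a: Iterable[float]) -> "Point3":
        x, y, z = (float(c) for c in a)
        return cls(x, y, z)

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


def as_vec(p: PointLike) -> np.ndarray:
    """Coerce a Point3 or array-like to a float64 length-3 array."""
    if isinstance(p, Point3):
        return p.to_array()
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise InvalidGeometryError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidGeometryError("non-finite coordinates")
    return a


def unit(v: PointLike) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    n = np.linalg.norm(a)
    if n < GEOM_TOL:
        raise InvalidGeometryError("cannot normalize a (near-)zero vector")
    return a / n


@dataclass(frozen=True)
class Segment3:
    """Directed segment between two distinct points."""

    p: np.ndarray
    q: np.ndarray

    def __init__(self, p: PointLike, q: PointLike):
        object.__setattr__(self, "p", as_vec(p))
        object.__setattr__(self, "q", as_vec(q))
        if np.linalg.norm(self.q - self.p) < GEOM_TOL:
            raise InvalidGeometryError("degenerate segment: p == q")

    @property
    def direction(self) -> np.ndarray:
        return unit(self.q - self.p)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.q - self.p))


@dataclass(frozen=True)
class Ray3:
    """Ray from an origin along a unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __init__(self, origin: PointLike, direction: PointLike):
        d = as_vec(direction)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise InvalidGeometryError("ray direction must be a unit vector")
        object.__setattr__(self, "origin", as_vec(origin))
        object.__setattr__(self, "direction", d)

    def at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


@dataclass(frozen=True)
class Cylinder:
    """Infinite circular cylinder: an axis ray and a radius in mm."""

    axis: Ray3
    radius: float

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise InvalidGeometryError(f"cylinder radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class PlanePatch:
    """Bounded planar patch: origin plus orthonormal in-plane axes and ranges.

    ``u_range``/``v_range`` are (lo, hi) intervals in mm around the origin.
    """

    origin: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    u_range: Tuple[float, float]
    v_range: Tuple[float, float]

    def __init__(
        self,
        origin: PointLike,
        u_axis: PointLike,
        v_axis: PointLike,
        u_range: Tuple[float, float],
        v_range: Tuple[float, float],
    ):
        u = as_vec(u_axis)
        v = as_vec(v_axis)
        if abs(np.linalg.norm(u) - 1.0) > 1e-9 or abs(np.linalg.norm(v) - 1.0) > 1e-9:
            raise InvalidGeometryError("patch axes must be unit vectors")
        if abs(float(np.dot(u, v))) > 1e-9:
            raise InvalidGeometryError("patch axes must be orthogonal")
        ur = (float(u_range[0]), float(u_range[1]))
        vr = (float(v_range[0]), float(v_range[1]))
        if not (ur[0] < ur[1] and vr[0] < vr[1]):
            raise InvalidGeometryError("patch ranges must be non-degenerate")
        object.__setattr__(self, "origin", as_vec(origin))
        object.__setattr__(self, "u_axis", u)
        object.__setattr__(self, "v_axis", v)
        object.__setattr__(self, "u_range", ur)
        object.__setattr__(self, "v_range", vr)

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u_axis, self.v_axis)

    def to_uv(self, p: PointLike) -> Tuple[float, float]:
        """In-plane coordinates of a point (its projection onto the plane)."""
        w = as_vec(p) - self.origin
        return float(np.dot(w, self.u_axis)), float(np.dot(w, self.v_axis))

    def from_uv(self, u: float, v: float) -> np.ndarray:
        return self.origin + u * self.u_axis + v * self.v_axis

    def contains_uv(self, u: float, v: float) -> bool:
        return (
            self.u_range[0] <= u <= self.u_range[1]
            and self.v_range[0] <= v <= self.v_range[1]
        )


@dataclass(frozen=True)
class PlaneHit:
    """Result of a ray/plane intersection."""

    point: np.ndarray
    uv: Tuple[float, float]
    in_patch: bool
    t: float = field(default=0.0)


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------


def incircle_diameter_right(base: float, height: float) -> float:
    """Diameter of the circle inscribed in a right triangle with the given legs.

    Uses the right-triangle identity d = base + height − hypotenuse, which
    equals the general 4·Area / perimeter formula when the angle between the
    legs is 90°.
    """
    if not (base > 0 and height > 0):
        raise InvalidGeometryError(
            f"triangle legs must be positive, got base={base}, height={height}"
        )
    return base + height - math.hypot(base, height)


def triangle_angle_deg(vertex: PointLike, p: PointLike, q: PointLike) -> float:
    """Interior angle at ``vertex`` of the triangle (vertex, p, q), degrees."""
    a = as_vec(p) - as_vec(vertex)
    b = as_vec(q) - as_vec(vertex)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < GEOM_TOL or nb < GEOM_TOL:
        raise InvalidGeometryError("degenerate (zero-length) triangle edge")
    cross = np.linalg.norm(np.cross(a, b))
    dot = float(np.dot(a, b))
    return math.degrees(math.atan2(cross, dot))


def incircle_center(
    A: PointLike,
    B: PointLike,
    C: PointLike,
    *,
    require_right_angle_at_C: bool = True,
    right_angle_tol_deg: float = RIGHT_ANGLE_TOL_DEG,
) -> np.ndarray:
    """Incenter of triangle ABC via the side-length-weighted vertex average.

    The incenter is (a·A + b·B + c·C)/(a+b+c) with a, b, c the side lengths
    opposite each vertex; it lies in the triangle's plane at distance
    inradius from each edge line.
    """
    Av, Bv, Cv = as_vec(A), as_vec(B), as_vec(C)
    area2 = np.linalg.norm(np.cross(Bv - Av, Cv - Av))
    if area2 < GEOM_TOL:
        raise InvalidGeometryError("collinear triangle vertices")
    if require_right_angle_at_C:
        ang = triangle_angle_deg(Cv, Av, Bv)
        if abs(ang - 90.0) > right_angle_tol_deg:
            raise InvalidGeometryError(
                f"angle at C is {ang:.3f}°, outside 90 ± {right_angle_tol_deg}°"
            )
    a = np.linalg.norm(Bv - Cv)  # opposite A
    b = np.linalg.norm(Av - Cv)  # opposite B
    c = np.linalg.norm(Av - Bv)  # opposite C
    return (a * Av + b * Bv + c * Cv) / (a + b + c)


def project_onto_plane(v: PointLike, normal: PointLike) -> np.ndarray:
    n = unit(normal)
    a = np.asarray(v, dtype=float)
    return a - float(np.dot(a, n)) * n


def angle_between_projected(
    l1_p: PointLike,
    l1_q: PointLike,
    l2_p: PointLike,
    l2_q: PointLike,
    plane_normal: PointLike,
) -> float:
    """Unsigned angle in [0, 90] between two lines projected into a plane.

    Line directions are q − p; each must have a non-degenerate projection
    onto the plane with the given normal.  The result is a line angle
    (folded at 90°), so it is symmetric in the two lines and invariant to
    swapping either line's endpoints.
    """
    n = unit(plane_normal)
    u = project_onto_plane(as_vec(l1_q) - as_vec(l1_p), n)
    v = project_onto_plane(as_vec(l2_q) - as_vec(l2_p), n)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < GEOM_TOL or nv < GEOM_TOL:
        raise ProjectionDegenerateError(
            "a direction is (near-)parallel to the projection plane normal"
        )
    cross = np.linalg.norm(np.cross(u, v))
    dot = float(np.dot(u, v))
    ang = math.degrees(math.atan2(cross, abs(dot)))
    return ang


def point_line_distance(p: PointLike, origin: PointLike, direction: PointLike) -> float:
    w = as_vec(p) - as_vec(origin)
    t = unit(direction)
    return float(np.linalg.norm(w - np.dot(w, t) * t))


def line_segment_distance(
    origin: PointLike, direction: PointLike, seg: Segment3
) -> float:
    """Minimum distance between an infinite line and a segment.

    The squared distance is a convex quadratic in the segment parameter, so
    the minimizer is the unconstrained optimum clamped to [0, 1].
    """
    o = as_vec(origin)
    t = unit(direction)
    # components of the segment endpoints perpendicular to the line
    b = (seg.p - o) - np.dot(seg.p - o, t) * t
    u = seg.q - seg.p
    a = u - np.dot(u, t) * t
    aa = float(np.dot(a, a))
    if aa < GEOM_TOL**2:
        # segment parallel to the line: constant distance
        return float(np.linalg.norm(b))
    s = float(np.clip(-np.dot(a, b) / aa, 0.0, 1.0))
    return float(np.linalg.norm(b + s * a))


def cylinder_segment_clearance(cyl: Cylinder, seg: Segment3) -> float:
    """Signed clearance from the cylinder surface to a segment.

    Positive: the segment stays outside the cylinder by that margin.
    Zero: tangent.  Negative: the segment comes within the radius of the
    axis (breach).  Exactly linear in the radius by construction.
    """
    return line_segment_distance(cyl.axis.origin, cyl.axis.direction, seg) - cyl.radius


def ray_plane_intersection(ray: Ray3, patch: PlanePatch) -> PlaneHit:
    """Intersect a ray with a patch's plane.

    Raises :class:`NoIntersectionError` for a parallel ray and
    :class:`IntersectionBehindRayError` when the line through the ray meets
    the plane only behind the origin.
    """
    n = patch.normal
    denom = float(np.dot(ray.direction, n))
    if abs(denom) < GEOM_TOL:
        raise NoIntersectionError("ray is parallel to the plane")
    t = float(np.dot(patch.origin - ray.origin, n) / denom)
    if t < 0:
        raise IntersectionBehindRayError(
            f"plane lies behind the ray origin (t = {t:.6g})", t=t
        )
    p = ray.at(t)
    u, v = patch.to_uv(p)
    return PlaneHit(point=p, uv=(u, v), in_patch=patch.contains_uv(u, v), t=t)


def rotation_about_axis(axis: PointLike, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    k = unit(axis)
    K = np.array(
        [[0.0, -k[2], k[1]], [k[2], 0.0, -k[0]], [-k[1], k[0], 0.0]]
    )
    return np.eye(3) + math.sin(angle_rad) * K + (1.0 - math.cos(angle_rad)) * (K @ K)
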