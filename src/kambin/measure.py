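"""Per-case measurement pipeline.

Turns one landmark set (a :class:`LumbarCase`) into the scalar safe-zone
measurements: inscribed-circle diameter ``d``, abduction angle ``beta``,
facet anchor point ``J`` with its quadrant label, and the trephine-to-root
clearances ``L1`` and ``L2``.

Conventions (active in every measurement, recorded in report headers):

* Case frame: x lateral toward the measured side, y posterior, z superior,
  all coordinates in mm.  Left-sided cases are mirrored into this frame on
  ingest; the original side is retained as metadata.
* ``beta`` is the unsigned angle between the transverse-plane projections
  of lines OD and DE (not the 3D angle).
* The trephine axis direction is the in-disc-plane midline direction
  abducted by ``beta`` toward the measured side, with zero cranio-caudal
  inclination.  The axis passes through the wire anchor point: the incircle
  center O shifted by the case's ``wire_offset`` perpendicular to the axis
  (offset (0, 0) puts the axis through O itself).
* Nerve roots are zero-radius segments; the trephine is unbounded along
  its axis, so clearances use line-segment distance.
* ``L2`` is the shortest distance from the trephine surface to the
  traversing root (the same rule as ``L1``).
* Quadrant boundary ties are half-open, favouring the upper and outer
  side; the distance to the nearest border is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import InvalidGeometryError, MeasurementError, ProjectionDegenerateError
from .geometry import (
    GEOM_TOL,
    RIGHT_ANGLE_TOL_DEG,
    Cylinder,
    PlaneHit,
    PlanePatch,
    PointLike,
    Ray3,
    Segment3,
    angle_between_projected,
    as_vec,
    cylinder_segment_clearance,
    incircle_center,
    incircle_diameter_right,
    project_onto_plane,
    ray_plane_intersection,
    triangle_angle_deg,
    unit,
)

#: maximum deviation of the disc tangent rectangle from a true rectangle, mm
RECTANGLE_TOL = 0.1

QUADRANT_LABELS = {
    (True, True): "A",  # upper outer
    (True, False): "B",  # upper inner
    (False, True): "C",  # lower outer
    (False, False): "D",  # lower inner
}

FACET_LANDMARK_NAMES = (
    "upper_vertex_L5",
    "lower_edge_L4",
    "lateral_edge_facet",
    "lateral_edge_exiting_root",
)


@dataclass(frozen=True)
class LumbarCase:
    """One side of one L4-L5 level: landmarks plus covariates, mm."""

    case_id: str
    side: str  # 'left' | 'right'
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    disc_corners: np.ndarray  # (4, 3) tangent rectangle, transverse plane
    E: np.ndarray  # spinous-process center
    facet_landmarks: Dict[str, np.ndarray]
    facet_patch: PlanePatch
    sex: str  # 'M' | 'F'
    age: float  # years
    bmi: float  # kg/m^2
    wire_offset: Tuple[float, float] = (0.0, 0.0)  # (lateral, superior), mm

    def __post_init__(self) -> None:
        for name in ("A", "B", "C", "E"):
            object.__setattr__(self, name, as_vec(getattr(self, name)))
        corners = np.asarray(self.disc_corners, dtype=float)
        if corners.shape != (4, 3):
            raise InvalidGeometryError(
                f"disc_corners must have shape (4, 3), got {corners.shape}"
            )
        object.__setattr__(self, "disc_corners", corners)
        if self.side not in ("left", "right"):
            raise InvalidGeometryError(f"side must be left/right, got {self.side!r}")
        if self.sex not in ("M", "F"):
            raise InvalidGeometryError(f"sex must be M/F, got {self.sex!r}")
        missing = [k for k in FACET_LANDMARK_NAMES if k not in self.facet_landmarks]
        if missing:
            raise InvalidGeometryError(f"missing facet landmarks: {missing}")
        object.__setattr__(
            self,
            "facet_landmarks",
            {k: as_vec(v) for k, v in self.facet_landmarks.items()},
        )
        ou, ov = self.wire_offset
        object.__setattr__(self, "wire_offset", (float(ou), float(ov)))

    def validate(self) -> None:
        """Check the full geometric invariants (rectangle, right angle)."""
        build_triangle(self)
        locate_disc_center(self)


@dataclass(frozen=True)
class KambinTriangle:
    """Right working triangle with role-labelled edges."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    exiting_root: Segment3  # hypotenuse AB
    traversing_root: Segment3  # height AC
    pedicle_line: Segment3  # base BC

    @property
    def base(self) -> float:
        return self.pedicle_line.length

    @property
    def height(self) -> float:
        return self.traversing_root.length

    @property
    def plane_normal(self) -> np.ndarray:
        """Unit normal of the triangle plane (orientation unspecified)."""
        return unit(np.cross(self.B - self.A, self.C - self.A))


@dataclass(frozen=True)
class TrephinePlan:
    """Planned trephine cylinder at abduction angle beta.

    ``cylinder.axis.origin`` is the wire anchor point (O plus the case's
    wire offset); ``cylinder.axis.direction`` points anteriorly (toward the
    disc).  ``anchor_O`` is the incircle center the plan was built from.
    """

    cylinder: Cylinder
    beta: float  # degrees
    anchor_O: np.ndarray
    wire_offset: Tuple[float, float] = (0.0, 0.0)

    @property
    def posterior_direction(self) -> np.ndarray:
        return -self.cylinder.axis.direction


@dataclass(frozen=True)
class QuadrantGrid:
    """Four-quadrant segmentation of the facet patch.

    Borders are in-patch coordinates: ``u_border`` separates outer (u >=)
    from inner, ``v_border`` separates upper (v >=) from lower.  Labels are
    fixed: A upper-outer, B upper-inner, C lower-outer, D lower-inner.
    """

    patch: PlanePatch
    u_border: float
    v_border: float


@dataclass(frozen=True)
class CaseMeasurements:
    """Full per-case measurement record."""

    case_id: str
    side: str
    d: float  # mm
    beta: float  # degrees
    O: np.ndarray
    D_center: np.ndarray
    J: np.ndarray
    j_in_patch: bool
    quadrant: str
    boundary_distance: float  # mm, distance from J to nearest quadrant border
    L1: float  # mm
    L2: float  # mm
    safe_L1: bool
    safe_L2: bool

    def __post_init__(self) -> None:
        if self.quadrant not in "ABCD":
            raise InvalidGeometryError(f"bad quadrant label {self.quadrant!r}")
        if self.safe_L1 != (self.L1 >= 0) or self.safe_L2 != (self.L2 >= 0):
            raise InvalidGeometryError("safety flags inconsistent with L1/L2 signs")


@dataclass(frozen=True)
class MeasurementConfig:
    """Knobs of the forward pipeline."""

    trephine_diameter: float = 8.0  # mm
    right_angle_tol_deg: float = RIGHT_ANGLE_TOL_DEG

    def __post_init__(self) -> None:
        if not (self.trephine_diameter > 0):
            raise InvalidGeometryError("trephine diameter must be > 0")


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def build_triangle(
    case: LumbarCase, *, right_angle_tol_deg: float = RIGHT_ANGLE_TOL_DEG
) -> KambinTriangle:
    """Assemble the working triangle and validate its right angle at C."""
    A, B, C = case.A, case.B, case.C
    if np.linalg.norm(np.cross(B - A, C - A)) < GEOM_TOL:
        raise InvalidGeometryError("triangle vertices are collinear")
    ang = triangle_angle_deg(C, A, B)
    if abs(ang - 90.0) > right_angle_tol_deg:
        raise InvalidGeometryError(
            f"angle at C is {ang:.3f} deg, outside 90 +/- {right_angle_tol_deg} deg"
        )
    return KambinTriangle(
        A=A,
        B=B,
        C=C,
        exiting_root=Segment3(A, B),
        traversing_root=Segment3(A, C),
        pedicle_line=Segment3(B, C),
    )


def measure_d(tri: KambinTriangle) -> Tuple[float, np.ndarray]:
    """Inscribed-circle diameter from the legs, and its center O."""
    d = incircle_diameter_right(tri.base, tri.height)
    O = incircle_center(tri.A, tri.B, tri.C)
    return d, O


def locate_disc_center(case: LumbarCase) -> np.ndarray:
    """Center of the disc tangent rectangle: the intersection of its diagonals.

    The four corners may arrive in any order; the diagonal pairing is the
    one whose two midpoints coincide (parallelogram condition), and the
    diagonals must have equal length within :data:`RECTANGLE_TOL`.
    """
    c = case.disc_corners
    pairings = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))
    for (i, j), (k, l) in pairings:
        m1 = (c[i] + c[j]) / 2.0
        m2 = (c[k] + c[l]) / 2.0
        if np.linalg.norm(m1 - m2) <= RECTANGLE_TOL:
            d1 = np.linalg.norm(c[i] - c[j])
            d2 = np.linalg.norm(c[k] - c[l])
            if abs(d1 - d2) <= RECTANGLE_TOL and d1 > RECTANGLE_TOL:
                return (m1 + m2) / 2.0
    raise InvalidGeometryError(
        f"disc corners do not form a rectangle within {RECTANGLE_TOL} mm"
    )


def disc_plane_normal(case: LumbarCase) -> np.ndarray:
    """Unit normal of the disc rectangle plane, oriented superiorly.

    The superior orientation cue is the traversing root direction C -> A,
    which keeps the result invariant under rigid motion of the whole case.
    """
    c = case.disc_corners
    n = np.cross(c[1] - c[0], c[2] - c[0])
    if np.linalg.norm(n) < GEOM_TOL:
        n = np.cross(c[1] - c[0], c[3] - c[0])
    n = unit(n)
    if float(np.dot(n, case.A - case.C)) < 0:
        n = -n
    return n


def measure_beta(
    O: PointLike,
    D: PointLike,
    E: PointLike,
    transverse_normal: PointLike,
) -> float:
    """Abduction angle: lines OD and DE projected into the transverse plane."""
    return angle_between_projected(D, O, D, E, transverse_normal)


def plan_trephine(
    O: PointLike,
    D: PointLike,
    E: PointLike,
    beta: float,
    diameter: float,
    disc_plane_normal: PointLike,
    wire_offset: Tuple[float, float] = (0.0, 0.0),
) -> TrephinePlan:
    """Build the trephine cylinder for a case.

    The axis direction is the midline direction E -> D projected into the
    disc plane and abducted by ``beta`` about the plane normal, posterior
    end swinging toward the measured side (the side O lies on); the
    cranio-caudal inclination is zero by construction.  The axis passes
    through the anchor point O + wire_offset, the offset being expressed in
    the (lateral, superior) basis perpendicular to the axis.
    """
    if not (diameter > 0):
        raise InvalidGeometryError("trephine diameter must be > 0")
    Ov, Dv, Ev = as_vec(O), as_vec(D), as_vec(E)
    n = unit(disc_plane_normal)
    m_raw = project_onto_plane(Dv - Ev, n)
    if np.linalg.norm(m_raw) < GEOM_TOL:
        raise ProjectionDegenerateError("midline DE degenerate in the disc plane")
    m = unit(m_raw)  # anterior midline direction, in-plane
    # lateral cue: in-plane component of O relative to D, perpendicular to m
    od = project_onto_plane(Ov - Dv, n)
    l_raw = od - float(np.dot(od, m)) * m
    beta_rad = math.radians(beta)
    if np.linalg.norm(l_raw) < GEOM_TOL:
        if abs(beta_rad) > 1e-12:
            raise ProjectionDegenerateError(
                "O lies on the midline: abduction side undefined for beta != 0"
            )
        lat = unit(np.cross(n, m))  # arbitrary but fixed for beta = 0
    else:
        lat = unit(l_raw)
    # tip (anterior) direction: midline abducted so the posterior end moves
    # toward the measured side
    tip = math.cos(beta_rad) * m - math.sin(beta_rad) * lat
    tip = unit(project_onto_plane(tip, n))  # guard: zero cranio-caudal tilt
    e_lat = unit(np.cross(n, tip))
    if float(np.dot(e_lat, lat)) < 0:
        e_lat = -e_lat
    ou, ov = float(wire_offset[0]), float(wire_offset[1])
    anchor = Ov + ou * e_lat + ov * n
    return TrephinePlan(
        cylinder=Cylinder(axis=Ray3(anchor, tip), radius=diameter / 2.0),
        beta=float(beta),
        anchor_O=Ov,
        wire_offset=(ou, ov),
    )


def locate_J(plan: TrephinePlan, facet_patch: PlanePatch) -> PlaneHit:
    """Posterior intersection of the trephine axis with the facet plane."""
    ray = Ray3(plan.cylinder.axis.origin, plan.posterior_direction)
    return ray_plane_intersection(ray, facet_patch)


def build_quadrant_grid(case: LumbarCase) -> QuadrantGrid:
    """Quadrant borders from the four facet construction landmarks.

    Horizontal lines through the upper facet vertex (L5) and the lower
    facet edge (L4) give the horizontal border as their mid-line; vertical
    lines through the lateral facet edge and the lateral exiting-root edge
    give the vertical border.
    """
    patch = case.facet_patch
    uv = {k: patch.to_uv(v) for k, v in case.facet_landmarks.items()}
    v1 = uv["upper_vertex_L5"][1]
    v2 = uv["lower_edge_L4"][1]
    u3 = uv["lateral_edge_facet"][0]
    u4 = uv["lateral_edge_exiting_root"][0]
    if abs(v1 - v2) < GEOM_TOL or abs(u3 - u4) < GEOM_TOL:
        raise InvalidGeometryError("coincident quadrant construction lines")
    return QuadrantGrid(patch=patch, u_border=(u3 + u4) / 2.0, v_border=(v1 + v2) / 2.0)


def assign_quadrant(
    J: PointLike, grid: QuadrantGrid, *, plane_tol: float = 1e-6
) -> Tuple[str, float]:
    """Quadrant label for a point plus its distance to the nearest border.

    Half-open convention: a point exactly on a border is assigned to the
    upper and/or outer side.
    """
    Jv = as_vec(J)
    off = abs(float(np.dot(Jv - grid.patch.origin, grid.patch.normal)))
    if off > plane_tol:
        raise InvalidGeometryError(
            f"J is {off:.3g} mm out of the facet plane (tolerance {plane_tol})"
        )
    u, v = grid.patch.to_uv(Jv)
    upper = v >= grid.v_border
    outer = u >= grid.u_border
    label = QUADRANT_LABELS[(upper, outer)]
    return label, min(abs(u - grid.u_border), abs(v - grid.v_border))


def measure_clearances(plan: TrephinePlan, tri: KambinTriangle) -> Tuple[float, float]:
    """Signed clearances (L1 to the exiting root, L2 to the traversing root)."""
    L1 = cylinder_segment_clearance(plan.cylinder, tri.exiting_root)
    L2 = cylinder_segment_clearance(plan.cylinder, tri.traversing_root)
    return L1, L2


def measure_case(
    case: LumbarCase, config: Optional[MeasurementConfig] = None
) -> CaseMeasurements:
    """Run the full deterministic pipeline on one case."""
    cfg = config or MeasurementConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # annotate with case id and stage
            raise MeasurementError(case.case_id, name, exc) from exc

    tri = stage("build_triangle", build_triangle, case,
                right_angle_tol_deg=cfg.right_angle_tol_deg)
    d, O = stage("measure_d", measure_d, tri)
    D = stage("locate_disc_center", locate_disc_center, case)
    n = stage("disc_plane_normal", disc_plane_normal, case)
    beta = stage("measure_beta", measure_beta, O, D, case.E, n)
    plan = stage(
        "plan_trephine",
        plan_trephine,
        O, D, case.E, beta, cfg.trephine_diameter, n,
        wire_offset=case.wire_offset,
    )
    hit = stage("locate_J", locate_J, plan, case.facet_patch)
    grid = stage("build_quadrant_grid", build_quadrant_grid, case)
    quadrant, border_dist = stage("assign_quadrant", assign_quadrant, hit.point, grid)
    L1, L2 = stage("measure_clearances", measure_clearances, plan, tri)
    return CaseMeasurements(
        case_id=case.case_id,
        side=case.side,
        d=float(d),
        beta=float(beta),
        O=O,
        D_center=D,
        J=hit.point,
        j_in_patch=hit.in_patch,
        quadrant=quadrant,
        boundary_distance=float(border_dist),
        L1=float(L1),
        L2=float(L2),
        safe_L1=bool(L1 >= 0),
        safe_L2=bool(L2 >= 0),
    )


def sweep_beta(
    case: LumbarCase,
    betas: np.ndarray,
    config: Optional[MeasurementConfig] = None,
) -> np.ndarray:
    """Clearances over a beta grid for one fixed anatomy.

    Overrides the measured abduction angle with each grid value while
    keeping every landmark (and the wire offset, expressed in the rotating
    axis frame) fixed.  Returns an array of rows (beta, L1, L2).
    """
    cfg = config or MeasurementConfig()
    tri = build_triangle(case, right_angle_tol_deg=cfg.right_angle_tol_deg)
    _, O = measure_d(tri)
    D = locate_disc_center(case)
    n = disc_plane_normal(case)
    rows = []
    for b in np.asarray(betas, dtype=float):
        plan = plan_trephine(
            O, D, case.E, float(b), cfg.trephine_diameter, n,
            wire_offset=case.wire_offset,
        )
        L1, L2 = measure_clearances(plan, tri)
        rows.append((float(b), float(L1), float(L2)))
    return np.array(rows)


# ---------------------------------------------------------------------------
# frame utilities
# ---------------------------------------------------------------------------

_MIRROR = np.diag([-1.0, 1.0, 1.0])


def _mirror_patch(patch: PlanePatch) -> PlanePatch:
    return PlanePatch(
        origin=_MIRROR @ patch.origin,
        u_axis=_MIRROR @ patch.u_axis,
        v_axis=_MIRROR @ patch.v_axis,
        u_range=patch.u_range,
        v_range=patch.v_range,
    )


def mirror_case(case: LumbarCase, *, flip_side: bool = True) -> LumbarCase:
    """Reflect a case across the midsagittal plane (x -> -x).

    Scalar measurements are invariant under this reflection; only the
    coordinates of O, D and J change.  Used to store left-sided cases in
    anatomical coordinates while measuring in the canonical frame.
    """
    side = case.side
    if flip_side:
        side = "left" if side == "right" else "right"
    return replace(
        case,
        side=side,
        A=_MIRROR @ case.A,
        B=_MIRROR @ case.B,
        C=_MIRROR @ case.C,
        E=_MIRROR @ case.E,
        disc_corners=case.disc_corners @ _MIRROR.T,
        facet_landmarks={k: _MIRROR @ v for k, v in case.facet_landmarks.items()},
        facet_patch=_mirror_patch(case.facet_patch),
    )


def transform_case(case: LumbarCase, R: np.ndarray, t: PointLike) -> LumbarCase:
    """Apply a rigid transform x -> R x + t to every landmark of a case."""
    R = np.asarray(R, dtype=float)
    tv = as_vec(t)

    def tp(p):
        return R @ p + tv

    return replace(
        case,
        A=tp(case.A),
        B=tp(case.B),
        C=tp(case.C),
        E=tp(case.E),
        disc_corners=np.array([tp(c) for c in case.disc_corners]),
        facet_landmarks={k: tp(v) for k, v in case.facet_landmarks.items()},
        facet_patch=PlanePatch(
            origin=tp(case.facet_patch.origin),
            u_axis=R @ case.facet_patch.u_axis,
            v_axis=R @ case.facet_patch.v_axis,
            u_range=case.facet_patch.u_range,
            v_range=case.facet_patch.v_range,
        ),
    )
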