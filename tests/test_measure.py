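"""Tests for the per-case measurement pipeline."""

import math
from dataclasses import replace

import numpy as np
import pytest

from kambin.errors import (
    InvalidGeometryError,
    MeasurementError,
    NoIntersectionError,
    ProjectionDegenerateError,
)
from kambin.geometry import PlanePatch, point_line_distance
from kambin.measure import (
    MeasurementConfig,
    QuadrantGrid,
    assign_quadrant,
    build_quadrant_grid,
    build_triangle,
    locate_disc_center,
    locate_J,
    measure_beta,
    measure_case,
    measure_clearances,
    measure_d,
    mirror_case,
    plan_trephine,
    sweep_beta,
    transform_case,
)
from kambin.synth import GeneratorConfig, TargetQuadruple, invert_case

from .conftest import random_rotation


def make_case(**overrides):
    """A hand-posed valid case: 30 x 40 right triangle, simple layout."""
    case = invert_case(
        TargetQuadruple(d=11.62, beta=32.02, L1=1.40, L2=2.30),
        GeneratorConfig(seed=0),
        case_id="T1",
    )
    return replace(case, **overrides) if overrides else case


class TestBuildTriangle:
    def test_30_40_right_triangle(self):
        case = make_case(
            A=np.array([0.0, 0.0, 40.0]),
            B=np.array([30.0, 0.0, 0.0]),
            C=np.array([0.0, 0.0, 0.0]),
        )
        tri = build_triangle(case)
        assert tri.exiting_root.length == pytest.approx(50.0)
        assert tri.base == pytest.approx(30.0)
        assert tri.height == pytest.approx(40.0)

    def test_collinear_raises(self):
        case = make_case(
            A=np.array([2.0, 0.0, 0.0]),
            B=np.array([1.0, 0.0, 0.0]),
            C=np.array([0.0, 0.0, 0.0]),
        )
        with pytest.raises(InvalidGeometryError):
            build_triangle(case)

    def test_non_right_raises_with_angle(self):
        case = make_case(
            A=np.array([10.0, 0.0, 40.0]),
            B=np.array([30.0, 0.0, 0.0]),
            C=np.array([0.0, 0.0, 0.0]),
        )
        with pytest.raises(InvalidGeometryError, match=r"angle at C"):
            build_triangle(case)

    def test_fixture_passes(self, fixture_cohort):
        for case in fixture_cohort:
            build_triangle(case)


class TestMeasureD:
    def test_30_40_gives_20(self):
        case = make_case(
            A=np.array([0.0, 0.0, 40.0]),
            B=np.array([30.0, 0.0, 0.0]),
            C=np.array([0.0, 0.0, 0.0]),
        )
        d, O = measure_d(build_triangle(case))
        assert d == pytest.approx(20.0, abs=1e-12)
        np.testing.assert_allclose(O, [10, 0, 10], atol=1e-9)

    def test_O_equidistant_from_edges(self, fixture_cohort):
        for case in fixture_cohort[:5]:
            tri = build_triangle(case)
            d, O = measure_d(tri)
            for seg in (tri.exiting_root, tri.traversing_root, tri.pedicle_line):
                dist = point_line_distance(O, seg.p, seg.q - seg.p)
                assert dist == pytest.approx(d / 2.0, abs=1e-9)


class TestDiscCenter:
    def test_axis_aligned(self):
        corners = np.array(
            [[-20, -15, 0], [20, -15, 0], [20, 15, 0], [-20, 15, 0]], float
        )
        case = make_case(disc_corners=corners)
        np.testing.assert_allclose(locate_disc_center(case), [0, 0, 0], atol=1e-12)

    def test_translation_equivariance(self):
        corners = np.array(
            [[-20, -15, 0], [20, -15, 0], [20, 15, 0], [-20, 15, 0]], float
        ) + np.array([3.0, -7.0, 2.0])
        case = make_case(disc_corners=corners)
        np.testing.assert_allclose(locate_disc_center(case), [3, -7, 2], atol=1e-12)

    def test_corner_order_irrelevant(self, rng):
        corners = np.array(
            [[-20, -15, 0], [20, -15, 0], [20, 15, 0], [-20, 15, 0]], float
        )
        for _ in range(5):
            case = make_case(disc_corners=corners[rng.permutation(4)])
            np.testing.assert_allclose(locate_disc_center(case), [0, 0, 0], atol=1e-12)

    def test_non_rectangle_raises(self):
        corners = np.array([[0, 0, 0], [20, 0, 0], [25, 15, 0], [-5, 14, 0]], float)
        case = make_case(disc_corners=corners)
        with pytest.raises(InvalidGeometryError):
            locate_disc_center(case)

    def test_roundtrip_on_fixture(self, fixture_cohort):
        for case in fixture_cohort:
            np.testing.assert_allclose(locate_disc_center(case), [0, 0, 0], atol=1e-9)


class TestMeasureBeta:
    Z = np.array([0.0, 0.0, 1.0])

    def test_perpendicular(self):
        # O lateral of D, E posterior: OD along x, DE along y
        assert measure_beta([10, 0, 3], [0, 0, 0], [0, 40, 0], self.Z) == pytest.approx(
            90.0
        )

    def test_O_on_midline(self):
        assert measure_beta([0, -20, 5], [0, 0, 0], [0, 40, 0], self.Z) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_known_angle(self):
        b = math.radians(32.02)
        O = [30 * math.sin(b), 30 * math.cos(b), 6.0]
        assert measure_beta(O, [0, 0, 0], [0, 60, 0], self.Z) == pytest.approx(
            32.02, abs=1e-9
        )

    def test_degenerate_projection_raises(self):
        with pytest.raises(ProjectionDegenerateError):
            measure_beta([0, 0, 10], [0, 0, 0], [0, 40, 0], [0, 1, 0])


class TestPlanTrephine:
    def test_beta_zero_axis_is_midline(self):
        plan = plan_trephine([10, 0, 3], [0, 0, 0], [0, 60, 0], 0.0, 8.0, [0, 0, 1])
        np.testing.assert_allclose(plan.cylinder.axis.direction, [0, -1, 0], atol=1e-12)
        np.testing.assert_allclose(plan.cylinder.axis.origin, [10, 0, 3], atol=1e-12)
        assert plan.cylinder.radius == 4.0

    def test_abducted_axis_direction(self):
        b = math.radians(30.0)
        O = [30 * math.sin(b), 30 * math.cos(b), 6.0]
        plan = plan_trephine(O, [0, 0, 0], [0, 60, 0], 30.0, 8.0, [0, 0, 1])
        # posterior end swings laterally: axis is parallel to the projected OD line
        np.testing.assert_allclose(
            plan.cylinder.axis.direction,
            [-math.sin(b), -math.cos(b), 0.0],
            atol=1e-12,
        )

    def test_axis_through_offset_anchor(self):
        b = math.radians(30.0)
        O = np.array([30 * math.sin(b), 30 * math.cos(b), 6.0])
        plan = plan_trephine(
            O, [0, 0, 0], [0, 60, 0], 30.0, 8.0, [0, 0, 1], wire_offset=(2.0, -3.0)
        )
        e_lat = np.array([math.cos(b), -math.sin(b), 0.0])
        np.testing.assert_allclose(
            plan.cylinder.axis.origin, O + 2.0 * e_lat + np.array([0, 0, -3.0]),
            atol=1e-12,
        )

    def test_invalid_diameter(self):
        with pytest.raises(InvalidGeometryError):
            plan_trephine([10, 0, 3], [0, 0, 0], [0, 60, 0], 10.0, 0.0, [0, 0, 1])

    def test_side_undefined_for_midline_O(self):
        with pytest.raises(ProjectionDegenerateError):
            plan_trephine([0, -10, 3], [0, 0, 0], [0, 60, 0], 20.0, 8.0, [0, 0, 1])


class TestLocateJ:
    def test_perpendicular_axis_hits_patch_origin(self):
        patch = PlanePatch([0, 20, 0], [1, 0, 0], [0, 0, 1], (-10, 10), (-10, 10))
        plan = plan_trephine([0.001, 0, 0], [0, 0, 0], [0, 60, 0], 0.0, 8.0, [0, 0, 1])
        hit = locate_J(plan, patch)
        np.testing.assert_allclose(hit.point, [0.001, 20, 0], atol=1e-9)
        assert hit.in_patch

    def test_parallel_axis_raises(self):
        patch = PlanePatch([0, 20, 0], [0, 1, 0], [0, 0, 1], (-10, 10), (-10, 10))
        plan = plan_trephine([10, 0, 0], [0, 0, 0], [0, 60, 0], 0.0, 8.0, [0, 0, 1])
        with pytest.raises(NoIntersectionError):
            locate_J(plan, patch)

    def test_fixture_all_in_patch(self, fixture_measurements):
        assert all(m.j_in_patch for m in fixture_measurements)


class TestQuadrantGrid:
    def patch(self):
        return PlanePatch([0, 20, 0], [1, 0, 0], [0, 0, 1], (-10, 10), (-10, 10))

    def grid_case(self):
        patch = self.patch()
        return make_case(
            facet_patch=patch,
            facet_landmarks={
                "upper_vertex_L5": patch.from_uv(0, 10),
                "lower_edge_L4": patch.from_uv(0, -10),
                "lateral_edge_facet": patch.from_uv(10, 0),
                "lateral_edge_exiting_root": patch.from_uv(-10, 0),
            },
        )

    def test_borders_at_midlines(self):
        grid = build_quadrant_grid(self.grid_case())
        assert grid.u_border == pytest.approx(0.0, abs=1e-12)
        assert grid.v_border == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_landmarks_raise(self):
        patch = self.patch()
        case = make_case(
            facet_patch=patch,
            facet_landmarks={
                "upper_vertex_L5": patch.from_uv(0, 5),
                "lower_edge_L4": patch.from_uv(0, 5),
                "lateral_edge_facet": patch.from_uv(10, 0),
                "lateral_edge_exiting_root": patch.from_uv(-10, 0),
            },
        )
        with pytest.raises(InvalidGeometryError):
            build_quadrant_grid(case)

    def test_assignment_and_ties(self):
        grid = build_quadrant_grid(self.grid_case())
        patch = grid.patch
        assert assign_quadrant(patch.from_uv(3, 3), grid)[0] == "A"
        assert assign_quadrant(patch.from_uv(-3, 3), grid)[0] == "B"
        assert assign_quadrant(patch.from_uv(3, -3), grid)[0] == "C"
        assert assign_quadrant(patch.from_uv(-3, -3), grid)[0] == "D"
        # exactly on the crossing: half-open, upper-outer wins
        label, border = assign_quadrant(patch.from_uv(0, 0), grid)
        assert label == "A"
        assert border == pytest.approx(0.0, abs=1e-12)

    def test_boundary_distance(self):
        grid = build_quadrant_grid(self.grid_case())
        _, dist = assign_quadrant(grid.patch.from_uv(1.0, 4.0), grid)
        assert dist == pytest.approx(1.0)

    def test_out_of_plane_raises(self):
        grid = build_quadrant_grid(self.grid_case())
        with pytest.raises(InvalidGeometryError):
            assign_quadrant([0, 25, 0], grid)

    def test_rigid_invariance(self, rng, fixture_cohort):
        case = fixture_cohort[0]
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        moved = transform_case(case, R, t)
        m0 = measure_case(case)
        m1 = measure_case(moved)
        assert m0.quadrant == m1.quadrant
        assert m1.d == pytest.approx(m0.d, abs=1e-9)
        assert m1.beta == pytest.approx(m0.beta, abs=1e-6)
        assert m1.L1 == pytest.approx(m0.L1, abs=1e-9)
        assert m1.L2 == pytest.approx(m0.L2, abs=1e-9)


class TestClearances:
    def test_perpendicular_limit(self):
        d = 11.62
        case = invert_case(
            TargetQuadruple(d=d, beta=0.0, L1=d / 2 - 4, L2=d / 2 - 4),
            GeneratorConfig(seed=0),
        )
        tri = build_triangle(case)
        _, O = measure_d(tri)
        plan = plan_trephine(O, [0, 0, 0], [0, 60, 0], 0.0, 8.0, [0, 0, 1])
        L1, L2 = measure_clearances(plan, tri)
        assert L1 == pytest.approx(d / 2 - 4, abs=1e-9)
        assert L2 == pytest.approx(d / 2 - 4, abs=1e-9)

    def test_breach_arithmetic(self):
        d = 9.46
        case = invert_case(
            TargetQuadruple(d=d, beta=0.0, L1=d / 2 - 4, L2=d / 2 - 4),
            GeneratorConfig(seed=0),
        )
        tri = build_triangle(case)
        _, O = measure_d(tri)
        plan = plan_trephine(O, [0, 0, 0], [0, 60, 0], 0.0, 12.0, [0, 0, 1])
        L1, L2 = measure_clearances(plan, tri)
        assert L1 == pytest.approx(-1.27, abs=1e-9)
        assert L2 == pytest.approx(-1.27, abs=1e-9)

    def test_diameter_shift(self, fixture_cohort):
        case = fixture_cohort[0]
        m8 = measure_case(case, MeasurementConfig(trephine_diameter=8.0))
        m9 = measure_case(case, MeasurementConfig(trephine_diameter=9.0))
        assert m9.L1 == pytest.approx(m8.L1 - 0.5, abs=1e-12)
        assert m9.L2 == pytest.approx(m8.L2 - 0.5, abs=1e-12)


class TestMeasureCase:
    def test_full_record(self, fixture_cohort):
        m = measure_case(fixture_cohort[0])
        assert m.case_id == fixture_cohort[0].case_id
        assert m.quadrant in "ABCD"
        assert m.safe_L1 == (m.L1 >= 0)
        assert m.safe_L2 == (m.L2 >= 0)
        assert np.all(np.isfinite(m.O)) and np.all(np.isfinite(m.J))

    def test_determinism(self, fixture_cohort):
        a = measure_case(fixture_cohort[3])
        b = measure_case(fixture_cohort[3])
        assert (a.d, a.beta, a.L1, a.L2, a.quadrant) == (
            b.d, b.beta, b.L1, b.L2, b.quadrant
        )
        np.testing.assert_array_equal(a.J, b.J)
        np.testing.assert_array_equal(a.O, b.O)

    def test_mirror_symmetry(self, fixture_cohort):
        case = fixture_cohort[0]
        mirrored = mirror_case(case)
        m0 = measure_case(case)
        m1 = measure_case(mirrored)
        assert m1.d == pytest.approx(m0.d, abs=1e-12)
        assert m1.beta == pytest.approx(m0.beta, abs=1e-9)
        assert m1.L1 == pytest.approx(m0.L1, abs=1e-9)
        assert m1.L2 == pytest.approx(m0.L2, abs=1e-9)
        assert m1.quadrant == m0.quadrant
        assert m1.J[0] == pytest.approx(-m0.J[0], abs=1e-9)

    def test_error_carries_case_id(self):
        case = make_case(
            A=np.array([10.0, 0.0, 40.0]),
            B=np.array([30.0, 0.0, 0.0]),
            C=np.array([0.0, 0.0, 0.0]),
        )
        with pytest.raises(MeasurementError, match="T1"):
            measure_case(case)


class TestSweep:
    def test_monotone_L1(self, fixture_cohort):
        rows = sweep_beta(fixture_cohort[0], np.arange(0.0, 61.0, 1.0))
        L1 = rows[:, 1]
        assert np.all(np.diff(L1) <= 1e-12)

    def test_beta_column(self, fixture_cohort):
        rows = sweep_beta(fixture_cohort[0], [0.0, 10.0, 20.0])
        np.testing.assert_allclose(rows[:, 0], [0, 10, 20])
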