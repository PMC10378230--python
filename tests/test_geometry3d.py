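"""Unit and property tests for the 3-D geometric primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from neutraltrack.errors import (
    BranchAmbiguityError,
    DegenerateGeometryError,
    NoIntersectionError,
)
from neutraltrack.geometry3d import (
    Circle3,
    Plane,
    Sphere,
    dihedral_angle,
    oriented_trace_angle,
    plane_from_points,
    plane_parallel_through,
    plane_perpendicular_through_chord,
    plane_trace_on_plane,
    point_on_circle_at_angle,
    segment_plane_intersection,
    signed_distance,
    sphere_plane_intersection,
    unit_vector,
)

XY = Plane(anchor=(0, 0, 0), normal=(0, 0, 1))
XZ = Plane(anchor=(0, 0, 0), normal=(0, 1, 0))
YZ = Plane(anchor=(0, 0, 0), normal=(1, 0, 0))


class TestPlaneFromPoints:
    def test_canonical_xy_plane(self):
        p = plane_from_points((0, 0, 0), (1, 0, 0), (0, 1, 0))
        assert np.allclose(p.anchor, 0)
        assert np.allclose(p.normal, (0, 0, 1))

    def test_orientation_follows_right_hand_rule(self):
        p = plane_from_points((0, 0, 0), (0, 1, 0), (0, 0, 1))
        assert np.allclose(p.normal, (1, 0, 0))

    @pytest.mark.parametrize("pts", [
        [(0, 0, 0), (1, 1, 1), (2, 2, 2)],        # collinear
        [(1, 2, 3), (1, 2, 3), (4, 5, 6)],        # coincident
    ])
    def test_degenerate_inputs_raise(self, pts):
        with pytest.raises(DegenerateGeometryError):
            plane_from_points(*pts)

    def test_generators_lie_on_plane(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pts = rng.uniform(-100, 100, (3, 3))
            try:
                plane = plane_from_points(*pts)
            except DegenerateGeometryError:
                continue
            for p in pts:
                assert abs(signed_distance(p, plane)) < 1e-9


class TestParallelAndPerpendicular:
    def test_parallel_through_point(self):
        p = plane_parallel_through(XY, (0, 0, 5))
        assert abs(signed_distance((0, 0, 5), p)) < 1e-12
        assert np.allclose(p.normal, XY.normal)

    def test_parallel_through_point_on_ref_is_identity(self):
        p = plane_parallel_through(XY, (3, -2, 0))
        assert abs(signed_distance((10, 10, 0), p)) < 1e-12

    def test_parallel_through_tilted_pm_normal(self):
        ref = Plane(anchor=(0, 0, 0), normal=(0, -0.99654, -0.08304))
        target = np.array([0, 28.17, 39.44])
        p = plane_parallel_through(ref, target)
        assert abs(signed_distance(target, p)) < 1e-12
        assert dihedral_angle(p, ref) < 1e-12

    def test_perpendicular_through_chord(self):
        p = plane_perpendicular_through_chord(XY, (-10, 0, -5), (10, 0, -5))
        assert abs(abs(dihedral_angle(p, XY)) - 90) < 1e-9
        for q in ((-10, 0, -5), (10, 0, -5)):
            assert abs(signed_distance(q, p)) < 1e-9

    def test_perpendicular_chord_normal_direction(self):
        p = plane_perpendicular_through_chord(XY, (0, 0, 0), (1, 1, 0))
        expected = unit_vector(np.cross((0, 0, 1), (1, 1, 0)))
        assert np.allclose(np.abs(p.normal), np.abs(expected))
        assert abs(dihedral_angle(p, XY) - 90) < 1e-9

    def test_chord_along_normal_raises(self):
        with pytest.raises(DegenerateGeometryError):
            plane_perpendicular_through_chord(XY, (0, 0, 0), (0, 0, 5))


class TestDihedralAngle:
    def test_orthogonal_planes(self):
        assert abs(dihedral_angle(XY, XZ) - 90) < 1e-12

    def test_identical_planes_zero(self):
        assert dihedral_angle(XY, XY) == 0.0

    def test_constructed_403(self):
        a = np.radians(40.3)
        b = Plane(anchor=(0, 0, 0), normal=(0, np.sin(a), np.cos(a)))
        assert abs(dihedral_angle(XY, b) - 40.3) < 1e-9

    def test_reflection_supplement(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n1 = unit_vector(rng.standard_normal(3))
            n2 = unit_vector(rng.standard_normal(3))
            a = Plane(anchor=rng.uniform(-10, 10, 3), normal=n1)
            b = Plane(anchor=rng.uniform(-10, 10, 3), normal=n2)
            # reflect b's normal through a's plane
            n2r = n2 - 2 * np.dot(n2, n1) * n1
            br = Plane(anchor=b.anchor, normal=n2r)
            if dihedral_angle(a, b) < 1e-6 or dihedral_angle(a, b) > 180 - 1e-6:
                continue
            assert abs(dihedral_angle(a, b) + dihedral_angle(a, br) - 180) < 1e-6


class TestTraces:
    def test_trace_of_xz_on_yz(self):
        line = plane_trace_on_plane(XZ, YZ)
        assert abs(np.abs(line.direction[2]) - 1) < 1e-12
        assert abs(signed_distance(line.point, XZ)) < 1e-9
        assert abs(signed_distance(line.point, YZ)) < 1e-9

    def test_parallel_planes_raise(self):
        other = Plane(anchor=(0, 0, 5), normal=(0, 0, 1))
        with pytest.raises(DegenerateGeometryError):
            plane_trace_on_plane(XY, other)

    def test_mcf_trace_contains_expected_points(self):
        mcf = plane_from_points((25, 45, 18), (-25, 45, 18), (0, 0, 0))
        line = plane_trace_on_plane(mcf, YZ)
        for q in ((0, 45, 18), (0, 0, 0)):
            rel = np.asarray(q) - line.point
            perp = rel - np.dot(rel, line.direction) * line.direction
            assert np.linalg.norm(perp) < 1e-9

    def test_oriented_trace_angle_orthogonal(self):
        a = plane_from_points((10, 50, 0), (-10, 50, 0), (0, 0, 0))
        b = plane_from_points((10, 50, 0), (-10, 50, 0), (0, 50, -20))
        angle = oriented_trace_angle(a, b, YZ, (0, -1, 0), (0, 0, -1))
        assert abs(angle - 90) < 1e-9

    def test_oriented_trace_angle_self_zero(self):
        a = plane_from_points((10, 50, 0), (-10, 50, 0), (0, 0, 0))
        assert oriented_trace_angle(a, a, YZ, (0, -1, 0), (0, -1, 0)) < 1e-12

    def test_orientation_hint_flips_to_supplement(self):
        a = plane_from_points((10, 50, 0), (-10, 50, 0), (0, 0, 0))
        b = plane_from_points((10, 50, 0), (-10, 50, 0), (0, 50, -20))
        one = oriented_trace_angle(a, b, YZ, (0, -1, 0), (0, 0, -1))
        other = oriented_trace_angle(a, b, YZ, (0, 1, 0), (0, 0, -1))
        assert abs(one + other - 180) < 1e-9


class TestSignedDistanceAndSegments:
    @pytest.mark.parametrize("p,expected", [
        ((0, 0, 5), 5.0), ((3, -7, 0), 0.0), ((0, 0, -5), -5.0),
    ])
    def test_signed_distance_sign_convention(self, p, expected):
        assert signed_distance(p, XY) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_chord_intersection(self):
        p = segment_plane_intersection((-25, 45, 18), (25, 45, 18), YZ)
        assert np.allclose(p, (0, 45, 18))

    def test_same_side_raises(self):
        with pytest.raises(NoIntersectionError):
            segment_plane_intersection((1, 0, 0), (2, 0, 0), YZ)

    def test_linear_interpolation(self):
        p = segment_plane_intersection((-1, 0, 0), (3, 0, 0), YZ)
        assert np.allclose(p, (0, 0, 0))

    def test_segment_in_plane_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            segment_plane_intersection((0, 1, 0), (0, 2, 0), YZ)


class TestSphereCircle:
    def test_great_circle(self):
        c = sphere_plane_intersection(Sphere(center=(0, 0, 0), radius=10), XY)
        assert np.allclose(c.center, 0)
        assert c.radius == pytest.approx(10)

    def test_small_circle_6_8_10(self):
        plane = Plane(anchor=(0, 0, 6), normal=(0, 0, 1))
        c = sphere_plane_intersection(Sphere(center=(0, 0, 0), radius=10), plane)
        assert np.allclose(c.center, (0, 0, 6))
        assert c.radius == pytest.approx(8)

    def test_missing_plane_raises(self):
        plane = Plane(anchor=(0, 0, 11), normal=(0, 0, 1))
        with pytest.raises(NoIntersectionError):
            sphere_plane_intersection(Sphere(center=(0, 0, 0), radius=10), plane)


class TestPointOnCircleAtAngle:
    circle = Circle3(center=(0, 0, 0), radius=70, plane_normal=(1, 0, 0))

    def test_anterior_superior_branch(self):
        p = point_on_circle_at_angle(self.circle, XY, 40.3, branch=(0, 1, 1))
        a = np.radians(40.3)
        assert np.allclose(p, (0, 70 * np.cos(a), 70 * np.sin(a)), atol=1e-9)

    def test_zero_angle_limit(self):
        p = point_on_circle_at_angle(self.circle, XY, 0.0, branch=(0, 1, 0))
        assert np.allclose(p, (0, 70, 0), atol=1e-9)

    def test_ninety_degrees_boundary(self):
        p = point_on_circle_at_angle(self.circle, XY, 90.0, branch=(0, 0, 1))
        assert np.allclose(p, (0, 0, 70), atol=1e-9)

    def test_brute_force_oracle(self):
        """Dense circle sampling oracle: best of 1e6 uniformly spaced points."""
        phi = np.linspace(0, 2 * np.pi, 1_000_000, endpoint=False)
        pts = 70 * (np.outer(np.cos(phi), [0, 1, 0]) + np.outer(np.sin(phi), [0, 0, 1]))
        # angle of each center ray to the reference trace (the y axis)
        ang = np.degrees(np.arctan2(np.abs(pts[:, 2]), np.abs(pts[:, 1])))
        quadrant = (pts[:, 1] > 0) & (pts[:, 2] > 0)
        cand = pts[quadrant]
        best = cand[np.argmin(np.abs(ang[quadrant] - 40.3))]
        p = point_on_circle_at_angle(self.circle, XY, 40.3, branch=(0, 1, 1))
        assert np.linalg.norm(p - best) < 0.01

    def test_ambiguous_branch_raises(self):
        # hint along the reference trace cannot separate +z from -z candidates
        with pytest.raises(BranchAmbiguityError):
            point_on_circle_at_angle(self.circle, XY, 40.3, branch=(0, 1, 0))

    def test_center_off_reference_plane_raises(self):
        shifted = Plane(anchor=(0, 0, 5), normal=(0, 0, 1))
        with pytest.raises(DegenerateGeometryError):
            point_on_circle_at_angle(self.circle, shifted, 40.3, branch=(0, 1, 1))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(seed=st.integers(0, 10**6))
def test_angles_invariant_under_rigid_motion_and_scaling(seed):
    """Every angle-returning operation is invariant under rigid motion + scaling."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-80, 80, (6, 3))
    try:
        a = plane_from_points(*pts[:3])
        b = plane_from_points(*pts[3:])
        base = dihedral_angle(a, b)
    except DegenerateGeometryError:
        return
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50, 50, 3)
    s = float(rng.uniform(0.2, 5.0))
    moved = (s * (pts @ R.T)) + t
    a2 = plane_from_points(*moved[:3])
    b2 = plane_from_points(*moved[3:])
    assert abs(dihedral_angle(a2, b2) - base) < 1e-6
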