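"""Coordinate-free 3-D geometric primitives for cephalometric track construction.

Everything downstream — the individual track, the neutral track, the plane
exports — is assembled from the handful of constructions in this module:
planes through three points, parallel and perpendicular planes, sphere/plane
intersections and points picked on circles at a prescribed angle.

Conventions
-----------
* Internal frame is RAS-like: x = subject's right, y = anterior, z = superior,
  units millimetres.  File readers convert external conventions at the boundary.
* Planes are stored as an anchor point plus a unit normal.  Normal orientation
  follows the right-hand rule on the argument order; every angle-returning
  operation is either orientation-insensitive or takes explicit orientation
  hints, so callers never depend on normal signs.
* Angles are degrees on the public surface, radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BranchAmbiguityError, DegenerateGeometryError, NoIntersectionError

#: Geometric degeneracy tolerance (mm or mm^2 depending on context).
TOL_DEGENERATE = 1e-9

__all__ = [
    "TOL_DEGENERATE",
    "Plane",
    "Sphere",
    "Circle3",
    "Line3",
    "as_point3",
    "unit_vector",
    "midpoint",
    "plane_from_points",
    "plane_parallel_through",
    "plane_perpendicular_through_chord",
    "dihedral_angle",
    "plane_trace_on_plane",
    "oriented_trace_angle",
    "signed_distance",
    "segment_plane_intersection",
    "sphere_plane_intersection",
    "point_on_circle_at_angle",
]


def as_point3(p) -> np.ndarray:
    """Coerce ``p`` to a finite float64 array of shape (3,)."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite coordinates: {a}")
    return a


def unit_vector(v) -> np.ndarray:
    """Normalize ``v`` to unit Euclidean length.

    Raises
    ------
    DegenerateGeometryError
        If the norm is below :data:`TOL_DEGENERATE`.
    """
    a = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(a))
    if n < TOL_DEGENERATE:
        raise DegenerateGeometryError(f"cannot normalize near-zero vector {a}")
    return a / n


def midpoint(a, b) -> np.ndarray:
    """Exact midpoint of two points."""
    return 0.5 * (as_point3(a) + as_point3(b))


@dataclass(frozen=True, eq=False)
class Plane:
    """Oriented plane: anchor point + unit normal."""

    anchor: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "anchor", as_point3(self.anchor))
        object.__setattr__(self, "normal", unit_vector(self.normal))

    def contains(self, p, tol: float = TOL_DEGENERATE) -> bool:
        """Membership test ``|(p - anchor) . normal| <= tol``."""
        return abs(signed_distance(p, self)) <= tol


@dataclass(frozen=True, eq=False)
class Sphere:
    """Sphere with center (mm) and radius (mm > 0)."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", as_point3(self.center))
        if not (self.radius > 0):
            raise DegenerateGeometryError(f"sphere radius must be > 0, got {self.radius}")


@dataclass(frozen=True, eq=False)
class Circle3:
    """Circle embedded in 3-space: center, radius and supporting-plane normal."""

    center: np.ndarray
    radius: float
    plane_normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "center", as_point3(self.center))
        object.__setattr__(self, "plane_normal", unit_vector(self.plane_normal))
        if not (self.radius > 0):
            raise DegenerateGeometryError(f"circle radius must be > 0, got {self.radius}")


@dataclass(frozen=True, eq=False)
class Line3:
    """Infinite line: point + unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", as_point3(self.point))
        object.__setattr__(self, "direction", unit_vector(self.direction))


def _stable_angle_deg(u, v) -> float:
    """Angle between two vectors in [0, 180] deg via atan2(|u x v|, u . v)."""
    cross = np.linalg.norm(np.cross(u, v))
    dot = float(np.dot(u, v))
    return float(np.degrees(np.arctan2(cross, dot)))


def plane_from_points(p1, p2, p3) -> Plane:
    """Plane through three non-collinear points.

    The normal follows the right-hand rule on ``(p2 - p1, p3 - p1)``.

    Raises
    ------
    DegenerateGeometryError
        If the triangle spanned by the points has area below
        :data:`TOL_DEGENERATE` mm^2 (collinear or coincident points).
    """
    p1, p2, p3 = as_point3(p1), as_point3(p2), as_point3(p3)
    cross = np.cross(p2 - p1, p3 - p1)
    area = 0.5 * float(np.linalg.norm(cross))
    if area < TOL_DEGENERATE:
        raise DegenerateGeometryError(
            f"points are collinear or coincident (triangle area {area:.3e} mm^2)"
        )
    return Plane(anchor=p1, normal=cross)


def plane_parallel_through(ref: Plane, p) -> Plane:
    """Plane through ``p`` parallel to ``ref`` (same normal, same sign)."""
    return Plane(anchor=as_point3(p), normal=ref.normal.copy())


def plane_perpendicular_through_chord(ref: Plane, a, b) -> Plane:
    """Plane containing the chord ``a -> b`` and perpendicular to ``ref``.

    The normal is proportional to ``ref.normal x (b - a)``.

    Raises
    ------
    DegenerateGeometryError
        If the chord is (near-)parallel to ``ref``'s normal, or ``a == b``.
    """
    a, b = as_point3(a), as_point3(b)
    cross = np.cross(ref.normal, b - a)
    if np.linalg.norm(cross) < TOL_DEGENERATE:
        raise DegenerateGeometryError(
            "chord is parallel to the reference normal (or endpoints coincide)"
        )
    return Plane(anchor=a, normal=cross)


def dihedral_angle(a: Plane, b: Plane) -> float:
    """Angle between two planes in degrees, via their oriented normals.

    Returns the angle of the oriented normals in ``[0, 180]``; symmetric in
    its arguments.  Identically-oriented parallel planes give 0, opposed
    normals give 180.  Computed as ``atan2(|n_a x n_b|, n_a . n_b)``, which
    is stable near 0 and 180 where the arccos form amplifies rounding noise.
    """
    return _stable_angle_deg(a.normal, b.normal)


def plane_trace_on_plane(p: Plane, section: Plane) -> Line3:
    """Intersection line (trace) of plane ``p`` on the ``section`` plane.

    The direction is proportional to ``p.normal x section.normal``.

    Raises
    ------
    DegenerateGeometryError
        If the planes are parallel.
    """
    d = np.cross(p.normal, section.normal)
    if np.linalg.norm(d) < TOL_DEGENERATE:
        raise DegenerateGeometryError("planes are parallel; no unique trace")
    n1, n2 = p.normal, section.normal
    c1 = float(np.dot(n1, p.anchor))
    c2 = float(np.dot(n2, section.anchor))
    dot = float(np.dot(n1, n2))
    denom = 1.0 - dot * dot
    point = ((c1 - c2 * dot) * n1 + (c2 - c1 * dot) * n2) / denom
    return Line3(point=point, direction=d)


def _oriented_trace_direction(p: Plane, section: Plane, orient_hint) -> np.ndarray:
    trace = plane_trace_on_plane(p, section)
    hint = unit_vector(orient_hint)
    d = float(np.dot(trace.direction, hint))
    if abs(d) < TOL_DEGENERATE:
        raise DegenerateGeometryError(
            "orientation hint is perpendicular to the trace direction"
        )
    return trace.direction if d > 0 else -trace.direction


def oriented_trace_angle(a: Plane, b: Plane, section: Plane, orient_a, orient_b) -> float:
    """Angle (degrees) between the traces of ``a`` and ``b`` on ``section``.

    Each trace direction is flipped, if necessary, to have a positive dot
    product with its orientation hint; the returned value is the angle in
    ``[0, 180]`` between the two oriented directions.  When every defining
    landmark lies in ``section`` this reduces exactly to the planar vertex
    angle used on lateral cephalograms.
    """
    da = _oriented_trace_direction(a, section, orient_a)
    db = _oriented_trace_direction(b, section, orient_b)
    return _stable_angle_deg(da, db)


def signed_distance(p, plane: Plane) -> float:
    """Signed distance ``(p - anchor) . normal`` in mm."""
    return float(np.dot(as_point3(p) - plane.anchor, plane.normal))


def segment_plane_intersection(a, b, plane: Plane) -> np.ndarray:
    """Intersection point of segment ``a -> b`` with ``plane``.

    Raises
    ------
    NoIntersectionError
        If both endpoints lie strictly on the same side.
    DegenerateGeometryError
        If the segment lies (numerically) within the plane.
    """
    a, b = as_point3(a), as_point3(b)
    da, db = signed_distance(a, plane), signed_distance(b, plane)
    if abs(da) <= TOL_DEGENERATE and abs(db) <= TOL_DEGENERATE:
        raise DegenerateGeometryError("segment lies in the plane; intersection not unique")
    if da * db > 0:
        raise NoIntersectionError(
            f"segment endpoints on the same side of the plane (d={da:.3g}, {db:.3g})"
        )
    t = da / (da - db)
    return a + t * (b - a)


def sphere_plane_intersection(s: Sphere, plane: Plane) -> Circle3:
    """Circle in which ``plane`` cuts ``s``.

    The circle center is the orthogonal projection of the sphere center onto
    the plane; the radius is ``sqrt(r^2 - d^2)``.  Tangency counts as no
    intersection.

    Raises
    ------
    NoIntersectionError
        If ``|d| >= r``.
    """
    d = signed_distance(s.center, plane)
    if abs(d) >= s.radius:
        raise NoIntersectionError(
            f"plane at distance {abs(d):.3g} mm misses sphere of radius {s.radius:.3g} mm"
        )
    center = s.center - d * plane.normal
    radius = float(np.sqrt(s.radius**2 - d**2))
    return Circle3(center=center, radius=radius, plane_normal=plane.normal)


def point_on_circle_at_angle(c: Circle3, ref: Plane, angle: float, branch) -> np.ndarray:
    """Point on circle ``c`` whose center ray makes ``angle`` with ``ref``'s trace.

    The construction happens inside the circle's supporting plane (the
    "section view"): the reference plane's trace on that plane is taken as the
    zero-angle line, and the returned point ``P`` satisfies that the ray
    ``center -> P`` makes ``angle`` degrees with that trace line.  Up to four
    candidates exist (two per trace orientation); ``branch`` is a direction
    hint and the candidate maximizing ``(P - center) . branch`` is chosen.

    Parameters
    ----------
    c : Circle3
    ref : Plane
        Must pass through the circle center (within tolerance).
    angle : float
        Degrees in ``[0, 90]``.
    branch : array-like
        3-vector hint selecting the anatomical quadrant.

    Raises
    ------
    DegenerateGeometryError
        If ``ref`` does not pass through the circle center, is parallel to the
        circle plane, or ``angle`` is out of range.
    BranchAmbiguityError
        If the hint does not isolate a single best candidate.
    """
    if not (0.0 <= angle <= 90.0):
        raise DegenerateGeometryError(f"angle must be in [0, 90] degrees, got {angle}")
    if abs(signed_distance(c.center, ref)) > 1e-6:
        raise DegenerateGeometryError("reference plane does not pass through circle center")
    # Trace of the reference plane on the circle's plane, and the in-plane
    # perpendicular: the working 2-D frame of the section view.
    cross = np.cross(ref.normal, c.plane_normal)
    if np.linalg.norm(cross) < TOL_DEGENERATE:
        raise DegenerateGeometryError("reference plane is parallel to the circle plane")
    t = unit_vector(cross)
    m = unit_vector(np.cross(c.plane_normal, t))
    theta = np.radians(angle)
    ct, st = np.cos(theta), np.sin(theta)
    offsets = [
        ct * t + st * m,
        ct * t - st * m,
        -ct * t + st * m,
        -ct * t - st * m,
    ]
    candidates = [c.center + c.radius * o for o in offsets]
    hint = unit_vector(branch)
    scores = np.array([np.dot(p - c.center, hint) for p in candidates])
    order = np.argsort(scores)[::-1]
    best, second = candidates[order[0]], candidates[order[1]]
    # Coincident candidates (e.g. angle = 90) are not ambiguous.
    if scores[order[0]] - scores[order[1]] < TOL_DEGENERATE * c.radius and (
        np.linalg.norm(best - second) > TOL_DEGENERATE * c.radius
    ):
        raise BranchAmbiguityError(
            "branch hint does not isolate a single candidate point on the circle"
        )
    return candidates[order[0]]
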