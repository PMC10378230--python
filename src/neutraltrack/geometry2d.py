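"""Planar geometry for the lateral-cephalogram (2-D) analysis.

2-D frame: x = +anterior, y = +superior (the subject faces +x), which is the
sagittal section of the 3-D frame with (y, z) -> (x, y).  All "lines" are
infinite lines through two landmarks; segments are never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BranchAmbiguityError, DegenerateGeometryError
from .geometry3d import TOL_DEGENERATE

__all__ = [
    "Line2",
    "Circle2",
    "as_point2",
    "unit_vector_2d",
    "perp_2d",
    "line_through",
    "parallel_line_through",
    "perpendicular_line_through",
    "angle_at_vertex",
    "angle_between_lines",
    "circle_point_at_angle_2d",
    "distance_point_line_2d",
]

#: Default anterior branch hint for circle constructions.
ANTERIOR_2D = np.array([1.0, 0.0])


def as_point2(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"expected a 2-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite coordinates: {a}")
    return a


def unit_vector_2d(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(a))
    if n < TOL_DEGENERATE:
        raise DegenerateGeometryError(f"cannot normalize near-zero vector {a}")
    return a / n


def perp_2d(v) -> np.ndarray:
    """Counter-clockwise perpendicular of a 2-vector."""
    a = np.asarray(v, dtype=float)
    return np.array([-a[1], a[0]])


@dataclass(frozen=True, eq=False)
class Line2:
    """Infinite line: point + unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", as_point2(self.point))
        object.__setattr__(self, "direction", unit_vector_2d(self.direction))


@dataclass(frozen=True, eq=False)
class Circle2:
    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", as_point2(self.center))
        if not (self.radius > 0):
            raise DegenerateGeometryError(f"circle radius must be > 0, got {self.radius}")


def line_through(p, q) -> Line2:
    """Infinite line through two distinct points, directed p -> q."""
    p, q = as_point2(p), as_point2(q)
    return Line2(point=p, direction=q - p)


def parallel_line_through(line: Line2, p) -> Line2:
    return Line2(point=as_point2(p), direction=line.direction.copy())


def perpendicular_line_through(line: Line2, p) -> Line2:
    return Line2(point=as_point2(p), direction=perp_2d(line.direction))


def angle_at_vertex(a, v, b) -> float:
    """Angle in degrees at vertex ``v`` between rays ``v->a`` and ``v->b``.

    Value in [0, 180].  Degenerate if either ray endpoint coincides with the
    vertex.
    """
    a, v, b = as_point2(a), as_point2(v), as_point2(b)
    u1 = unit_vector_2d(a - v)
    u2 = unit_vector_2d(b - v)
    return _stable_angle_2d(u1, u2)


def _stable_angle_2d(u1, u2) -> float:
    """Angle between 2-vectors in [0, 180] deg via atan2(|cross|, dot)."""
    cross = abs(float(u1[0] * u2[1] - u1[1] * u2[0]))
    dot = float(np.dot(u1, u2))
    return float(np.degrees(np.arctan2(cross, dot)))


def angle_between_lines(l1: Line2, l2: Line2) -> float:
    """Unoriented angle between two infinite lines, in [0, 90] degrees."""
    a = _stable_angle_2d(l1.direction, l2.direction)
    return min(a, 180.0 - a)


def circle_point_at_angle_2d(center, radius, ref_dir, angle, branch=ANTERIOR_2D) -> np.ndarray:
    """Point at distance ``radius`` from ``center`` whose center ray makes
    ``angle`` degrees with ``ref_dir``.

    Of the two solutions (rotations of ``ref_dir`` by +/- angle), the one
    maximizing the dot product with the ``branch`` hint is returned.

    Raises
    ------
    DegenerateGeometryError
        If ``radius <= 0`` or ``angle`` outside (0, 180) (boundaries allowed).
    BranchAmbiguityError
        If the hint scores both candidates equally while they differ.
    """
    center = as_point2(center)
    if not (radius > 0):
        raise DegenerateGeometryError(f"radius must be > 0, got {radius}")
    if not (0.0 <= angle <= 180.0):
        raise DegenerateGeometryError(f"angle must be in [0, 180] degrees, got {angle}")
    u = unit_vector_2d(ref_dir)
    theta = np.radians(angle)
    ct, st = np.cos(theta), np.sin(theta)
    rot_plus = np.array([ct * u[0] - st * u[1], st * u[0] + ct * u[1]])
    rot_minus = np.array([ct * u[0] + st * u[1], -st * u[0] + ct * u[1]])
    candidates = [center + radius * rot_plus, center + radius * rot_minus]
    hint = unit_vector_2d(branch)
    scores = [float(np.dot(p - center, hint)) for p in candidates]
    i = int(np.argmax(scores))
    j = 1 - i
    if abs(scores[i] - scores[j]) < TOL_DEGENERATE * radius and (
        np.linalg.norm(candidates[i] - candidates[j]) > TOL_DEGENERATE * radius
    ):
        raise BranchAmbiguityError("branch hint does not separate the two circle points")
    return candidates[i]


def distance_point_line_2d(p, l: Line2) -> float:
    """Unsigned perpendicular distance from point to infinite line, in mm."""
    p = as_point2(p)
    return abs(float(np.dot(p - l.point, perp_2d(l.direction))))
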