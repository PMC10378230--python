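"""The subject's individual track: four structural planes (3-D) or lines (2-D)
and the two diagnostic angles measured between them.

3-D planes (each through three landmarks):

* MCF — middle cranial floor: rMCF, lMCF, Ba
* PM  — pterygo-mandibular plane: rMCF, lMCF, PNS
* MR  — mandibular ramus: mCo, rGo, lGo
* FOP — functional occlusal plane: rPoc, lPoc, mAoc

2-D lines (lateral cephalogram): MCF = SE—Ar, PM = SE—Ptm, MR = Ar—Go,
FOP = Poc—Aoc.

The diagnostic angles are MCF^PM (anterior cranial-base angle, vertex SE in
2-D) and MCF^MR (posterior angle, vertex Ar in 2-D, obtuse in typical
anatomy).  In 3-D they are measured either between sagittal traces of the
planes (default, directly comparable to the 2-D vertex angles) or as
dihedral angles between plane normals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DegenerateGeometryError
from .geometry2d import Line2, angle_at_vertex, line_through
from .geometry3d import (
    Plane,
    dihedral_angle,
    midpoint,
    oriented_trace_angle,
    plane_from_points,
    unit_vector,
)
from .landmarks_io import LandmarkSet2D, LandmarkSet3D

__all__ = [
    "IndividualTrack3D",
    "IndividualTrack2D",
    "AngleSet",
    "midsagittal_plane",
    "build_individual_track_3d",
    "build_individual_track_2d",
    "measure_angles_3d",
    "measure_angles_2d",
]


@dataclass(eq=False)
class AngleSet:
    """The two diagnostic track angles, degrees."""

    mcf_pm: float
    mcf_mr: float

    def as_dict(self) -> dict[str, float]:
        return {"MCF^PM": self.mcf_pm, "MCF^MR": self.mcf_mr}


@dataclass(eq=False)
class IndividualTrack3D:
    MCF: Plane
    PM: Plane
    MR: Plane
    FOP: Plane
    midsagittal: Plane
    landmarks: LandmarkSet3D

    def planes(self) -> dict[str, Plane]:
        return {"MCF": self.MCF, "PM": self.PM, "MR": self.MR, "FOP": self.FOP}


@dataclass(eq=False)
class IndividualTrack2D:
    MCF: Line2
    PM: Line2
    MR: Line2
    FOP: Line2
    landmarks: LandmarkSet2D

    def lines(self) -> dict[str, Line2]:
        return {"MCF": self.MCF, "PM": self.PM, "MR": self.MR, "FOP": self.FOP}


def midsagittal_plane(lm: LandmarkSet3D) -> Plane:
    """Estimate the mid-sagittal plane through Ba from the bilateral pairs.

    The normal is the normalized sum of the unit left-to-right vectors of the
    MCF, condylion and gonion pairs; the plane is anchored at Ba.  The sign of
    the normal is irrelevant downstream.
    """
    total = np.zeros(3)
    for r, l in (("rMCF", "lMCF"), ("rCo", "lCo"), ("rGo", "lGo")):
        total += unit_vector(lm[r] - lm[l])
    if np.linalg.norm(total) < 1e-9:
        raise DegenerateGeometryError("bilateral pair directions cancel; cannot estimate "
                                      "a mid-sagittal plane")
    return Plane(anchor=lm.Ba, normal=total)


def build_individual_track_3d(lm: LandmarkSet3D) -> IndividualTrack3D:
    """Construct the four individual-track planes plus the mid-sagittal section.

    Raises a degenerate-geometry error naming the failing plane when any
    defining landmark triple is collinear.
    """
    triples = {
        "MCF": (lm.rMCF, lm.lMCF, lm.Ba),
        "PM": (lm.rMCF, lm.lMCF, lm.PNS),
        "MR": (lm.mCo, lm.rGo, lm.lGo),
        "FOP": (lm.rPoc, lm.lPoc, lm.mAoc),
    }
    planes = {}
    for name, (p1, p2, p3) in triples.items():
        try:
            planes[name] = plane_from_points(p1, p2, p3)
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(f"{name} plane degenerate: {exc}") from exc
    return IndividualTrack3D(**planes, midsagittal=midsagittal_plane(lm), landmarks=lm)


def build_individual_track_2d(lm: LandmarkSet2D) -> IndividualTrack2D:
    pairs = {
        "MCF": (lm.SE, lm.Ar),
        "PM": (lm.SE, lm.Ptm),
        "MR": (lm.Ar, lm.Go),
        "FOP": (lm.Poc, lm.Aoc),
    }
    lines = {}
    for name, (p, q) in pairs.items():
        try:
            lines[name] = line_through(p, q)
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(f"{name} line degenerate: {exc}") from exc
    return IndividualTrack2D(**lines, landmarks=lm)


def measure_angles_3d(track: IndividualTrack3D,
                      convention: Literal["trace", "dihedral"] = "trace") -> AngleSet:
    """Measure MCF^PM and MCF^MR on a built 3-D track.

    ``trace`` (default) measures between the planes' traces on the
    mid-sagittal section with anatomical orientations chosen to match the 2-D
    vertex angles: MCF^PM orients the cranial-base trace toward Ba and the PM
    trace toward PNS (vertex at the shared rMCF-lMCF chord); MCF^MR orients
    the cranial-base trace away from Ba (toward the cranial end, as the 2-D
    ray Ar->SE does) and the ramus trace from the condylar level toward the
    gonial level, yielding the obtuse posterior angle of typical anatomy.

    ``dihedral`` measures between the plane normals as oriented by the
    construction order.
    """
    lm = track.landmarks
    if convention == "dihedral":
        return AngleSet(
            mcf_pm=dihedral_angle(track.MCF, track.PM),
            mcf_mr=dihedral_angle(track.MCF, track.MR),
        )
    if convention != "trace":
        raise ValueError(f"unknown angle convention {convention!r}")
    section = track.midsagittal
    mid_mcf = midpoint(lm.rMCF, lm.lMCF)
    m_go = midpoint(lm.rGo, lm.lGo)
    mcf_pm = oriented_trace_angle(
        track.MCF, track.PM, section,
        orient_a=lm.Ba - mid_mcf,       # cranial end -> Ba
        orient_b=lm.PNS - mid_mcf,      # toward PNS
    )
    mcf_mr = oriented_trace_angle(
        track.MCF, track.MR, section,
        orient_a=mid_mcf - lm.Ba,       # Ba -> cranial end
        orient_b=m_go - lm.mCo,         # condylar level -> gonial level
    )
    return AngleSet(mcf_pm=mcf_pm, mcf_mr=mcf_mr)


def measure_angles_2d(track: IndividualTrack2D) -> AngleSet:
    """Vertex angles of the 2-D track: MCF^PM at SE (rays to Ar and Ptm),
    MCF^MR at Ar (rays to SE and Go)."""
    lm = track.landmarks
    return AngleSet(
        mcf_pm=angle_at_vertex(lm.Ar, lm.SE, lm.Ptm),
        mcf_mr=angle_at_vertex(lm.SE, lm.Ar, lm.Go),
    )
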