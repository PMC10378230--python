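"""Neutral-track construction: the idealized reference configuration against
which a subject's individual track is compared.

The only normative value of the method is the cranial-base angle of 40.3
degrees between the neutral middle cranial floor (MCFn) and the neutral
pterygo-mandibular plane (PMn).  Everything else is built from the subject's
own dimensions:

3-D (sphere centered at Ba):
    1. mid-sagittal plane through Ba estimated from the bilateral pairs;
    2. MCFx = intersection of the rMCF-lMCF chord with the mid-sagittal plane;
    3. sphere(Ba, |Ba-MCFx|) cut by the mid-sagittal plane -> sagittal circle;
    4. CPBa = plane through Ba parallel to PM; SEn = circle point whose ray
       from Ba makes 40.3 deg with CPBa's sagittal trace (anterior-superior
       branch, toward MCFx);
    5. PMn = plane through SEn parallel to PM;
    6. rSEn/lSEn flank SEn laterally; MCFn = plane through Ba, rSEn, lSEn;
    7. CPCo = plane through mCo parallel to PMn; GoP = plane through rGo,
       lGo perpendicular to PMn; rGon/lGon = gonions displaced along the PMn
       normal to lie halfway between PMn and CPCo; MRn = plane through mCo,
       rGon, lGon;
    8. FOPn = plane through rPoc, lPoc perpendicular to PMn.

2-D (circle centered at Ar, radius |Ar-SE|): the same construction on the
lateral cephalogram, with Gon halfway between PMn and its parallel through Ar.

The lateral flanking points rSEn/lSEn are "arbitrary" in the method; two
modes are provided.  ``tangent`` (default) places them at SEn +/- delta along
the sagittal normal, so MCFn contains the Ba-SEn ray exactly and the 40.3 deg
identity is exact and delta-independent.  ``on_sphere`` keeps them on the
sphere, on the constant-elevation circle through SEn (sphere cut by the plane
through SEn parallel to CPBa), which bends the sagittal trace of MCFn
slightly away from the Ba-SEn ray — a documented deviation of order 0.3 deg
at delta = 5 mm that vanishes as delta -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .errors import DegenerateGeometryError, GeometryError
from .geometry2d import (
    Circle2,
    Line2,
    angle_at_vertex,
    angle_between_lines,
    circle_point_at_angle_2d,
    perp_2d,
    unit_vector_2d,
)
from .geometry3d import (
    Circle3,
    Plane,
    Sphere,
    dihedral_angle,
    midpoint,
    oriented_trace_angle,
    plane_from_points,
    plane_parallel_through,
    plane_perpendicular_through_chord,
    point_on_circle_at_angle,
    segment_plane_intersection,
    signed_distance,
    sphere_plane_intersection,
    unit_vector,
)
from .individual_track import IndividualTrack3D, midsagittal_plane
from .landmarks_io import LandmarkSet2D, LandmarkSet3D

__all__ = [
    "NEUTRAL_ANGLE_DEG",
    "NeutralTrack3D",
    "NeutralTrack2D",
    "midsagittal_plane",
    "locate_mcfx",
    "locate_sen",
    "build_pmn",
    "build_mcfn",
    "locate_gon",
    "build_neutral_track_3d",
    "build_neutral_track_2d",
    "neutral_self_check",
    "track_delta",
]

#: The normative cranial-base angle of the neutral track, degrees.
NEUTRAL_ANGLE_DEG = 40.3

#: Smallest allowed lateral flank offset for rSEn/lSEn, mm.
MIN_DELTA_MM = 0.1


@dataclass(eq=False)
class NeutralTrack3D:
    sphere: Sphere
    sagittal_circle: Circle3
    CPBa: Plane
    CPCo: Plane
    GoP: Plane
    MCFx: np.ndarray
    SEn: np.ndarray
    rSEn: np.ndarray
    lSEn: np.ndarray
    rGon: np.ndarray
    lGon: np.ndarray
    MCFn: Plane
    PMn: Plane
    MRn: Plane
    FOPn: Plane
    neutral_angle: float
    sagittal: Plane
    PM: Plane
    landmarks: LandmarkSet3D
    mcfn_mode: str
    delta: float

    def planes(self) -> dict[str, Plane]:
        return {"MCFn": self.MCFn, "PMn": self.PMn, "MRn": self.MRn, "FOPn": self.FOPn}

    def points(self) -> dict[str, np.ndarray]:
        return {
            "MCFx": self.MCFx, "SEn": self.SEn, "rSEn": self.rSEn, "lSEn": self.lSEn,
            "rGon": self.rGon, "lGon": self.lGon,
        }


@dataclass(eq=False)
class NeutralTrack2D:
    circle: Circle2
    SEn: np.ndarray
    Gon: np.ndarray
    MCFn: Line2
    PMn: Line2
    MRn: Line2
    FOPn: Line2
    PM: Line2
    neutral_angle: float
    landmarks: LandmarkSet2D

    def lines(self) -> dict[str, Line2]:
        return {"MCFn": self.MCFn, "PMn": self.PMn, "MRn": self.MRn, "FOPn": self.FOPn}


def locate_mcfx(lm: LandmarkSet3D, sagittal: Plane) -> np.ndarray:
    """MCFx: the rMCF-lMCF chord's intersection with the mid-sagittal plane."""
    return segment_plane_intersection(lm.rMCF, lm.lMCF, sagittal)


def locate_sen(lm: LandmarkSet3D, sagittal: Plane, pm: Plane,
               neutral_angle: float = NEUTRAL_ANGLE_DEG):
    """Sphere, sagittal circle, CPBa and the neutral sphenoethmoidal point SEn.

    SEn is the point of the sagittal circle whose ray from Ba makes
    ``neutral_angle`` degrees with CPBa (the construction plane through Ba
    parallel to PM), on the anterior-superior branch — the candidate whose
    ray has the largest dot product with Ba->MCFx.
    """
    mcfx = locate_mcfx(lm, sagittal)
    radius = float(np.linalg.norm(mcfx - lm.Ba))
    if radius < 1e-9:
        raise DegenerateGeometryError("MCFx coincides with Ba: zero sphere radius")
    sphere = Sphere(center=lm.Ba, radius=radius)
    circle = sphere_plane_intersection(sphere, sagittal)
    cpba = plane_parallel_through(pm, lm.Ba)
    sen = point_on_circle_at_angle(circle, cpba, neutral_angle, branch=mcfx - lm.Ba)
    return sphere, circle, cpba, sen


def build_pmn(pm: Plane, sen) -> Plane:
    """PMn: plane through SEn parallel to PM (same normal)."""
    return plane_parallel_through(pm, sen)


def build_mcfn(ba, sen, sagittal: Plane, delta: float = 5.0,
               mode: Literal["tangent", "on_sphere"] = "tangent",
               cpba: Optional[Plane] = None):
    """Flanking points rSEn/lSEn and the neutral middle cranial floor MCFn.

    ``tangent``: rSEn/lSEn = SEn +/- delta * sagittal normal.  MCFn then
    contains the Ba-SEn ray exactly, so the plane is independent of delta and
    its sagittal-trace angle with PMn is exactly the neutral angle.

    ``on_sphere``: rSEn/lSEn lie on the sphere, on the constant-elevation
    circle through SEn (sphere cut by the plane through SEn parallel to
    ``cpba``), displaced laterally so their sagittal-normal coordinate is
    +/- delta.  Requires ``cpba``; introduces a small documented trace-angle
    deviation decreasing with delta.
    """
    ba = np.asarray(ba, dtype=float)
    sen = np.asarray(sen, dtype=float)
    if delta < MIN_DELTA_MM:
        raise DegenerateGeometryError(
            f"flank offset delta must be >= {MIN_DELTA_MM} mm, got {delta}")
    n = sagittal.normal
    if mode == "tangent":
        rsen = sen + delta * n
        lsen = sen - delta * n
    elif mode == "on_sphere":
        if cpba is None:
            raise ValueError("on_sphere mode requires the CPBa plane")
        radius = float(np.linalg.norm(sen - ba))
        level = plane_parallel_through(cpba, sen)
        circle = sphere_plane_intersection(Sphere(center=ba, radius=radius), level)
        # In-plane frame of the elevation circle: lateral component of the
        # sagittal normal, and its in-plane perpendicular through SEn.
        e1 = n - float(np.dot(n, level.normal)) * level.normal
        e1 = unit_vector(e1)
        rel = sen - circle.center
        e2 = unit_vector(rel - float(np.dot(rel, e1)) * e1)
        if delta >= circle.radius:
            raise DegenerateGeometryError(
                f"delta {delta} mm exceeds elevation-circle radius {circle.radius:.3g} mm")
        along = float(np.sqrt(circle.radius**2 - delta**2))
        rsen = circle.center + delta * e1 + along * e2
        lsen = circle.center - delta * e1 + along * e2
    else:
        raise ValueError(f"unknown MCFn mode {mode!r}")
    mcfn = plane_from_points(ba, rsen, lsen)
    return rsen, lsen, mcfn


def locate_gon(lm: LandmarkSet3D, pmn: Plane):
    """CPCo, GoP and the neutral gonions.

    CPCo is the plane through mCo parallel to PMn; GoP the plane through both
    gonions perpendicular to PMn.  Each gonion is displaced purely along the
    PMn normal until its distance to PMn equals half the CPCo-PMn distance,
    which keeps it at the gonion's level inside GoP.
    """
    d_cpco = signed_distance(lm.mCo, pmn)
    if abs(d_cpco) < 1e-9:
        raise DegenerateGeometryError("mCo lies on PMn; Gon construction undefined")
    cpco = plane_parallel_through(pmn, lm.mCo)
    gop = plane_perpendicular_through_chord(pmn, lm.rGo, lm.lGo)
    d_mid = 0.5 * d_cpco
    n = pmn.normal
    rgon = lm.rGo + (d_mid - signed_distance(lm.rGo, pmn)) * n
    lgon = lm.lGo + (d_mid - signed_distance(lm.lGo, pmn)) * n
    return cpco, gop, rgon, lgon


def build_neutral_track_3d(lm: LandmarkSet3D,
                           neutral_angle: float = NEUTRAL_ANGLE_DEG,
                           delta: float = 5.0,
                           mcfn_mode: Literal["tangent", "on_sphere"] = "tangent",
                           ) -> NeutralTrack3D:
    """Run the full 3-D neutral-track construction on a landmark set.

    Geometry errors are re-raised annotated with the failing stage name.
    """
    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except GeometryError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    sagittal = stage("midsagittal_plane", midsagittal_plane, lm)
    pm = stage("pm_plane", plane_from_points, lm.rMCF, lm.lMCF, lm.PNS)
    mcfx = stage("locate_mcfx", locate_mcfx, lm, sagittal)
    sphere, circle, cpba, sen = stage("locate_sen", locate_sen, lm, sagittal, pm,
                                      neutral_angle)
    pmn = stage("build_pmn", build_pmn, pm, sen)
    rsen, lsen, mcfn = stage("build_mcfn", build_mcfn, lm.Ba, sen, sagittal,
                             delta, mcfn_mode, cpba)
    cpco, gop, rgon, lgon = stage("locate_gon", locate_gon, lm, pmn)
    mrn = stage("build_mrn", plane_from_points, lm.mCo, rgon, lgon)
    fopn = stage("build_fopn", plane_perpendicular_through_chord, pmn, lm.rPoc, lm.lPoc)
    return NeutralTrack3D(
        sphere=sphere, sagittal_circle=circle, CPBa=cpba, CPCo=cpco, GoP=gop,
        MCFx=mcfx, SEn=sen, rSEn=rsen, lSEn=lsen, rGon=rgon, lGon=lgon,
        MCFn=mcfn, PMn=pmn, MRn=mrn, FOPn=fopn,
        neutral_angle=neutral_angle, sagittal=sagittal, PM=pm, landmarks=lm,
        mcfn_mode=mcfn_mode, delta=delta,
    )


def build_neutral_track_2d(lm: LandmarkSet2D,
                           neutral_angle: float = NEUTRAL_ANGLE_DEG) -> NeutralTrack2D:
    """Run the 2-D neutral-track construction on a lateral-cephalogram set.

    The circle is centered at Ar with radius |Ar-SE|; SEn is the anterior
    circle point whose ray from Ar makes the neutral angle with the PM
    direction (alternate interior angles make the angle at SEn between MCFn
    and PMn equal to the same value).  Gon sits at Go's level along PMn,
    halfway between PMn and its parallel through Ar.
    """
    radius = float(np.linalg.norm(lm.SE - lm.Ar))
    if radius < 1e-9:
        raise DegenerateGeometryError("SE coincides with Ar: zero circle radius")
    # PM direction oriented superior-ward (from Ptm toward SE).
    u_pm = unit_vector_2d(lm.SE - lm.Ptm)
    circle = Circle2(center=lm.Ar, radius=radius)
    anterior = lm.SE - lm.Ar  # anterior-superior hint toward the cranial floor
    sen = circle_point_at_angle_2d(lm.Ar, radius, u_pm, neutral_angle, branch=anterior)
    mcfn = Line2(point=lm.Ar, direction=sen - lm.Ar)
    pmn = Line2(point=sen, direction=u_pm)
    pm = Line2(point=lm.SE, direction=u_pm)
    # Gon: same PMn-parallel coordinate as Go, halfway between PMn and the
    # parallel through Ar.
    n = perp_2d(u_pm)
    c_mid = 0.5 * (float(np.dot(sen, n)) + float(np.dot(lm.Ar, n)))
    gon = lm.Go + (c_mid - float(np.dot(lm.Go, n))) * n
    mrn = Line2(point=lm.Ar, direction=gon - lm.Ar)
    fopn = Line2(point=lm.Poc, direction=n)
    return NeutralTrack2D(circle=circle, SEn=sen, Gon=gon, MCFn=mcfn, PMn=pmn,
                          MRn=mrn, FOPn=fopn, PM=pm, neutral_angle=neutral_angle,
                          landmarks=lm)


def neutral_self_check(nt) -> dict[str, float]:
    """The construction's defining angle identities, as measured on the result.

    Returns {"MCFn^PMn": ..., "FOPn^PMn": ..., "PMn^PM": ...}; on any valid
    input these are (neutral_angle, 90, 0) up to the mode's documented MCFn
    deviation.
    """
    if isinstance(nt, NeutralTrack3D):
        lm = nt.landmarks
        mcfn_pmn = oriented_trace_angle(
            nt.MCFn, nt.PMn, nt.sagittal,
            orient_a=lm.Ba - nt.SEn,     # MCFn trace from SEn toward Ba
            orient_b=lm.PNS - nt.SEn,    # PMn trace toward the PNS side
        )
        return {
            "MCFn^PMn": mcfn_pmn,
            "FOPn^PMn": dihedral_angle(nt.FOPn, nt.PMn),
            "PMn^PM": dihedral_angle(nt.PMn, nt.PM),
        }
    if isinstance(nt, NeutralTrack2D):
        lm = nt.landmarks
        # Orient PMn toward the Ptm side for the acute vertex angle at SEn.
        d = nt.PMn.direction
        if float(np.dot(d, lm.Ptm - lm.SE)) < 0:
            d = -d
        mcfn_pmn = angle_at_vertex(lm.Ar, nt.SEn, nt.SEn + d)
        return {
            "MCFn^PMn": mcfn_pmn,
            "FOPn^PMn": angle_between_lines(nt.FOPn, nt.PMn),
            "PMn^PM": angle_between_lines(nt.PMn, nt.PM),
        }
    raise TypeError(f"expected a neutral track, got {type(nt).__name__}")


def track_delta(individual: IndividualTrack3D, neutral: NeutralTrack3D,
                sagittal: Optional[Plane] = None) -> dict[str, float]:
    """Per-plane angular deviation of the individual track from its neutral
    counterpart (sagittal-trace angles; PM vs PMn is 0 by construction)."""
    sagittal = sagittal if sagittal is not None else individual.midsagittal
    lm = individual.landmarks
    mid_mcf = midpoint(lm.rMCF, lm.lMCF)
    m_go = midpoint(lm.rGo, lm.lGo)
    m_gon = midpoint(neutral.rGon, neutral.lGon)
    m_poc = midpoint(lm.rPoc, lm.lPoc)
    anterior_occlusal = lm.mAoc - m_poc
    return {
        "MCF^MCFn": oriented_trace_angle(individual.MCF, neutral.MCFn, sagittal,
                                         orient_a=mid_mcf - lm.Ba,
                                         orient_b=neutral.SEn - lm.Ba),
        "PM^PMn": 0.0,
        "MR^MRn": oriented_trace_angle(individual.MR, neutral.MRn, sagittal,
                                       orient_a=m_go - lm.mCo,
                                       orient_b=m_gon - lm.mCo),
        "FOP^FOPn": oriented_trace_angle(individual.FOP, neutral.FOPn, sagittal,
                                         orient_a=anterior_occlusal,
                                         orient_b=anterior_occlusal),
    }
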