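"""Deterministic generator of craniofacial landmark sets.

Produces bilaterally quasi-symmetric 3-D landmark sets built from a fixed,
mirror-symmetric template, with four knobs:

* ``scale`` — global size factor;
* ``ramus_angle_offset`` / ``cranial_base_offset`` — rotations (degrees)
  about the lateral axis through anatomically fixed hinge points (the ramus
  group about mCo, basion about the MCF mid-chord), emulating the rotational
  growth factor the track analysis is designed to detect.  Positive offsets
  open (increase) MCF^MR and MCF^PM respectively;
* ``asymmetry`` — per-pair lateral shifts (mm), breaking mirror symmetry;
* ``noise_sd`` — isotropic Gaussian landmark noise (mm).

Each 3-D subject comes with a consistent 2-D lateral-cephalogram set obtained
by exact mid-sagittal projection (the generator works in the canonical frame,
so projection drops the lateral coordinate):

* SE = proj(midpoint(rMCF, lMCF)), Ptm = proj(PNS), Go = proj(mid-gonion),
  Poc = proj(mid-Poc), Aoc = proj(mAoc);
* Ar — articulare has no 3-D counterpart; it is emulated as the foot of the
  perpendicular from proj(mCo) onto the projected cranial-base line
  (proj(Ba)–SE).  Articulare lies on the cranial-base shadow near the
  condyle, and this rule keeps the 2-D MCF line collinear with the 3-D MCF
  plane's sagittal trace, so noise-free symmetric subjects reproduce MCF^PM
  identically in 2-D and 3-D.  The residual 2-D/3-D gap in MCF^MR (the 2-D
  ramus line is anchored at Ar rather than at the projected mCo) is exactly
  the kind of method discrepancy the cohort comparison quantifies.

Subject ``i`` of a cohort draws its parameters and noise from a dedicated
stream derived from ``(master_seed, i)``, so cohorts are reproducible and
stable under reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .landmarks_io import LandmarkSet2D, LandmarkSet3D

__all__ = [
    "SubjectParams",
    "CohortDistribution",
    "template_landmarks",
    "generate_subject",
    "generate_cohort",
    "project_to_2d",
]

# Fixed mirror-symmetric template (mm, RAS frame, Ba at the origin).
_TEMPLATE = {
    "Ba": (0.0, 0.0, 0.0),
    "rMCF": (25.0, 45.0, 18.0),
    "lMCF": (-25.0, 45.0, 18.0),
    "PNS": (0.0, 48.0, -18.0),
    "rCo": (50.0, 8.0, 2.0),
    "lCo": (-50.0, 8.0, 2.0),
    "rGo": (45.0, 25.0, -55.0),
    "lGo": (-45.0, 25.0, -55.0),
    "rPoc": (25.0, 45.0, -48.0),
    "lPoc": (-25.0, 45.0, -48.0),
    "rAoc": (20.0, 70.0, -47.0),
    "lAoc": (-20.0, 70.0, -47.0),
}

_PAIRS = (("rMCF", "lMCF"), ("rCo", "lCo"), ("rGo", "lGo"),
          ("rPoc", "lPoc"), ("rAoc", "lAoc"))


@dataclass(frozen=True)
class SubjectParams:
    """Generator knobs for one synthetic subject."""

    scale: float = 1.0
    ramus_angle_offset: float = 0.0     # degrees
    cranial_base_offset: float = 0.0    # degrees
    asymmetry: float = 0.0              # mm, lateral perturbation amplitude
    noise_sd: float = 0.0               # mm, isotropic landmark noise
    seed: int = 0

    def __post_init__(self):
        if not (self.scale > 0):
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.asymmetry < 0:
            raise ValueError(f"asymmetry must be >= 0, got {self.asymmetry}")


@dataclass(frozen=True)
class CohortDistribution:
    """Per-subject parameter distribution for cohort generation."""

    noise_sd: float = 0.5               # mm, fixed for every subject
    asymmetry_max: float = 2.0          # mm, asymmetry ~ U(0, max)
    offset_sd: float = 3.0              # degrees, offsets ~ N(0, sd)
    scale_range: tuple = (0.9, 1.1)     # scale ~ U(lo, hi)


def template_landmarks() -> LandmarkSet3D:
    """The fixed mirror-symmetric template landmark set (mm)."""
    return LandmarkSet3D(**{k: np.array(v) for k, v in _TEMPLATE.items()})


def _rot_x(deg: float) -> np.ndarray:
    """Rotation about the +x (lateral) axis; positive = clockwise in the
    right-side sagittal view, which opens the track angles."""
    t = np.radians(-deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rotate_about(points: dict, names, hinge: np.ndarray, deg: float) -> None:
    R = _rot_x(deg)
    for name in names:
        points[name] = hinge + R @ (points[name] - hinge)


def project_to_2d(lm: LandmarkSet3D) -> LandmarkSet2D:
    """Exact mid-sagittal projection of a canonical-frame 3-D set.

    Drops the lateral (x) coordinate: 2-D frame is (anterior, superior).
    """
    def proj(p):
        return np.array([p[1], p[2]])

    se = proj(0.5 * (lm.rMCF + lm.lMCF))
    ba = proj(lm.Ba)
    mco = proj(lm.mCo)
    u = se - ba
    norm = np.linalg.norm(u)
    if norm < 1e-12:
        raise ValueError("projected cranial-base line degenerate (Ba == SE)")
    u = u / norm
    ar = ba + float(np.dot(mco - ba, u)) * u
    return LandmarkSet2D(
        SE=se,
        Ar=ar,
        Ptm=proj(lm.PNS),
        Go=proj(0.5 * (lm.rGo + lm.lGo)),
        Poc=proj(0.5 * (lm.rPoc + lm.lPoc)),
        Aoc=proj(lm.mAoc),
    )


def generate_subject(params: SubjectParams) -> tuple[LandmarkSet3D, LandmarkSet2D]:
    """One synthetic subject: 3-D landmark set plus its projected 2-D set.

    Deterministic for a given ``params`` (including seed); with all knobs at
    zero and scale 1 it returns exactly the template and its projection.
    """
    rng = np.random.default_rng(params.seed)
    pts = {k: params.scale * np.array(v) for k, v in _TEMPLATE.items()}

    mco = 0.5 * (pts["rCo"] + pts["lCo"])
    _rotate_about(pts, ("rGo", "lGo"), mco, params.ramus_angle_offset)
    mid_mcf = 0.5 * (pts["rMCF"] + pts["lMCF"])
    _rotate_about(pts, ("Ba",), mid_mcf, params.cranial_base_offset)

    # Lateral pair shifts and landmark noise are always drawn (then scaled by
    # their amplitudes) so the stream layout is independent of the knobs.
    shifts = rng.uniform(-1.0, 1.0, size=len(_PAIRS)) * params.asymmetry
    for (r, l), d in zip(_PAIRS, shifts):
        offset = np.array([d, 0.0, 0.0])
        pts[r] = pts[r] + offset
        pts[l] = pts[l] + offset
    names = list(_TEMPLATE)
    noise = rng.standard_normal((len(names), 3)) * params.noise_sd
    for name, eps in zip(names, noise):
        pts[name] = pts[name] + eps

    lm3 = LandmarkSet3D(**pts)
    return lm3, project_to_2d(lm3)


def _subject_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def generate_cohort(n: int, distribution: CohortDistribution | None = None,
                    seed: int = 0) -> list[tuple[SubjectParams, LandmarkSet3D, LandmarkSet2D]]:
    """Generate ``n`` subjects with parameters drawn per ``distribution``.

    Subject ``i`` uses the stream ``SeedSequence(seed, spawn_key=(i,))`` both
    for its parameter draws and (via a derived integer seed) its landmark
    noise, so any subject can be regenerated in isolation.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    dist = distribution or CohortDistribution()
    lo, hi = dist.scale_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid scale range {dist.scale_range}")
    subjects = []
    for i in range(n):
        ss = _subject_seed(seed, i)
        rng = np.random.default_rng(ss)
        params = SubjectParams(
            scale=float(rng.uniform(lo, hi)),
            ramus_angle_offset=float(rng.normal(0.0, dist.offset_sd)),
            cranial_base_offset=float(rng.normal(0.0, dist.offset_sd)),
            asymmetry=float(rng.uniform(0.0, dist.asymmetry_max)),
            noise_sd=dist.noise_sd,
            seed=int(ss.generate_state(1)[0] & 0x7FFFFFFF),
        )
        lm3, lm2 = generate_subject(params)
        subjects.append((params, lm3, lm2))
    return subjects


def with_seed(params: SubjectParams, seed: int) -> SubjectParams:
    """Convenience copy of ``params`` with a different seed."""
    return replace(params, seed=seed)
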