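"""Landmark file I/O, validation, report serialization and plane-mesh export.

Supported landmark formats
--------------------------
csv
    Header ``name,x,y,z`` (``name,x,y`` in 2-D), comma separated, dot decimal.
json
    Flat object ``{"Ba": [x, y, z], ...}``.
fcsv
    3D Slicer markups fiducial file (``# Markups fiducial file version``
    header).  Coordinates are taken as RAS unless the header declares LPS.

Coordinates are mapped into the internal RAS-like frame (x = right,
y = anterior, z = superior, mm).  Landmark names are resolved
case-insensitively through an explicit synonym table; unknown names warn and
are ignored, missing required names raise.
"""

from __future__ import annotations

import csv
import io
import json
import struct
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .errors import (
    DuplicateLandmarkError,
    MalformedFileError,
    MissingLandmarkError,
    ReportValidationError,
    UnknownLandmarkWarning,
)
from .geometry3d import Plane, as_point3, midpoint
from .geometry2d import as_point2

__all__ = [
    "LANDMARKS_3D",
    "LANDMARKS_2D",
    "LandmarkSet3D",
    "LandmarkSet2D",
    "Finding",
    "AnalysisReport",
    "parse_landmarks_3d",
    "parse_landmarks_2d",
    "validate_landmarks",
    "export_planes_mesh",
    "write_report",
    "read_report",
]

#: Required landmark names, 3-D individual track.
LANDMARKS_3D = (
    "rMCF", "lMCF", "Ba", "rCo", "lCo", "rGo", "lGo",
    "PNS", "rPoc", "lPoc", "rAoc", "lAoc",
)

#: Required landmark names, 2-D lateral cephalogram.
LANDMARKS_2D = ("SE", "Ar", "Ptm", "Go", "Poc", "Aoc")


def _norm_key(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


# Explicit, versioned synonym table: normalized form -> canonical name.
_SYNONYMS_3D = {}
for canonical, extras in {
    "rMCF": ["right middle cranial floor", "middle cranial floor right side", "mcf right"],
    "lMCF": ["left middle cranial floor", "middle cranial floor left side", "mcf left"],
    "Ba": ["basion"],
    "rCo": ["right condylion", "condylion right"],
    "lCo": ["left condylion", "condylion left"],
    "rGo": ["right gonion", "gonion right"],
    "lGo": ["left gonion", "gonion left"],
    "PNS": ["posterior nasal spine"],
    "rPoc": ["right posterior occlusal contact", "posterior occlusal contact right side"],
    "lPoc": ["left posterior occlusal contact", "posterior occlusal contact left side"],
    "rAoc": ["right anterior occlusal contact", "anterior occlusal contact right side"],
    "lAoc": ["left anterior occlusal contact", "anterior occlusal contact left side"],
}.items():
    _SYNONYMS_3D[_norm_key(canonical)] = canonical
    for alias in extras:
        _SYNONYMS_3D[_norm_key(alias)] = canonical

_SYNONYMS_2D = {}
for canonical, extras in {
    "SE": ["sphenoethmoidal junction", "sphenoethmoidale"],
    "Ar": ["articulare"],
    "Ptm": ["pterygomaxillary fissure", "pterygomaxillare"],
    "Go": ["gonion"],
    "Poc": ["posterior occlusal contact"],
    "Aoc": ["anterior occlusal contact"],
}.items():
    _SYNONYMS_2D[_norm_key(canonical)] = canonical
    for alias in extras:
        _SYNONYMS_2D[_norm_key(alias)] = canonical


@dataclass(eq=False)
class LandmarkSet3D:
    """The 12 named 3-D landmarks of the individual track, in mm (RAS frame).

    Derived midpoints ``mCo`` (between the condylions) and ``mAoc`` (between
    the anterior occlusal contacts) are exposed as properties.
    """

    rMCF: np.ndarray
    lMCF: np.ndarray
    Ba: np.ndarray
    rCo: np.ndarray
    lCo: np.ndarray
    rGo: np.ndarray
    lGo: np.ndarray
    PNS: np.ndarray
    rPoc: np.ndarray
    lPoc: np.ndarray
    rAoc: np.ndarray
    lAoc: np.ndarray

    def __post_init__(self):
        for f in fields(self):
            setattr(self, f.name, as_point3(getattr(self, f.name)))

    @property
    def mCo(self) -> np.ndarray:
        return midpoint(self.rCo, self.lCo)

    @property
    def mAoc(self) -> np.ndarray:
        return midpoint(self.rAoc, self.lAoc)

    def __getitem__(self, name: str) -> np.ndarray:
        if name in ("mCo", "mAoc"):
            return getattr(self, name)
        if name not in LANDMARKS_3D:
            raise KeyError(name)
        return getattr(self, name)

    def as_dict(self, derived: bool = False) -> dict:
        d = {name: getattr(self, name).copy() for name in LANDMARKS_3D}
        if derived:
            d["mCo"] = self.mCo
            d["mAoc"] = self.mAoc
        return d

    @classmethod
    def from_mapping(cls, mapping) -> "LandmarkSet3D":
        missing = [n for n in LANDMARKS_3D if n not in mapping]
        if missing:
            raise MissingLandmarkError(missing)
        return cls(**{n: mapping[n] for n in LANDMARKS_3D})

    def transformed(self, func) -> "LandmarkSet3D":
        """New set with ``func`` (point -> point) applied to every landmark."""
        return LandmarkSet3D(**{n: func(getattr(self, n)) for n in LANDMARKS_3D})


@dataclass(eq=False)
class LandmarkSet2D:
    """The 6 named lateral-cephalogram landmarks, in mm (x anterior, y superior)."""

    SE: np.ndarray
    Ar: np.ndarray
    Ptm: np.ndarray
    Go: np.ndarray
    Poc: np.ndarray
    Aoc: np.ndarray

    def __post_init__(self):
        for f in fields(self):
            setattr(self, f.name, as_point2(getattr(self, f.name)))

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in LANDMARKS_2D:
            raise KeyError(name)
        return getattr(self, name)

    def as_dict(self) -> dict:
        return {name: getattr(self, name).copy() for name in LANDMARKS_2D}

    @classmethod
    def from_mapping(cls, mapping) -> "LandmarkSet2D":
        missing = [n for n in LANDMARKS_2D if n not in mapping]
        if missing:
            raise MissingLandmarkError(missing)
        return cls(**{n: mapping[n] for n in LANDMARKS_2D})


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _frame_to_ras(xyz: np.ndarray, frame: str) -> np.ndarray:
    """Map coordinates from an external frame convention into internal RAS."""
    frame = frame.upper()
    if frame == "RAS":
        return xyz
    if frame == "LPS":
        return xyz * np.array([-1.0, -1.0, 1.0])
    raise ValueError(f"unknown coordinate frame {frame!r} (expected RAS or LPS)")


def _read_text(source) -> str:
    if isinstance(source, (str, Path)):
        return Path(source).read_text()
    return source.read()


def _infer_format(source, dim: int) -> str:
    if isinstance(source, (str, Path)):
        suffix = Path(source).suffix.lower().lstrip(".")
        if suffix in ("csv", "json", "fcsv"):
            return suffix
    raise ValueError("cannot infer landmark format; pass format='csv'|'json'|'fcsv'")


def _rows_from_csv(text: str, ncols: int):
    rows = []
    reader = csv.reader(io.StringIO(text))
    for lineno, row in enumerate(reader, start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if row[0].lstrip().startswith("#"):
            continue
        if len(row) < 1 + ncols:
            raise MalformedFileError(
                f"expected {1 + ncols} comma-separated fields, got {len(row)}", line=lineno
            )
        name = row[0].strip()
        try:
            coords = [float(v) for v in row[1 : 1 + ncols]]
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise MalformedFileError(f"non-numeric coordinate in {row!r}", line=lineno)
        rows.append((name, coords, lineno))
    return rows


def _rows_from_json(text: str, ncols: int):
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise MalformedFileError(f"invalid JSON: {exc}", line=exc.lineno)
    if not isinstance(obj, dict):
        raise MalformedFileError("JSON landmark file must be an object name -> [coords]")
    rows = []
    for name, coords in obj.items():
        coords = list(np.ravel(coords))
        if len(coords) != ncols:
            raise MalformedFileError(f"landmark {name!r} must have {ncols} coordinates")
        rows.append((name, [float(c) for c in coords], None))
    return rows


def _rows_from_fcsv(text: str):
    """Parse a Slicer markups fiducial file; returns (rows, frame)."""
    frame = None
    rows = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("coordinatesystem"):
                value = body.split("=", 1)[-1].strip().upper()
                if value in ("LPS", "1"):
                    frame = "LPS"
                elif value in ("RAS", "0"):
                    frame = "RAS"
            continue
        parts = line.split(",")
        if len(parts) < 12:
            raise MalformedFileError(
                f"fcsv row needs >= 12 fields (id,x,y,z,...,label), got {len(parts)}",
                line=lineno,
            )
        try:
            coords = [float(v) for v in parts[1:4]]
        except ValueError:
            raise MalformedFileError(f"non-numeric coordinate in {parts[1:4]!r}", line=lineno)
        rows.append((parts[11].strip(), coords, lineno))
    return rows, frame


def _resolve_rows(rows, synonyms, required, frame, ncols):
    resolved = {}
    for name, coords, lineno in rows:
        canonical = synonyms.get(_norm_key(name))
        if canonical is None:
            warnings.warn(f"unknown landmark name {name!r} ignored", UnknownLandmarkWarning)
            continue
        if canonical in resolved:
            raise DuplicateLandmarkError(
                f"landmark {canonical!r} appears more than once"
                + (f" (line {lineno})" if lineno else "")
            )
        xyz = np.asarray(coords, dtype=float)
        if ncols == 3:
            xyz = _frame_to_ras(xyz, frame)
        resolved[canonical] = xyz
    missing = [n for n in required if n not in resolved]
    if missing:
        raise MissingLandmarkError(missing)
    return resolved


def parse_landmarks_3d(source, format: Optional[str] = None, frame: str = "RAS") -> LandmarkSet3D:
    """Read a 3-D landmark file into a :class:`LandmarkSet3D`.

    Parameters
    ----------
    source : path or file-like
    format : 'csv' | 'json' | 'fcsv', optional
        Inferred from the file suffix when omitted.
    frame : 'RAS' | 'LPS'
        Convention of the coordinates in the file.  For fcsv the header's
        ``CoordinateSystem`` declaration takes precedence.
    """
    fmt = (format or _infer_format(source, 3)).lower()
    text = _read_text(source)
    if fmt == "csv":
        rows = _rows_from_csv(text, 3)
    elif fmt == "json":
        rows = _rows_from_json(text, 3)
    elif fmt == "fcsv":
        rows, header_frame = _rows_from_fcsv(text)
        frame = header_frame or frame
    else:
        raise ValueError(f"unknown format {fmt!r}")
    resolved = _resolve_rows(rows, _SYNONYMS_3D, LANDMARKS_3D, frame, 3)
    return LandmarkSet3D.from_mapping(resolved)


def parse_landmarks_2d(source, format: Optional[str] = None) -> LandmarkSet2D:
    """Read a 2-D (lateral cephalogram) landmark file into a :class:`LandmarkSet2D`."""
    fmt = (format or _infer_format(source, 2)).lower()
    text = _read_text(source)
    if fmt == "csv":
        rows = _rows_from_csv(text, 2)
    elif fmt == "json":
        rows = _rows_from_json(text, 2)
    else:
        raise ValueError(f"unknown 2-D format {fmt!r} (csv or json)")
    resolved = _resolve_rows(rows, _SYNONYMS_2D, LANDMARKS_2D, "RAS", 2)
    return LandmarkSet2D.from_mapping(resolved)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Finding:
    severity: Literal["error", "warning"]
    code: str
    message: str


#: Inter-landmark distances outside this band raise a plausibility warning (mm).
PLAUSIBLE_DISTANCE_MM = (5.0, 200.0)

_PLANE_TRIPLES = {
    "MCF": ("rMCF", "lMCF", "Ba"),
    "PM": ("rMCF", "lMCF", "PNS"),
    "MR": ("mCo", "rGo", "lGo"),
    "FOP": ("rPoc", "lPoc", "mAoc"),
}

_BILATERAL_PAIRS = (("rMCF", "lMCF"), ("rCo", "lCo"), ("rGo", "lGo"),
                    ("rPoc", "lPoc"), ("rAoc", "lAoc"))


def validate_landmarks(lm: LandmarkSet3D) -> list[Finding]:
    """Check a landmark set; returns findings instead of raising.

    Errors: non-finite coordinates, degenerate required planes.
    Warnings: inverted left/right laterality, implausible inter-landmark
    distances (outside the 5-200 mm band).
    """
    findings: list[Finding] = []
    for name in LANDMARKS_3D:
        if not np.all(np.isfinite(lm[name])):
            findings.append(Finding("error", "non-finite", f"landmark {name} is non-finite"))
    for plane_name, triple in _PLANE_TRIPLES.items():
        p1, p2, p3 = (lm[n] for n in triple)
        area = 0.5 * float(np.linalg.norm(np.cross(p2 - p1, p3 - p1)))
        if area < 1e-9:
            findings.append(
                Finding("error", "degenerate-plane",
                        f"{plane_name} plane degenerate: {', '.join(triple)} collinear")
            )
    for r, l in _BILATERAL_PAIRS:
        if lm[r][0] <= lm[l][0]:
            findings.append(
                Finding("warning", "laterality",
                        f"{r}/{l} laterality looks inverted (x_right <= x_left)")
            )
    lo, hi = PLAUSIBLE_DISTANCE_MM
    names = list(LANDMARKS_3D)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = float(np.linalg.norm(lm[a] - lm[b]))
            if not (lo <= d <= hi):
                findings.append(
                    Finding("warning", "distance",
                            f"|{a}-{b}| = {d:.1f} mm outside the {lo:.0f}-{hi:.0f} mm band")
                )
    return findings


# ---------------------------------------------------------------------------
# Plane mesh export
# ---------------------------------------------------------------------------

_GROUP_COLORS = {
    "individual": (255, 255, 255),
    "neutral": (0, 90, 214),
    "construction": (150, 150, 150),
}

_NEUTRAL_NAMES = {"MCFn", "PMn", "MRn", "FOPn"}
_INDIVIDUAL_NAMES = {"MCF", "PM", "MR", "FOP"}


def _default_group(name: str) -> str:
    if name in _INDIVIDUAL_NAMES:
        return "individual"
    if name in _NEUTRAL_NAMES:
        return "neutral"
    return "construction"


def _plane_patch(plane: Plane, bounds) -> np.ndarray:
    """Rectangular patch: the minimal in-plane rectangle covering the
    projections of the bounding-box corners onto the plane."""
    lo = as_point3(bounds[0])
    hi = as_point3(bounds[1])
    if not np.all(hi > lo):
        raise ValueError("bounds must satisfy max > min on every axis")
    n = plane.normal
    # In-plane orthonormal frame.
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, n)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - np.dot(seed, n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    rel = corners - plane.anchor
    us = rel @ u
    vs = rel @ v
    quad_uv = [(us.min(), vs.min()), (us.max(), vs.min()),
               (us.max(), vs.max()), (us.min(), vs.max())]
    return np.array([plane.anchor + a * u + b * v for a, b in quad_uv])


def export_planes_mesh(planes, bounds, path, format: Optional[str] = None,
                       groups: Optional[dict] = None) -> Path:
    """Export named track planes as a colored mesh (ascii PLY or binary STL).

    Parameters
    ----------
    planes : mapping name -> Plane (or iterable of (name, Plane))
        Individual-track planes render white, neutral-track planes blue,
        construction planes gray (override with ``groups``).
    bounds : (min_xyz, max_xyz)
        Axis-aligned box (mm) controlling patch extents: each plane becomes
        the minimal rectangle covering the box's projection onto it.
    path : output file path.
    format : 'ply' | 'stl', inferred from the suffix when omitted.
    groups : optional mapping name -> 'individual'|'neutral'|'construction'.
    """
    items = list(planes.items()) if isinstance(planes, dict) else list(planes)
    if not items:
        raise ValueError("no planes to export")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("ply", "stl"):
        raise ValueError(f"unsupported mesh format {fmt!r} (ply or stl)")
    groups = groups or {}
    vertices: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []
    face_colors: list[tuple[int, int, int]] = []
    for name, plane in items:
        quad = _plane_patch(plane, bounds)
        base = len(vertices)
        vertices.extend(quad)
        color = _GROUP_COLORS[groups.get(name, _default_group(name))]
        faces.append((base, base + 1, base + 2))
        faces.append((base, base + 2, base + 3))
        face_colors.extend([color, color])
    verts = np.asarray(vertices, dtype=float)
    if fmt == "ply":
        _write_ascii_ply(path, verts, faces, face_colors)
    else:
        _write_binary_stl(path, verts, faces)
    return path


def _write_ascii_ply(path: Path, vertices, faces, face_colors) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(faces)}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write("end_header\n")
        for v in vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for (i, j, k), (r, g, b) in zip(faces, face_colors):
            fh.write(f"3 {i} {j} {k} {r} {g} {b}\n")


def _write_binary_stl(path: Path, vertices, faces) -> None:
    with open(path, "wb") as fh:
        fh.write(b"\0" * 80)
        fh.write(struct.pack("<I", len(faces)))
        for i, j, k in faces:
            a, b, c = vertices[i], vertices[j], vertices[k]
            n = np.cross(b - a, c - a)
            norm = np.linalg.norm(n)
            n = n / norm if norm > 0 else np.zeros(3)
            fh.write(struct.pack("<3f", *n))
            for p in (a, b, c):
                fh.write(struct.pack("<3f", *p))
            fh.write(struct.pack("<H", 0))


# ---------------------------------------------------------------------------
# Analysis report
# ---------------------------------------------------------------------------

class Provenance(BaseModel):
    model_config = ConfigDict(extra="forbid")
    config: dict
    version: str
    input_digest: Optional[str] = None


class AnalysisReport(BaseModel):
    """Serializable record of one subject's track analysis."""

    model_config = ConfigDict(extra="forbid")

    subject_id: str
    mode: Literal["2d", "3d"]
    angles_individual: dict[str, float]
    neutral_self_check: dict[str, float]
    track_delta: Optional[dict[str, float]] = None
    points: dict[str, list[float]] = {}
    provenance: Provenance

    @field_validator("angles_individual", "neutral_self_check", "track_delta")
    @classmethod
    def _angles_valid(cls, v):
        if v is None:
            return v
        for name, value in v.items():
            if not np.isfinite(value):
                raise ValueError(f"angle {name!r} is not finite: {value}")
            if not (-180.0 <= value <= 360.0):
                raise ValueError(f"angle {name!r} out of range: {value}")
        return v

    @field_validator("points")
    @classmethod
    def _points_valid(cls, v):
        for name, coords in v.items():
            if not np.all(np.isfinite(coords)):
                raise ValueError(f"point {name!r} has non-finite coordinates")
        return v


def write_report(report: AnalysisReport, path) -> Path:
    """Serialize a report to JSON; round-trips losslessly via :func:`read_report`."""
    try:
        # Revalidate so reports assembled via model_construct (or mutated in
        # place) cannot smuggle NaN/out-of-range values into a file.
        report = AnalysisReport.model_validate(report.model_dump())
        payload = report.model_dump_json(indent=2)
    except Exception as exc:
        raise ReportValidationError(str(exc)) from exc
    path = Path(path)
    path.write_text(payload + "\n")
    return path


def read_report(path) -> AnalysisReport:
    try:
        return AnalysisReport.model_validate_json(Path(path).read_text())
    except Exception as exc:
        raise ReportValidationError(str(exc)) from exc
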