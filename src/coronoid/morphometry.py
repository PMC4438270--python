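"""Mandibular landmark vocabulary and the ten morphometric parameters.

The toolkit's parameter vector (d1..d10, all mm) is the classic set of
mandibular distances driving the parametric model:

==== ========== ====================================================
id   short name definition (operationalization in this toolkit)
==== ========== ====================================================
d1   Gn-IdD     direct distance infradentale (idD) - gnathion (Gn)
d2   Go-GoD     bigonial width: distance between left/right gonion
d3   Ko-KoD     bicondylar breadth: distance between the condyle points
d4   VTM        mandibular body height at the mental-foramen level,
                measured on the mesh perpendicular to the base plane
d5   STM        mandibular body breadth at the same level, perpendicular
                to the body's long axis (mesh)
d6   DTM        mandibular length: distance from the chin point to the
                line along the posterior border of the two angles
d7   MSR        minimum ramus breadth perpendicular to the ramus height
                direction (mesh)
d8   MVR        maximum ramus height: condylion (Kon) - gonion (Go)
d9   VKo        condyle height: component of Kon - mandibular-notch
                point (MU) perpendicular to the MVR axis
d10  Gn-KoD     gnathion - condylion distance
==== ========== ====================================================

d4, d5 and d7 require the mesh; they may instead be supplied directly via
``overrides`` (e.g. when read from a measurement sheet). Bilateral
parameters use the configured ``side`` (default: right, the side of the
modeled coronoid process); d2 and d3 are inherently bilateral.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateConfigurationError,
    MeshUnavailableError,
    MissingLandmarkError,
    ParameterError,
)
from .geometry import (
    Plane,
    build_object_coordinate_system,
    intersect_mesh_plane,
    to_ocs_frame,
)

PARAMETER_NAMES = ("d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8", "d9", "d10")
PARAMETER_SHORT_NAMES = {
    "d1": "Gn-IdD", "d2": "Go-GoD", "d3": "Ko-KoD", "d4": "VTM", "d5": "STM",
    "d6": "DTM", "d7": "MSR", "d8": "MVR", "d9": "VKo", "d10": "Gn-KoD",
}
MESH_PARAMETERS = ("d4", "d5", "d7")

#: canonical landmark vocabulary; bilateral names carry _left/_right
LANDMARK_VOCABULARY = (
    "BO_left", "BO_right", "Gn", "Go_left", "Go_right",
    "Kon_left", "Kon_right", "MU_left", "MU_right", "idD",
)

#: landmarks each parameter reads (either side of a bilateral pair counts)
PARAMETER_LANDMARKS = {
    "d1": ("Gn", "idD"),
    "d2": ("Go_left", "Go_right"),
    "d3": ("Kon_left", "Kon_right"),
    "d4": ("BO_*", "Gn", "Go_*"),
    "d5": ("BO_*", "Gn", "Go_*"),
    "d6": ("Gn", "Go_left", "Go_right"),
    "d7": ("Kon_*", "Go_*"),
    "d8": ("Kon_*", "Go_*"),
    "d9": ("Kon_*", "MU_*", "Go_*"),
    "d10": ("Gn", "Kon_*"),
}


@dataclass
class LandmarkSet:
    """Named anatomical points (mm) with a frame tag (``scanner`` or ``ocs``)."""

    points: dict
    frame: str = "scanner"

    def __post_init__(self):
        self.points = {str(k): np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.points:
            raise MissingLandmarkError(name)
        return self.points[name]

    def get(self, name: str, default=None):
        return self.points.get(name, default)

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def names(self) -> list[str]:
        return list(self.points)

    def require(self, names, context: str = ""):
        missing = [n for n in names if n not in self.points]
        if missing:
            raise MissingLandmarkError(missing, context)

    def transformed(self, func) -> "LandmarkSet":
        return LandmarkSet({k: func(v) for k, v in self.points.items()}, frame="ocs")

    # -- serialization -----------------------------------------------------

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [{"name": k, "x": v[0], "y": v[1], "z": v[2]} for k, v in self.points.items()]
        ).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, aliases: dict | None = None, frame: str = "scanner") -> "LandmarkSet":
        df = pd.read_csv(path)
        if not {"name", "x", "y", "z"}.issubset(df.columns):
            raise ParameterError("landmark CSV must have columns name,x,y,z")
        aliases = aliases or {}
        pts = {aliases.get(r.name, r.name): (r.x, r.y, r.z) for r in df.itertuples(index=False)}
        return cls(pts, frame=frame)

    def to_json(self, path) -> None:
        json.dump({k: v.tolist() for k, v in self.points.items()}, open(path, "w"), indent=1)

    @classmethod
    def from_json(cls, path, frame: str = "scanner") -> "LandmarkSet":
        return cls(json.load(open(path)), frame=frame)


@dataclass
class MorphometricParameters:
    """The ten-element parameter vector in fixed d1..d10 order (mm)."""

    values: np.ndarray
    specimen_id: str | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).reshape(-1)
        if v.shape != (10,):
            raise ParameterError(f"expected 10 parameters, got {v.shape[0]}")
        if not np.all(np.isfinite(v)):
            raise ParameterError("parameters must be finite")
        self.values = v

    def is_anatomical(self) -> bool:
        """True if every distance is strictly positive (as a measured
        anatomical distance must be). Synthetic or probe vectors — e.g. the
        all-zero vector used to read off model intercepts — may be not."""
        return bool(np.all(self.values > 0))

    def __getitem__(self, name: str) -> float:
        return float(self.values[PARAMETER_NAMES.index(name)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(PARAMETER_NAMES), name=self.specimen_id)

    @classmethod
    def from_mapping(cls, mapping, specimen_id=None) -> "MorphometricParameters":
        missing = [n for n in PARAMETER_NAMES if n not in mapping]
        if missing:
            raise ParameterError(f"missing parameter(s): {missing}")
        return cls([mapping[n] for n in PARAMETER_NAMES], specimen_id)


def read_parameter_table(path) -> pd.DataFrame:
    """Read a per-specimen parameter CSV (columns specimen_id,d1..d10)."""
    df = pd.read_csv(path)
    missing = [c for c in ("specimen_id", *PARAMETER_NAMES) if c not in df.columns]
    if missing:
        raise ParameterError(f"parameter CSV missing column(s): {missing}")
    return df[["specimen_id", *PARAMETER_NAMES]]


def write_parameter_table(df: pd.DataFrame, path) -> None:
    df[["specimen_id", *PARAMETER_NAMES]].to_csv(path, index=False, float_format="%.17g")


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def _point_line_distance(p, a, b) -> float:
    p, a, b = (np.asarray(v, float) for v in (p, a, b))
    u = b - a
    n = np.linalg.norm(u)
    if n < 1e-9:
        raise DegenerateConfigurationError("posterior-border line endpoints coincide")
    u = u / n
    r = p - a
    return float(np.linalg.norm(r - (r @ u) * u))


def _section_extent(mesh, plane: Plane, direction, near) -> float:
    curves = intersect_mesh_plane(mesh, plane, roi_point=near)
    if not curves:
        raise DegenerateConfigurationError("measurement plane misses the mesh")
    proj = curves[0].vertices @ (np.asarray(direction, float) / np.linalg.norm(direction))
    return float(proj.max() - proj.min())


def compute_morphometric_parameters(
    landmarks: LandmarkSet,
    mesh=None,
    side: str = "right",
    overrides: dict | None = None,
    specimen_id: str | None = None,
) -> MorphometricParameters:
    """Compute d1..d10 from landmarks (and the mesh for d4, d5, d7).

    ``overrides`` maps parameter names to externally measured values, which
    take precedence and lift the mesh requirement for that parameter.
    """
    if side not in ("left", "right"):
        raise ParameterError("side must be 'left' or 'right'")
    overrides = dict(overrides or {})
    s = lambda base: f"{base}_{side}"
    out: dict[str, float] = {}

    def need(names, param):
        missing = [n for n in names if n not in landmarks]
        if missing:
            raise MissingLandmarkError(missing, f"required for {param} ({PARAMETER_SHORT_NAMES[param]})")

    direct = {
        "d1": ("Gn", "idD"),
        "d2": ("Go_left", "Go_right"),
        "d3": ("Kon_left", "Kon_right"),
        "d8": (s("Kon"), s("Go")),
        "d10": ("Gn", s("Kon")),
    }
    for p, (a, b) in direct.items():
        if p in overrides:
            continue
        need((a, b), p)
        out[p] = _dist(landmarks[a], landmarks[b])

    if "d6" not in overrides:
        chin = "Pog" if "Pog" in landmarks else "Gn"
        need((chin, "Go_left", "Go_right"), "d6")
        out["d6"] = _point_line_distance(landmarks[chin], landmarks["Go_left"], landmarks["Go_right"])

    if "d9" not in overrides:
        need((s("Kon"), s("MU"), s("Go")), "d9")
        r = landmarks[s("Kon")] - landmarks[s("MU")]
        v = landmarks[s("Kon")] - landmarks[s("Go")]
        v = v / np.linalg.norm(v)
        out["d9"] = float(np.linalg.norm(r - (r @ v) * v))

    mesh_needed = [p for p in MESH_PARAMETERS if p not in overrides]
    if mesh_needed:
        if mesh is None:
            raise MeshUnavailableError(
                f"parameters {mesh_needed} require a mesh (or values via overrides)"
            )
        out.update(_mesh_parameters(landmarks, mesh, side, mesh_needed))

    out.update({k: float(v) for k, v in overrides.items()})
    params = MorphometricParameters([out[n] for n in PARAMETER_NAMES], specimen_id)
    if not params.is_anatomical():
        bad = [n for n in PARAMETER_NAMES if params[n] <= 0]
        raise DegenerateConfigurationError(f"non-positive measured distance(s): {bad}")
    return params


def _mesh_parameters(landmarks: LandmarkSet, mesh, side: str, wanted) -> dict:
    """Slice-based body/ramus measurements, evaluated in the OCS frame."""
    s = lambda base: f"{base}_{side}"
    ocs = build_object_coordinate_system(landmarks)
    lm = landmarks if landmarks.frame == "ocs" else to_ocs_frame(landmarks, ocs)
    m = mesh if landmarks.frame == "ocs" else to_ocs_frame(mesh, ocs)
    z = np.array([0.0, 0.0, 1.0])
    out = {}

    if "d4" in wanted or "d5" in wanted:
        lm.require(("BO_" + side, "Gn", s("Go")), "body cross-section (VTM/STM)")
        axis = lm[s("Go")] - lm["Gn"]
        axis[2] = 0.0  # body long axis taken in the base plane
        axis = axis / np.linalg.norm(axis)
        plane = Plane(lm["BO_" + side], axis)
        if "d4" in wanted:
            out["d4"] = _section_extent(m, plane, z, lm["BO_" + side])
        if "d5" in wanted:
            out["d5"] = _section_extent(m, plane, np.cross(z, axis), lm["BO_" + side])

    if "d7" in wanted:
        lm.require((s("Kon"), s("Go")), "ramus sections (MSR)")
        go, kon = lm[s("Go")], lm[s("Kon")]
        u = (kon - go) / np.linalg.norm(kon - go)
        w = np.cross(u, np.array([1.0, 0.0, 0.0]))
        w = w / np.linalg.norm(w)
        breadths = []
        for t in np.linspace(0.25, 0.75, 11):
            c = go + t * (kon - go)
            try:
                breadths.append(_section_extent(m, Plane(c, u), w, c))
            except DegenerateConfigurationError:
                continue
        if not breadths:
            raise DegenerateConfigurationError("no ramus section intersects the mesh")
        out["d7"] = float(min(breadths))
    return out


@dataclass
class LandmarkValidationReport:
    """Report-only landmark QC: completeness, symmetry, frame."""

    frame: str
    missing: list[str] = field(default_factory=list)
    extra: list[str] = field(default_factory=list)
    affected_parameters: dict = field(default_factory=dict)
    asymmetry: dict = field(default_factory=dict)
    asymmetry_flagged: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.missing and not self.asymmetry_flagged


def validate_landmarks(landmarks: LandmarkSet, max_asymmetry_ratio: float = 1.25) -> LandmarkValidationReport:
    """Check a landmark set against the canonical vocabulary.

    Reports missing and extra names, the parameters each missing landmark
    affects, and left/right asymmetry (ratio of distances from a midline
    reference) beyond ``max_asymmetry_ratio``.
    """
    present = set(landmarks.names())
    missing = [n for n in LANDMARK_VOCABULARY if n not in present]
    extra = sorted(present - set(LANDMARK_VOCABULARY))

    affected: dict[str, list[str]] = {}
    for name in missing:
        base = name.split("_")[0]
        for p, req in PARAMETER_LANDMARKS.items():
            hits = any(r == name or r == base + "_*" for r in req)
            if hits:
                affected.setdefault(name, []).append(p)

    ref = landmarks.get("Gn")
    if ref is None and present:
        ref = np.mean([landmarks[n] for n in present], axis=0)
    asym, flagged = {}, []
    for base in ("BO", "Go", "Kon", "MU"):
        left, right = landmarks.get(f"{base}_left"), landmarks.get(f"{base}_right")
        if left is None or right is None or ref is None:
            continue
        dl, dr = np.linalg.norm(left - ref), np.linalg.norm(right - ref)
        if min(dl, dr) < 1e-9:
            continue
        ratio = float(max(dl, dr) / min(dl, dr))
        asym[base] = ratio
        if ratio > max_asymmetry_ratio:
            flagged.append(base)
    return LandmarkValidationReport(landmarks.frame, missing, extra, affected, asym, flagged)
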