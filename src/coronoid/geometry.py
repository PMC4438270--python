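"""Landmark-driven mesh geometry.

This module builds the specimen-specific object coordinate system (OCS) of
the mandible from named anatomical landmarks, cuts triangle meshes with
planes into ordered intersection curves, and samples labeled anatomical
points on those curves.

The OCS follows the standard landmark construction: the origin is the
midpoint between the left and right mental-foramen points; the mediosagittal
(MS) plane contains the origin with its normal along the inter-foramen line;
the mandibular (base) plane is normal to the MS plane, leveled at the most
inferior of a configurable set of inferior-border landmarks, then translated
to the origin; the anteroposterior (AP) plane is normal to both. Axis
polarity: +x points from the left to the right mental foramen, +z points
away from the inferior landmark (upward), and +y = z x x closes a
right-handed frame.

All coordinates are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.interpolate import CubicSpline

from .errors import (
    DegenerateConfigurationError,
    MissingLandmarkError,
    ParameterError,
)

#: absolute geometric tolerance, mm
GEOM_TOL = 1e-6
#: linear-algebra tolerance (orthonormality, unit norms)
LINALG_TOL = 1e-9

#: landmarks eligible to level the mandibular plane, in priority order
DEFAULT_INFERIOR_LANDMARKS = ("Gn", "Go_left", "Go_right")


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < GEOM_TOL:
        raise DegenerateConfigurationError(f"{what} has near-zero length ({n:g})")
    return v / n


@dataclass(frozen=True)
class Plane:
    """An oriented plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > LINALG_TOL:
            n = _unit(n, "plane normal")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points - self.point) @ self.normal

    def translated_to(self, point: np.ndarray) -> "Plane":
        return Plane(np.asarray(point, dtype=float), self.normal)


@dataclass(frozen=True)
class ObjectCoordinateSystem:
    """Specimen-specific frame: origin, right-handed axes, and the three
    coordinate planes (mediosagittal, mandibular, anteroposterior)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        R = self.rotation
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-8:
            raise DegenerateConfigurationError("axes are not orthonormal")
        if np.linalg.norm(np.cross(self.x_axis, self.y_axis) - self.z_axis) > 1e-8:
            raise DegenerateConfigurationError("axes are not right-handed")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose columns are the OCS axes in the parent frame."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    @property
    def ms_plane(self) -> Plane:
        return Plane(self.origin, self.x_axis)

    @property
    def mandibular_plane(self) -> Plane:
        return Plane(self.origin, self.z_axis)

    @property
    def ap_plane(self) -> Plane:
        return Plane(self.origin, self.y_axis)

    @classmethod
    def identity(cls) -> "ObjectCoordinateSystem":
        return cls(np.zeros(3), np.eye(3)[0], np.eye(3)[1], np.eye(3)[2])

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """World -> OCS coordinates (rigid transform)."""
        points = np.asarray(points, dtype=float)
        return (points - self.origin) @ self.rotation

    def from_frame(self, points: np.ndarray) -> np.ndarray:
        """OCS -> world coordinates."""
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.origin


def build_object_coordinate_system(
    landmarks,
    inferior_landmarks: tuple[str, ...] = DEFAULT_INFERIOR_LANDMARKS,
) -> ObjectCoordinateSystem:
    """Construct the object coordinate system from a landmark set.

    Parameters
    ----------
    landmarks
        Mapping ``name -> (3,) point`` (a plain dict or a
        :class:`~coronoid.morphometry.LandmarkSet`). Must contain
        ``BO_left`` and ``BO_right`` (mental foramina) and at least one of
        `inferior_landmarks`.
    inferior_landmarks
        Candidate landmarks for leveling the mandibular plane, in priority
        order; the most inferior available one is used.
    """
    get = landmarks.get if hasattr(landmarks, "get") else landmarks.__getitem__
    missing = [n for n in ("BO_left", "BO_right") if get(n) is None]
    if missing:
        raise MissingLandmarkError(missing, "object coordinate system")
    bo_l = np.asarray(get("BO_left"), dtype=float)
    bo_r = np.asarray(get("BO_right"), dtype=float)
    if np.linalg.norm(bo_r - bo_l) < GEOM_TOL:
        raise DegenerateConfigurationError("mental foramen landmarks coincide")

    origin = 0.5 * (bo_l + bo_r)
    x_axis = _unit(bo_r - bo_l, "inter-foramen line")

    candidates = [(n, np.asarray(get(n), dtype=float)) for n in inferior_landmarks if get(n) is not None]
    if not candidates:
        raise MissingLandmarkError(list(inferior_landmarks), "inferior-border landmark for the mandibular plane")

    def _down(p):
        w = p - origin
        return w - (w @ x_axis) * x_axis

    # provisional down direction from the highest-priority candidate, then
    # keep the candidate that is most inferior along it
    d0 = _unit(_down(candidates[0][1]), "inferior landmark offset")
    _, lowest = max(candidates, key=lambda item: _down(item[1]) @ d0)
    z_axis = -_unit(_down(lowest), "inferior landmark offset")
    y_axis = np.cross(z_axis, x_axis)
    return ObjectCoordinateSystem(origin, x_axis, y_axis, z_axis)


def to_ocs_frame(obj, ocs: ObjectCoordinateSystem):
    """Express an object in the OCS frame (rigid transform; isometry).

    Accepts an ``(n, 3)`` / ``(3,)`` array, a mapping of named points, a
    :class:`trimesh.Trimesh`, a :class:`Curve3D`, or any object exposing
    ``transformed(func)``; returns the same kind.
    """
    if isinstance(obj, trimesh.Trimesh):
        out = obj.copy()
        out.vertices = ocs.to_frame(out.vertices)
        return out
    if isinstance(obj, Curve3D):
        return replace(obj, vertices=ocs.to_frame(obj.vertices))
    if hasattr(obj, "transformed"):
        return obj.transformed(ocs.to_frame)
    if isinstance(obj, dict):
        return {k: ocs.to_frame(np.asarray(v, dtype=float)) for k, v in obj.items()}
    return ocs.to_frame(np.asarray(obj, dtype=float))


def load_mesh(path) -> trimesh.Trimesh:
    """Load an STL/PLY mesh (mm) and drop degenerate (zero-area) faces."""
    mesh = trimesh.load_mesh(path)
    clean_mesh(mesh)
    return mesh


def clean_mesh(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """In-place removal of degenerate faces and unreferenced vertices."""
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    return mesh


@dataclass
class Curve3D:
    """An ordered polyline in 3D with chord-length parameterization.

    For closed curves the first/last connectivity is implied; the first
    vertex is not duplicated at the end.
    """

    vertices: np.ndarray
    closed: bool = False
    curve_id: str | None = None
    _cumlen: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        # drop consecutive duplicates (plane sections can emit them)
        if len(v) > 1:
            keep = np.ones(len(v), dtype=bool)
            keep[1:] = np.linalg.norm(np.diff(v, axis=0), axis=1) > 1e-12
            v = v[keep]
        if self.closed and len(v) > 1 and np.linalg.norm(v[0] - v[-1]) <= 1e-12:
            v = v[:-1]
        if len(v) < 2:
            raise ParameterError("a curve needs at least two distinct vertices")
        self.vertices = v
        pts = np.vstack([v, v[:1]]) if self.closed else v
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self._cumlen = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def cumulative_lengths(self) -> np.ndarray:
        return self._cumlen

    @property
    def length(self) -> float:
        return float(self._cumlen[-1])

    def _spline(self) -> CubicSpline:
        t = self._cumlen / self.length
        if self.closed:
            pts = np.vstack([self.vertices, self.vertices[:1]])
            return CubicSpline(t, pts, bc_type="periodic")
        return CubicSpline(t, self.vertices, bc_type="natural")

    def point_at(self, fractions, smooth: bool = True) -> np.ndarray:
        """Points at arclength fractions in [0, 1] (chord-length measure).

        With ``smooth`` a natural (periodic, if closed) cubic through the
        vertices is evaluated; otherwise the polyline is interpolated
        linearly. The curve vertices themselves are reproduced exactly in
        both modes.
        """
        f = np.atleast_1d(np.asarray(fractions, dtype=float))
        if self.closed:
            f = np.mod(f, 1.0)
        elif np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
            raise ParameterError("arclength fraction outside [0, 1] on an open curve")
        if smooth:
            return self._spline()(np.clip(f, 0.0, 1.0))
        t = self._cumlen / self.length
        pts = np.vstack([self.vertices, self.vertices[:1]]) if self.closed else self.vertices
        return np.column_stack([np.interp(f, t, pts[:, k]) for k in range(3)])

    def nearest_point(self, query: np.ndarray) -> tuple[np.ndarray, float]:
        """Exact nearest point on the polyline to ``query`` and its distance."""
        q = np.asarray(query, dtype=float)
        pts = np.vstack([self.vertices, self.vertices[:1]]) if self.closed else self.vertices
        a, b = pts[:-1], pts[1:]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        t = np.clip(np.einsum("ij,ij->i", q - a, ab) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(proj - q, axis=1)
        k = int(np.argmin(d))
        return proj[k], float(d[k])


def intersect_mesh_plane(
    mesh: trimesh.Trimesh,
    plane: Plane,
    roi_point: np.ndarray | None = None,
) -> list[Curve3D]:
    """Intersect a triangle mesh with a plane into ordered polyline curves.

    Segments from adjacent triangles are chained by shared mesh-edge
    identity into maximal polylines; loops are flagged closed. Curves are
    returned sorted by descending length. If ``roi_point`` is given, only
    the curve nearest to it is returned. An empty list means the plane
    misses the mesh.
    """
    section = mesh.section(plane_origin=plane.point, plane_normal=plane.normal)
    if section is None:
        return []
    curves = []
    for i, poly in enumerate(section.discrete):
        poly = np.asarray(poly, dtype=float)
        closed = len(poly) > 3 and np.linalg.norm(poly[0] - poly[-1]) < 1e-9
        try:
            curves.append(Curve3D(poly, closed=closed, curve_id=f"section_{i}"))
        except ParameterError:
            continue  # single-point grazing contact
    curves.sort(key=lambda c: c.length, reverse=True)
    if roi_point is not None and curves:
        curves = [min(curves, key=lambda c: c.nearest_point(roi_point)[1])]
    return curves


def sample_curve_points(
    curve: Curve3D,
    labels,
    mode: str = "even",
    anchor: np.ndarray | None = None,
    smooth: bool = True,
) -> list[tuple[str, np.ndarray]]:
    """Sample labeled anatomical points on a curve.

    ``even`` mode distributes ``len(labels)`` points uniformly in arclength:
    fractions k/(n-1) on an open curve, k/n on a closed one. ``anchored``
    mode takes a single label and returns the curve point nearest to the
    ``anchor`` landmark (e.g. a point pinned to the gnathion).
    """
    labels = list(labels)
    if mode == "even":
        n = len(labels)
        if n < 2:
            raise ParameterError("even sampling needs at least two points")
        fracs = np.arange(n) / (n if curve.closed else n - 1)
        pts = curve.point_at(fracs, smooth=smooth)
        return list(zip(labels, pts))
    if mode == "anchored":
        if anchor is None:
            raise ParameterError("anchored sampling requires an anchor point")
        if len(labels) != 1:
            raise ParameterError("anchored sampling takes exactly one label")
        point, _ = curve.nearest_point(anchor)
        return [(labels[0], point)]
    raise ParameterError(f"unknown sampling mode {mode!r}")
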