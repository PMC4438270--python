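"""Synthetic populations with known ground truth.

No public dataset of measured mandible coordinates exists for this
pipeline, so every stage is exercised against synthetic data whose
generating process is known exactly: parameter vectors drawn uniformly
within published anatomical ranges, coordinates produced by a known linear
parametric model plus independent Gaussian measurement noise, and a
smooth coronoid-like test solid with analytically planted landmarks.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import trimesh

from .errors import ParameterError
from .morphometry import PARAMETER_NAMES, LandmarkSet
from .regression import ParametricModel, TrainingSet, predict_points
from .template import HMCP_TEMPLATE, Template

#: default per-parameter sampling ranges (mm). d1, d9 and d10 reproduce the
#: spread of the published example measurement vectors; the remaining
#: parameters use standard adult mandibular anthropometry (see the methods
#: note for sources of magnitude).
DEFAULT_PARAMETER_RANGES = {
    "d1": (28.5, 32.7),     # gnathion-infradentale height
    "d2": (85.0, 105.0),    # bigonial width
    "d3": (110.0, 130.0),   # bicondylar breadth
    "d4": (25.0, 35.0),     # body height at the mental foramen
    "d5": (10.0, 16.0),     # body breadth at the mental foramen
    "d6": (70.0, 90.0),     # mandibular length
    "d7": (28.0, 38.0),     # minimum ramus breadth
    "d8": (55.0, 70.0),     # maximum ramus height
    "d9": (16.1, 24.3),     # condyle height
    "d10": (115.7, 136.3),  # gnathion-condylion distance
}

#: coefficient magnitude bounds matching the published coefficient table
INTERCEPT_RANGE = (-25.0, 25.0)
SLOPE_RANGE = (-3.0, 3.0)


def make_ground_truth_model(seed: int, template: Template = HMCP_TEMPLATE) -> ParametricModel:
    """Random coefficient table with published-scale magnitudes:
    intercepts in [-25, 25] mm, slopes in [-3, 3] mm/mm."""
    rng = np.random.default_rng(seed)
    p = template.n_points
    coeffs = np.empty((p, 3, 11))
    coeffs[:, :, 0] = rng.uniform(*INTERCEPT_RANGE, size=(p, 3))
    coeffs[:, :, 1:] = rng.uniform(*SLOPE_RANGE, size=(p, 3, 10))
    return ParametricModel(
        list(template.labels),
        coeffs,
        template,
        metadata={"template": template.template_id, "ground_truth_seed": int(seed)},
    )


def sample_parameter_vectors(
    n: int, ranges: dict | None = None, seed: int = 0
) -> pd.DataFrame:
    """Uniform parameter vectors within per-parameter ranges (d1..d10 order)."""
    if n < 1:
        raise ParameterError("need n >= 1 parameter vectors")
    ranges = {**DEFAULT_PARAMETER_RANGES, **(ranges or {})}
    rng = np.random.default_rng(seed)
    cols = {}
    for name in PARAMETER_NAMES:
        low, high = ranges[name]
        if low > high:
            raise ParameterError(f"invalid range for {name}: ({low}, {high})")
        cols[name] = rng.uniform(low, high, size=n) if high > low else np.full(n, float(low))
    df = pd.DataFrame(cols)
    df.insert(0, "specimen_id", [f"S{i + 1:03d}" for i in range(n)])
    return df


def generate_training_set(
    model: ParametricModel,
    parameters: pd.DataFrame,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[TrainingSet, np.ndarray]:
    """Coordinates = model prediction + iid Gaussian noise per coordinate.

    Returns the (noisy) training set and the noiseless ground-truth
    coordinate tensor for recovery tests.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    ids = parameters["specimen_id"].astype(str).tolist()
    D = parameters[list(PARAMETER_NAMES)].to_numpy(float)
    truth = np.stack([predict_points(model, d).coordinates for d in D])
    noisy = truth + rng.normal(0.0, noise_sd, size=truth.shape) if noise_sd > 0 else truth.copy()
    training = TrainingSet(ids, D, noisy, list(model.labels), model.template)
    return training, truth


# ---------------------------------------------------------------------------
# synthetic coronoid-like mesh
# ---------------------------------------------------------------------------

def generate_synthetic_coronoid_mesh(
    height: float = 60.0,
    depth: float = 45.0,
    thickness: float = 10.0,
    ramus_angle_deg: float = 125.0,
    notch_depth: float = 0.35,
    resolution: int = 8,
    perturbation: float = 0.02,
    seed: int = 0,
) -> tuple[trimesh.Trimesh, LandmarkSet]:
    """A smooth, watertight coronoid-like test solid with planted landmarks.

    The solid is a star-shaped blob: a unit sphere whose radius is
    modulated by two superior lobes (coronoid- and condyle-like processes)
    separated by a saddle notch, plus small seeded random bumps for
    specimen variety. It is scaled anisotropically to
    ``thickness x depth x height`` and sheared so the superior (ramus)
    direction makes ``ramus_angle_deg`` with the anterior body direction
    (anatomically 90-140 deg, most commonly 120-130). Landmarks (BO pair,
    Gn, Go, Kon, MU per side plus idD) are exact mesh vertices by
    construction. Not an anatomical mandible: it reproduces only the
    geometric features the pipeline exercises (notch, processes, plantable
    landmarks). Units mm; +z superior, -y anterior, +x right.
    """
    for name, val in (("height", height), ("depth", depth), ("thickness", thickness)):
        if val <= 0:
            raise ParameterError(f"{name} must be positive")
    if not 90.0 <= ramus_angle_deg <= 140.0:
        raise ParameterError("ramus_angle_deg outside the anatomical range 90-140")
    rng = np.random.default_rng(seed)
    n_phi, n_theta = 6 * resolution, 12 * resolution

    phi = np.linspace(0.0, np.pi, n_phi + 1)          # 0 = +z pole
    theta = np.arange(n_theta) * 2 * np.pi / n_theta  # 90 deg = +y posterior
    P, T = np.meshgrid(phi[1:-1], theta, indexing="ij")
    ring_dirs = np.stack(
        [np.sin(P) * np.cos(T), np.sin(P) * np.sin(T), np.cos(P)], axis=-1
    )
    dirs = np.vstack([[[0.0, 0.0, 1.0]], ring_dirs.reshape(-1, 3), [[0.0, 0.0, -1.0]]])

    def lobe(center, width):
        return np.exp((dirs @ center - 1.0) / width)

    d30 = np.radians(30.0)
    condyle_dir = np.array([0.0, np.sin(d30), np.cos(d30)])    # posterior lobe
    coronoid_dir = np.array([0.0, -np.sin(d30), np.cos(d30)])  # anterior lobe
    radius = (
        1.0
        + 0.45 * lobe(condyle_dir, 0.06)
        + 0.45 * lobe(coronoid_dir, 0.06)
        - notch_depth * lobe(np.array([0.0, 0.0, 1.0]), 0.03)
    )
    if perturbation > 0:
        # seeded smooth bumps, applied mirror-symmetrically in x so the
        # planted left/right landmark pairs both lie exactly on the surface
        for _ in range(6):
            c = rng.normal(size=3)
            c /= np.linalg.norm(c)
            amp, width = rng.uniform(-perturbation, perturbation), rng.uniform(0.1, 0.4)
            radius += amp * (lobe(c, width) + lobe(c * np.array([-1.0, 1.0, 1.0]), width)) / 2.0

    scale = np.array([thickness / 2.0, depth / 2.0, height / 2.0])
    vertices = dirs * radius[:, None] * scale
    # shear: tilt the superior direction posteriorly by (angle - 90) deg
    vertices[:, 1] += vertices[:, 2] * np.tan(np.radians(ramus_angle_deg - 90.0))

    faces = _uv_sphere_faces(n_phi, n_theta)
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)

    def ring_vertex(phi_deg, theta_deg):
        i = round(phi_deg / 180.0 * n_phi)
        j = round(theta_deg / 360.0 * n_theta) % n_theta
        assert 1 <= i <= n_phi - 1, "landmark latitude must be a ring node"
        return 1 + (i - 1) * n_theta + j

    # every landmark is an exact mesh vertex; left/right pairs sit at
    # x-mirrored grid nodes (theta and 180-theta), which coincide in
    # position because the radius field is mirror-symmetric
    landmark_indices = {
        "MU_right": ring_vertex(8.0, 60.0),      # notch floor, right of midline
        "MU_left": ring_vertex(8.0, 120.0),
        "Kon_right": ring_vertex(30.0, 60.0),    # condyle-lobe flank
        "Kon_left": ring_vertex(30.0, 120.0),
        "Go_right": ring_vertex(150.0, 60.0),    # posteroinferior corner
        "Go_left": ring_vertex(150.0, 120.0),
        "BO_right": ring_vertex(135.0, 300.0),   # anterior flank foramina
        "BO_left": ring_vertex(135.0, 240.0),
        "Gn": ring_vertex(150.0, 270.0),         # most inferior midline point
        "idD": ring_vertex(120.0, 270.0),        # anterior midline, above Gn
    }
    landmarks = LandmarkSet(
        {name: vertices[idx].copy() for name, idx in landmark_indices.items()},
        frame="scanner",
    )
    return mesh, landmarks


def _uv_sphere_faces(n_phi: int, n_theta: int) -> np.ndarray:
    """Triangulation of a UV sphere grid with welded pole vertices."""
    faces = []
    top, bottom = 0, 1 + (n_phi - 1) * n_theta

    def ring(i, j):
        return 1 + (i - 1) * n_theta + (j % n_theta)

    for j in range(n_theta):  # top fan
        faces.append([top, ring(1, j), ring(1, j + 1)])
    for i in range(1, n_phi - 1):
        for j in range(n_theta):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j), ring(i + 1, j + 1)
            faces.append([a, d, b])
            faces.append([a, c, d])
    for j in range(n_theta):  # bottom fan
        faces.append([bottom, ring(n_phi - 1, j + 1), ring(n_phi - 1, j)])
    return np.array(faces)
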