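import numpy as np
import pytest
import trimesh

from coronoid import (
    generate_synthetic_coronoid_mesh,
    generate_training_set,
    make_ground_truth_model,
    sample_parameter_vectors,
)


def random_rigid_transform(rng):
    """A uniformly random rotation + translation as a callable."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=40.0, size=3)
    return lambda pts: np.asarray(pts, dtype=float) @ Q.T + t


def random_landmark_set(rng):
    """A geometrically valid random landmark configuration (dict form)."""
    lm = {
        "BO_left": np.array([-12.0, -30.0, 5.0]),
        "BO_right": np.array([12.0, -30.0, 5.0]),
        "Gn": np.array([0.0, -35.0, -15.0]),
        "Go_left": np.array([-40.0, 30.0, -12.0]),
        "Go_right": np.array([40.0, 30.0, -12.0]),
        "Kon_left": np.array([-45.0, 35.0, 45.0]),
        "Kon_right": np.array([45.0, 35.0, 45.0]),
        "MU_left": np.array([-42.0, 20.0, 35.0]),
        "MU_right": np.array([42.0, 20.0, 35.0]),
        "idD": np.array([0.0, -34.0, 10.0]),
    }
    jitter = {k: v + rng.normal(scale=2.0, size=3) for k, v in lm.items()}
    move = random_rigid_transform(rng)
    return {k: move(v) for k, v in jitter.items()}


@pytest.fixture(scope="session")
def ground_truth_model():
    return make_ground_truth_model(seed=123)


@pytest.fixture(scope="session")
def noiseless_population(ground_truth_model):
    params = sample_parameter_vectors(30, seed=11)
    training, truth = generate_training_set(ground_truth_model, params, noise_sd=0.0, seed=12)
    return training, truth


@pytest.fixture(scope="session")
def noisy_population(ground_truth_model):
    params = sample_parameter_vectors(30, seed=21)
    training, truth = generate_training_set(ground_truth_model, params, noise_sd=0.5, seed=22)
    return training, truth


@pytest.fixture(scope="session")
def synthetic_specimen():
    return generate_synthetic_coronoid_mesh(seed=1)


@pytest.fixture(scope="session")
def icosphere10():
    return trimesh.creation.icosphere(subdivisions=4, radius=10.0)
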