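"""Design matrix, least-squares fit, prediction, residuals, serialization."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from coronoid import (
    HMCP_TEMPLATE,
    ModelFormatError,
    ParametricModel,
    ShapeError,
    TrainingSet,
    build_design_matrix,
    fit_parametric_model,
    load_model,
    predict_points,
    residual_table,
    save_model,
)
from coronoid.reference import (
    REFERENCE_D1,
    REFERENCE_POINTS,
    reference_model,
    reference_model_frame,
)
from coronoid.synthetic import make_ground_truth_model, sample_parameter_vectors, generate_training_set


class TestDesignMatrix:
    def test_single_zero_specimen(self):
        X = build_design_matrix(np.zeros((1, 10)))
        assert X.shape == (1, 11)
        assert np.array_equal(X[0], np.array([1.0] + [0.0] * 10))

    def test_published_d1_column_is_reproduced(self):
        D = np.zeros((7, 10))
        D[:, 0] = REFERENCE_D1
        X = build_design_matrix(D)
        assert np.array_equal(X[:, 1], np.array(REFERENCE_D1))
        assert np.all(X[:, 0] == 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_columns_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        D = rng.uniform(10, 150, size=(12, 10))
        X = build_design_matrix(D)
        assert np.array_equal(X[:, 1:], D)

    def test_dataframe_missing_column_raises(self):
        from coronoid import ParameterError

        df = pd.DataFrame({"d1": [1.0]})
        with pytest.raises(ParameterError, match="d2"):
            build_design_matrix(df)


class TestFit:
    def test_exact_recovery_on_noiseless_data(self, ground_truth_model, noiseless_population):
        training, _ = noiseless_population
        model, diag = fit_parametric_model(training)
        assert diag.rank == 11
        assert not diag.rank_deficient
        assert np.max(np.abs(model.coefficients - ground_truth_model.coefficients)) < 1e-8

    def test_rank_deficient_fit_matches_pseudoinverse_oracle(self, ground_truth_model):
        """n=10 specimens, 11 unknowns: minimum-norm solution via SVD."""
        params = sample_parameter_vectors(10, seed=31)
        training, _ = generate_training_set(ground_truth_model, params, noise_sd=0.5, seed=32)
        model, diag = fit_parametric_model(training)
        assert diag.rank_deficient and diag.rank == 10
        assert any("minimum-norm" in w for w in diag.warnings)
        X = build_design_matrix(training.parameters)
        Y = training.coordinates.reshape(10, -1)
        B_oracle = scipy.linalg.pinv(X) @ Y  # independent SVD route
        B_fit = model.coefficients.reshape(-1, 11).T
        assert np.max(np.abs(B_fit - B_oracle)) < 1e-8
        assert np.linalg.norm(Y - X @ B_fit) == pytest.approx(np.linalg.norm(Y - X @ B_oracle), abs=1e-8)

    def test_adding_on_model_specimen_leaves_fit_unchanged(self, noisy_population):
        training, _ = noisy_population
        model, _ = fit_parametric_model(training)
        new_params = sample_parameter_vectors(1, seed=77)[
            ["d%d" % i for i in range(1, 11)]
        ].to_numpy(float)
        new_coords = predict_points(model, new_params[0]).coordinates
        grown = TrainingSet(
            training.specimen_ids + ["extra"],
            np.vstack([training.parameters, new_params]),
            np.concatenate([training.coordinates, new_coords[None]], axis=0),
            list(training.labels),
            training.template,
        )
        model2, _ = fit_parametric_model(grown)
        assert np.max(np.abs(model2.coefficients - model.coefficients)) < 1e-8

    def test_shape_mismatch_raises(self, ground_truth_model):
        with pytest.raises(ShapeError):
            TrainingSet(["a", "b"], np.zeros((2, 10)), np.zeros((3, 39, 3)), list(HMCP_TEMPLATE.labels))

    def test_constant_column_warning(self, ground_truth_model):
        params = sample_parameter_vectors(12, ranges={"d5": (12.0, 12.0)}, seed=41)
        training, _ = generate_training_set(ground_truth_model, params, noise_sd=0.1, seed=42)
        _, diag = fit_parametric_model(training)
        assert any("d5" in w for w in diag.warnings)


class TestPredict:
    def test_reference_intercepts_returned_for_zero_parameters(self):
        model = reference_model()
        pts = predict_points(model, np.zeros(10))
        assert pts["P1"][0] == pytest.approx(0.068, abs=1e-12)
        assert pts["P1"][1] == pytest.approx(24.840, abs=1e-12)

    def test_zero_model_predicts_origin(self):
        model = ParametricModel(["A"], np.zeros((1, 3, 11)), template=None)
        assert np.array_equal(predict_points(model, np.arange(10.0)).coordinates, np.zeros((1, 3)))

    @pytest.mark.parametrize("seed", range(5))
    def test_prediction_matches_dot_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = make_ground_truth_model(seed)
        d = rng.uniform(10, 140, size=10)
        pts = predict_points(model, d)
        for j, lab in enumerate(model.labels):
            for k in range(3):
                b = model.coefficients[j, k]
                expected = b[0] + sum(b[i + 1] * d[i] for i in range(10))
                assert abs(pts.coordinates[j, k] - expected) < 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(alpha=st.floats(0.0, 1.0), seed=st.integers(0, 100))
    def test_prediction_is_affine_in_parameters(self, alpha, seed):
        rng = np.random.default_rng(seed)
        model = make_ground_truth_model(5)
        p1, p2 = rng.uniform(10, 140, size=(2, 10))
        blend = predict_points(model, alpha * p1 + (1 - alpha) * p2).coordinates
        expect = alpha * predict_points(model, p1).coordinates + (1 - alpha) * predict_points(model, p2).coordinates
        assert np.max(np.abs(blend - expect)) < 1e-9


class TestResiduals:
    def test_noiseless_residuals_vanish(self, noiseless_population):
        training, _ = noiseless_population
        model, diag = fit_parametric_model(training)
        assert diag.max_abs_residual < 1e-8
        table, summary = residual_table(model, training)
        assert table["residual"].abs().max() < 1e-8
        assert summary.shape == (3, training.n)

    def test_normal_equations_orthogonality(self, noisy_population):
        """For a full-rank overdetermined fit, X'E = 0 per response."""
        training, _ = noisy_population
        _, diag = fit_parametric_model(training)
        X = build_design_matrix(training.parameters)
        E = diag.residuals.reshape(training.n, -1)
        assert np.max(np.abs(X.T @ E)) < 1e-6

    def test_residual_is_measured_minus_calculated(self):
        model = ParametricModel(["A"], np.concatenate([np.full((1, 3, 1), 3.8), np.zeros((1, 3, 10))], axis=2))
        training = TrainingSet(["s"], np.ones((1, 10)), np.full((1, 1, 3), 5.0), ["A"], None)
        table, _ = residual_table(model, training)
        assert np.allclose(table["residual"], 1.2)


class TestSerialization:
    def test_round_trip_is_bitwise_lossless(self, tmp_path, ground_truth_model):
        path = tmp_path / "model.csv"
        save_model(ground_truth_model, path)
        back = load_model(path)
        assert back.labels == ground_truth_model.labels
        assert np.array_equal(back.coefficients, ground_truth_model.coefficients)
        assert back.metadata["template"] == "hmcp39"

    def test_reference_table_parses_into_four_points(self, tmp_path):
        path = tmp_path / "reference.csv"
        reference_model_frame().to_csv(path, index=False)
        model = load_model(path)
        assert tuple(model.labels) == REFERENCE_POINTS
        assert model.coefficients.shape == (4, 3, 11)

    def test_short_row_is_a_parse_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        head = "point,axis," + ",".join(f"b{i}" for i in range(11))
        path.write_text(head + "\nP1,x," + ",".join(["0.1"] * 10) + "\n")
        with pytest.raises(ModelFormatError, match="P1"):
            load_model(path)

    def test_missing_axis_row_is_an_error(self, tmp_path):
        path = tmp_path / "hole.csv"
        df = reference_model_frame()
        df = df[~((df["point"] == "P2") & (df["axis"] == "y"))]
        df.to_csv(path, index=False)
        with pytest.raises(ModelFormatError, match="P2"):
            load_model(path)
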