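"""Error reports, cross-validation, lofted surfaces, surface deviation."""

import numpy as np
import pytest
import trimesh

from coronoid import (
    AnatomicalPointSet,
    LabelMismatchError,
    ShapeError,
    Template,
    evaluate_training,
    fit_parametric_model,
    leave_one_out,
    max_coordinate_error,
    predict_points,
    reconstruct_surface,
    surface_deviation,
)
from coronoid.evaluation import _closest_point_distance
from coronoid.synthetic import generate_training_set, sample_parameter_vectors


def pointset(coords, labels=None, template=None):
    coords = np.asarray(coords, dtype=float)
    labels = labels or [f"P{i + 1}" for i in range(len(coords))]
    return AnatomicalPointSet(labels, coords, template=template)


class TestMaxCoordinateError:
    def test_identical_sets_give_zero(self):
        a = pointset(np.random.default_rng(0).normal(size=(39, 3)))
        row = max_coordinate_error(a, a)
        assert row.max_abs == (0.0, 0.0, 0.0)
        assert row.overall_max == 0.0

    def test_single_offset_point(self):
        a = pointset([[0, 0, 0], [1, 1, 1]])
        b = pointset([[0.3, -1.2, 0], [1, 1, 1]])
        row = max_coordinate_error(b, a)
        assert row.max_abs == pytest.approx((0.3, 1.2, 0.0))
        assert row.overall_argmax == ("P1", "y")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = pointset(rng.normal(size=(39, 3)))
        b = pointset(rng.normal(size=(39, 3)))
        row = max_coordinate_error(a, b)
        diff = np.abs(a.coordinates - b.coordinates)
        brute = [max(diff[j][k] for j in range(39)) for k in range(3)]
        assert np.allclose(row.max_abs, brute)
        assert row.overall_max == pytest.approx(diff.max())

    def test_label_mismatch_raises(self):
        a = pointset([[0, 0, 0]], labels=["A"])
        b = pointset([[0, 0, 0]], labels=["B"])
        with pytest.raises(LabelMismatchError):
            max_coordinate_error(a, b)

    def test_label_order_does_not_matter(self):
        a = pointset([[0, 0, 0], [1, 0, 0]], labels=["A", "B"])
        b = pointset([[1, 0, 0], [0, 0, 5]], labels=["B", "A"])
        row = max_coordinate_error(a, b)
        assert row.max_abs == pytest.approx((0.0, 0.0, 5.0))


class TestCrossValidation:
    def test_loo_on_noiseless_linear_population_is_exact(self, noiseless_population):
        training, _ = noiseless_population
        report = leave_one_out(training)
        assert report.mode == "loo"
        assert len(report.rows) == training.n
        assert report.overall_max < 1e-6

    def test_loo_deterministic_across_runs(self, noisy_population):
        training, _ = noisy_population
        r1 = leave_one_out(training)
        r2 = leave_one_out(training)
        assert [r.max_abs for r in r1.rows] == [r.max_abs for r in r2.rows]

    def test_insample_never_worse_than_loo_on_average(self, noisy_population):
        training, _ = noisy_population
        ins = evaluate_training(training, mode="insample")
        loo = evaluate_training(training, mode="loo")
        assert np.mean([r.overall_max for r in ins.rows]) <= np.mean([r.overall_max for r in loo.rows])

    def test_loo_needs_three_specimens(self, ground_truth_model):
        params = sample_parameter_vectors(2, seed=1)
        training, _ = generate_training_set(ground_truth_model, params, 0.0, seed=2)
        with pytest.raises(ShapeError):
            leave_one_out(training)

    def test_report_table_layout(self, noisy_population):
        training, _ = noisy_population
        table = evaluate_training(training, mode="insample").to_table()
        assert list(table.index) == ["X", "Y", "Z"]
        assert list(table.columns) == training.specimen_ids


class TestLoftedSurface:
    strip_template = Template("strip", (("A1", "A2", "A3", "A4"), ("B1", "B2", "B3", "B4")))

    def strip_points(self, width=5.0, length=10.0):
        xs = np.array([0.0, 3.0, 7.0, 10.0]) * (length / 10.0)
        coords = np.array([[x, 0.0, 0.0] for x in xs] + [[x, width, 0.0] for x in xs])
        return AnatomicalPointSet(list(self.strip_template.labels), coords, template=self.strip_template)

    def test_planar_strip_area(self):
        mesh = reconstruct_surface(self.strip_points(), resolution=33)
        assert mesh.area == pytest.approx(50.0, rel=1e-9)
        assert np.allclose(mesh.vertices[:, 2], 0.0)

    def test_surface_interpolates_input_points(self):
        pts = self.strip_points()
        mesh = reconstruct_surface(pts, resolution=17)
        assert _closest_point_distance(pts.coordinates, mesh).max() < 1e-6

    def test_cylinder_patch_matches_analytic_surface(self):
        """Rows on a radius-20 cylinder reconstruct to within chord error."""
        r, rows, per_row = 20.0, 4, 9
        template = Template("cyl", tuple(tuple(f"r{i}c{j}" for j in range(per_row)) for i in range(rows)))
        th = np.linspace(-0.6, 0.6, per_row)
        zs = np.linspace(0.0, 15.0, rows)
        coords = np.array([[r * np.sin(t), r * np.cos(t), z] for z in zs for t in th])
        pts = AnatomicalPointSet(list(template.labels), coords, template=template)
        mesh = reconstruct_surface(pts, resolution=65)
        radii = np.linalg.norm(mesh.vertices[:, :2], axis=1)
        chord = r * (th[1] - th[0])
        sagitta = chord**2 / (8.0 * r)
        assert np.max(np.abs(radii - r)) < 2.0 * sagitta

    def test_denser_tessellation_never_hurts_interpolation(self):
        pts = self.strip_points()
        errs = [
            _closest_point_distance(pts.coordinates, reconstruct_surface(pts, resolution=res)).max()
            for res in (9, 33, 129)
        ]
        assert errs[0] < 1e-9  # planar case is exact at any density
        assert errs[2] <= errs[0] + 1e-12

    def test_ragged_rows_rejected(self):
        from coronoid import TemplateError

        bad = Template("bad", (("A", "B", "C"), ("D", "E")))
        coords = np.random.default_rng(0).normal(size=(5, 3))
        pts = AnatomicalPointSet(list(bad.labels), coords, template=bad)
        with pytest.raises(TemplateError):
            reconstruct_surface(pts)


class TestSurfaceDeviation:
    def test_identical_meshes_deviate_zero(self):
        m = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        row = surface_deviation(m, m, max_edge=1.5)
        assert row.max_deviation < 1e-9
        assert row.mean_deviation < 1e-9

    def test_concentric_spheres_offset(self):
        inner = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        outer = trimesh.creation.icosphere(subdivisions=3, radius=10.5)
        row = surface_deviation(outer, inner, max_edge=0.5)
        # analytic offset 0.5 mm, within the mesh chord tolerance
        assert row.max_deviation == pytest.approx(0.5, abs=0.05)
        assert row.mean_deviation == pytest.approx(0.5, abs=0.05)
        assert row.max_deviation >= row.mean_deviation >= 0.0

    def test_direction_is_calculated_to_reference(self):
        big = trimesh.Trimesh(
            vertices=[[-10, -10, 0], [10, -10, 0], [10, 10, 0], [-10, 10, 0]],
            faces=[[0, 1, 2], [0, 2, 3]],
            process=False,
        )
        small = trimesh.Trimesh(
            vertices=[[-1, -1, 0], [1, -1, 0], [1, 1, 0], [-1, 1, 0]],
            faces=[[0, 1, 2], [0, 2, 3]],
            process=False,
        )
        assert surface_deviation(small, big, max_edge=1.0).max_deviation < 1e-9
        assert surface_deviation(big, small, max_edge=1.0).max_deviation > 5.0
        sym = surface_deviation(small, big, max_edge=1.0, symmetric=True)
        assert sym.max_deviation > 5.0

    def test_empty_mesh_rejected(self):
        from coronoid import ParameterError

        m = trimesh.creation.box()
        with pytest.raises(ParameterError):
            surface_deviation(m, trimesh.Trimesh())


class TestPipelineConsistency:
    def test_noiseless_pipeline_deviation_bounded_by_loft_error(self, noiseless_population):
        """fit -> predict -> loft on noiseless data: the predicted and
        measured surfaces coincide up to coefficient round-off."""
        training, _ = noiseless_population
        model, _ = fit_parametric_model(training)
        pred = predict_points(model, training.parameters[0])
        meas = training.point_set(0)
        s_pred = reconstruct_surface(pred, resolution=25)
        s_meas = reconstruct_surface(meas, resolution=25)
        # sampling density scaled to the surface extent; the bound tested is
        # about surface identity, not about discretization
        row = surface_deviation(s_pred, s_meas, max_edge=s_meas.scale / 20.0)
        assert row.max_deviation < 1e-6
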