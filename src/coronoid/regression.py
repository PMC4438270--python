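"""Per-point, per-axis multilinear parametric model.

Each template point coordinate is modeled as an affine function of the ten
morphometric parameters,

    coord = b0 + b1*d1 + ... + b10*d10,

so a training set of n specimens yields, for every (point, axis) response,
an ordinary least-squares problem Y = X B + E with the n x 11 design matrix
X = [1 | d1 .. d10]. With ten or fewer specimens the system is
column-rank-deficient (11 unknowns); the fit then returns the minimum-norm
least-squares solution computed by singular value decomposition, and the
diagnostics carry an explicit rank warning. The normal-equation quantities
(Gram matrix A = X'X, its pseudoinverse K, fitted values M = X B, residuals
E = Y - M) are reported in the diagnostics, but the solve itself always
goes through the SVD for numerical stability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ModelFormatError, ParameterError, ShapeError
from .morphometry import PARAMETER_NAMES, MorphometricParameters
from .template import AXES, HMCP_TEMPLATE, AnatomicalPointSet, Template

#: singular values below RANK_RTOL x largest are treated as zero
RANK_RTOL = 1e-10

COEF_COLUMNS = tuple(f"b{i}" for i in range(11))


@dataclass
class TrainingSet:
    """n specimens x (10 parameters + p template points in the OCS frame)."""

    specimen_ids: list[str]
    parameters: np.ndarray      # (n, 10), d1..d10 order
    coordinates: np.ndarray     # (n, p, 3), mm
    labels: list[str]
    template: Template | None = HMCP_TEMPLATE

    def __post_init__(self):
        self.specimen_ids = [str(s) for s in self.specimen_ids]
        self.parameters = np.asarray(self.parameters, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.specimen_ids)
        if self.parameters.shape != (n, 10):
            raise ShapeError(f"parameters must be ({n}, 10), got {self.parameters.shape}")
        if self.coordinates.shape != (n, len(self.labels), 3):
            raise ShapeError(
                f"coordinates must be ({n}, {len(self.labels)}, 3), got {self.coordinates.shape}"
            )
        if not (np.all(np.isfinite(self.parameters)) and np.all(np.isfinite(self.coordinates))):
            raise ShapeError("training set contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.specimen_ids)

    def subset(self, idx) -> "TrainingSet":
        idx = np.asarray(idx)
        return TrainingSet(
            [self.specimen_ids[i] for i in idx],
            self.parameters[idx],
            self.coordinates[idx],
            list(self.labels),
            self.template,
        )

    def point_set(self, i: int) -> AnatomicalPointSet:
        return AnatomicalPointSet(list(self.labels), self.coordinates[i], "ocs", self.template)

    # -- serialization -----------------------------------------------------

    def to_csvs(self, parameters_path, coordinates_path) -> None:
        pd.DataFrame(self.parameters, columns=list(PARAMETER_NAMES)).assign(
            specimen_id=self.specimen_ids
        )[["specimen_id", *PARAMETER_NAMES]].to_csv(parameters_path, index=False, float_format="%.17g")
        rows = []
        for i, sid in enumerate(self.specimen_ids):
            for j, lab in enumerate(self.labels):
                x, y, z = self.coordinates[i, j]
                rows.append({"specimen_id": sid, "point": lab, "x": x, "y": y, "z": z})
        pd.DataFrame(rows).to_csv(coordinates_path, index=False, float_format="%.17g")

    @classmethod
    def from_csvs(cls, parameters_path, coordinates_path, template: Template | None = HMCP_TEMPLATE):
        par = pd.read_csv(parameters_path)
        coo = pd.read_csv(coordinates_path)
        for col in ("specimen_id", *PARAMETER_NAMES):
            if col not in par.columns:
                raise ParameterError(f"parameter CSV missing column {col!r}")
        for col in ("specimen_id", "point", "x", "y", "z"):
            if col not in coo.columns:
                raise ParameterError(f"coordinate CSV missing column {col!r}")
        ids = par["specimen_id"].astype(str).tolist()
        labels = coo[coo["specimen_id"].astype(str) == ids[0]]["point"].tolist()
        coords = np.empty((len(ids), len(labels), 3))
        for i, sid in enumerate(ids):
            block = coo[coo["specimen_id"].astype(str) == sid].set_index("point")
            try:
                coords[i] = block.loc[labels, ["x", "y", "z"]].to_numpy(float)
            except KeyError as e:
                raise ShapeError(f"specimen {sid}: missing point {e}") from None
        return cls(ids, par[list(PARAMETER_NAMES)].to_numpy(float), coords, labels, template)


@dataclass
class FitDiagnostics:
    """Normal-equation view of the fit plus rank bookkeeping."""

    gram: np.ndarray            # A = X'X, (11, 11)
    gram_pinv: np.ndarray       # K = pinv(A)
    rank: int
    singular_values: np.ndarray
    fitted: np.ndarray          # M = X B, (n, p, 3)
    residuals: np.ndarray       # E = Y - M, (n, p, 3)
    rank_deficient: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def max_abs_residual(self) -> float:
        return float(np.max(np.abs(self.residuals))) if self.residuals.size else 0.0


@dataclass
class ParametricModel:
    """Coefficient table: one b0..b10 row per (template point, axis)."""

    labels: list[str]
    coefficients: np.ndarray     # (p, 3, 11)
    template: Template | None = HMCP_TEMPLATE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        p = len(self.labels)
        if self.coefficients.shape != (p, 3, 11):
            raise ShapeError(f"coefficients must be ({p}, 3, 11), got {self.coefficients.shape}")

    @property
    def n_points(self) -> int:
        return len(self.labels)

    def coefficient(self, label: str, axis: str, index: int) -> float:
        return float(self.coefficients[self.labels.index(label), AXES.index(axis), index])

    def predict(self, parameters) -> AnatomicalPointSet:
        return predict_points(self, parameters)


def build_design_matrix(parameters) -> np.ndarray:
    """n x 11 design matrix: a leading column of ones, then d1..d10.

    Accepts an (n, 10) array, a DataFrame with d1..d10 columns, or a list of
    :class:`MorphometricParameters`.
    """
    if isinstance(parameters, pd.DataFrame):
        missing = [c for c in PARAMETER_NAMES if c not in parameters.columns]
        if missing:
            raise ParameterError(f"missing parameter column(s): {missing}")
        D = parameters[list(PARAMETER_NAMES)].to_numpy(float)
    elif isinstance(parameters, (list, tuple)) and parameters and isinstance(parameters[0], MorphometricParameters):
        D = np.array([p.values for p in parameters])
    else:
        D = np.asarray(parameters, dtype=float)
        if D.ndim == 1:
            D = D[None, :]
    if D.ndim != 2 or D.shape[1] != 10:
        raise ShapeError(f"expected an (n, 10) parameter array, got {D.shape}")
    if D.shape[0] < 1:
        raise ShapeError("need at least one specimen")
    return np.column_stack([np.ones(D.shape[0]), D])


def fit_parametric_model(
    training: TrainingSet, rank_rtol: float = RANK_RTOL
) -> tuple[ParametricModel, FitDiagnostics]:
    """Least-squares fit of all (point, axis) responses.

    Minimum-norm solution by SVD when the design is column-rank-deficient
    (always the case for n <= 11 specimens); the rank policy is recorded in
    the model metadata and flagged in the diagnostics.
    """
    if training.n < 2:
        raise ShapeError("fitting needs at least two specimens")
    X = build_design_matrix(training.parameters)
    n, p = training.n, len(training.labels)
    Y = training.coordinates.reshape(n, p * 3)

    B, _, rank, sv = np.linalg.lstsq(X, Y, rcond=rank_rtol)
    M = X @ B
    E = Y - M

    warnings = []
    const = [PARAMETER_NAMES[j] for j in range(10) if np.ptp(X[:, j + 1]) == 0.0]
    if const:
        warnings.append(f"constant parameter column(s) (collinear with intercept): {const}")
    deficient = rank < 11
    if deficient:
        warnings.append(
            f"design matrix rank {rank} < 11 (n={n}); minimum-norm solution returned"
        )

    A = X.T @ X
    diagnostics = FitDiagnostics(
        gram=A,
        gram_pinv=np.linalg.pinv(A, rcond=rank_rtol),
        rank=int(rank),
        singular_values=sv,
        fitted=M.reshape(n, p, 3),
        residuals=E.reshape(n, p, 3),
        rank_deficient=deficient,
        warnings=warnings,
    )
    model = ParametricModel(
        list(training.labels),
        B.T.reshape(p, 3, 11),
        training.template,
        metadata={
            "template": training.template.template_id if training.template else None,
            "parameter_order": list(PARAMETER_NAMES),
            "n_specimens": n,
            "rank": int(rank),
            "rank_policy": f"minimum-norm SVD, rtol={rank_rtol:g}",
            "toolkit_version": __version__,
        },
    )
    return model, diagnostics


def predict_points(model: ParametricModel, parameters) -> AnatomicalPointSet:
    """Evaluate the model: coord = b0 + sum_i bi * di for every point/axis."""
    if isinstance(parameters, MorphometricParameters):
        d = parameters.values
    else:
        d = np.asarray(parameters, dtype=float).reshape(-1)
    if d.shape != (10,):
        raise ShapeError(f"expected 10 parameters, got {d.shape}")
    v = np.concatenate([[1.0], d])
    coords = model.coefficients @ v
    return AnatomicalPointSet(list(model.labels), coords, frame="ocs", template=model.template)


def residual_table(model: ParametricModel, training: TrainingSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residuals E = measured - predicted for every specimen/point/axis.

    Returns the long-format table and a per-specimen, per-axis max |E|
    summary (axes as rows, specimens as columns).
    """
    if list(training.labels) != list(model.labels):
        raise ShapeError("training point labels do not match the model")
    rows = []
    for i, sid in enumerate(training.specimen_ids):
        pred = predict_points(model, training.parameters[i])
        E = training.coordinates[i] - pred.coordinates
        for j, lab in enumerate(training.labels):
            for k, ax in enumerate(AXES):
                rows.append({"specimen_id": sid, "point": lab, "axis": ax, "residual": E[j, k]})
    table = pd.DataFrame(rows)
    summary = (
        table.assign(abs_residual=table["residual"].abs())
        .pivot_table(index="axis", columns="specimen_id", values="abs_residual", aggfunc="max")
        .loc[list(AXES), training.specimen_ids]
    )
    return table, summary


def save_model(model: ParametricModel, path) -> None:
    """Write the coefficient table (CSV: point,axis,b0..b10) and a JSON
    metadata sidecar; coefficients keep full double precision."""
    path = Path(path)
    rows = []
    for j, lab in enumerate(model.labels):
        for k, ax in enumerate(AXES):
            rows.append({"point": lab, "axis": ax, **dict(zip(COEF_COLUMNS, model.coefficients[j, k]))})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    meta = dict(model.metadata)
    meta.setdefault("template", model.template.template_id if model.template else None)
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1, default=str))


def load_model(path, template: Template | None = None) -> ParametricModel:
    """Read a coefficient CSV written by :func:`save_model` (or hand-built
    in the same layout)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")  # bit-exact round trip
    missing = [c for c in ("point", "axis", *COEF_COLUMNS) if c not in df.columns]
    if missing:
        raise ModelFormatError(f"{path.name}: missing column(s) {missing}")
    if df[list(COEF_COLUMNS)].isna().any(axis=None):
        bad = df.index[df[list(COEF_COLUMNS)].isna().any(axis=1)][0]
        raise ModelFormatError(
            f"{path.name}: row {bad + 2} (point {df.loc[bad, 'point']}, axis {df.loc[bad, 'axis']}) "
            "does not carry 11 coefficients"
        )
    labels = list(dict.fromkeys(df["point"]))
    coeffs = np.full((len(labels), 3, 11), np.nan)
    for _, r in df.iterrows():
        if r["axis"] not in AXES:
            raise ModelFormatError(f"{path.name}: unknown axis {r['axis']!r} for point {r['point']}")
        coeffs[labels.index(r["point"]), AXES.index(r["axis"])] = [r[c] for c in COEF_COLUMNS]
    if np.isnan(coeffs).any():
        holes = [
            f"{labels[j]}/{AXES[k]}"
            for j in range(len(labels))
            for k in range(3)
            if np.isnan(coeffs[j, k]).any()
        ]
        raise ModelFormatError(f"{path.name}: missing coefficient row(s) for {holes}")
    metadata = {}
    meta_path = path.with_suffix(".meta.json")
    if meta_path.exists():
        metadata = json.loads(meta_path.read_text())
    if template is None and len(labels) == HMCP_TEMPLATE.n_points and set(labels) == set(HMCP_TEMPLATE.labels):
        template = HMCP_TEMPLATE
    return ParametricModel(labels, coeffs, template, metadata)
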