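"""Published reference data for the coronoid-process parametric model.

The original study printed the fitted regression coefficients for four of
the 39 template points (P1, P2, P38, P39), rounded to three decimals, and
one worked matrix example with seven-specimen measurement columns for the
first point's X coordinate and for parameters d1, d9 and d10. Those
printed values are reproduced here verbatim; they serve as format
fixtures and numerical cross-checks (at the printed 3-decimal precision),
not as a refittable dataset — the underlying per-specimen measurements
for d2..d8 were never published.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .morphometry import PARAMETER_NAMES
from .regression import COEF_COLUMNS, ParametricModel
from .template import Template

#: published coefficients, (point, axis) -> (b0, b1, ..., b10), mm
REFERENCE_COEFFICIENTS = {
    ("P1", "x"): (0.068, 1.167, -0.001, -0.685, 2.443, -0.648, -0.096, 0.362, -0.102, 0.317, -0.549),
    ("P1", "y"): (24.840, 0.738, -0.002, -0.650, 1.732, -0.104, 0.235, 0.784, 0.952, -0.471, -0.402),
    ("P1", "z"): (18.606, 0.161, 0.000, -0.325, 1.247, -0.113, 0.080, -0.330, 0.753, -0.582, -0.140),
    ("P2", "x"): (12.708, 1.115, -0.001, -0.790, 3.060, -0.891, -0.012, 0.181, -0.162, 0.192, -0.621),
    ("P2", "y"): (13.340, 1.226, -0.002, -0.773, 1.644, 0.044, 0.211, 0.969, 1.170, -0.565, -0.449),
    ("P2", "z"): (18.989, 0.095, 0.000, -0.318, 1.393, -0.221, 0.004, -0.140, 0.819, -0.387, -0.173),
    ("P38", "x"): (-6.762, 1.098, -0.001, -0.519, 1.454, -0.591, -0.044, 0.335, -0.107, 0.087, -0.378),
    ("P38", "y"): (18.717, 1.684, -0.002, -1.030, 2.287, 0.181, 0.386, 0.764, 1.158, -0.870, -0.576),
    ("P38", "z"): (-0.679, 0.276, 0.000, -0.105, 0.121, 0.008, 0.021, -0.405, 0.657, -0.554, 0.046),
    ("P39", "x"): (-3.095, 1.215, -0.001, -0.605, 1.388, -0.470, 0.077, 0.536, -0.062, -0.107, -0.409),
    ("P39", "y"): (17.478, 1.715, -0.002, -1.018, 2.109, 0.210, 0.413, 0.773, 1.160, -0.943, -0.551),
    ("P39", "z"): (-0.669, 0.276, 0.000, -0.105, 0.122, 0.008, 0.021, -0.405, 0.657, -0.553, 0.046),
}

REFERENCE_POINTS = ("P1", "P2", "P38", "P39")

#: worked-example measurement columns (seven specimens), mm
REFERENCE_XCOORD_P1 = (-51.874, -47.712, -46.269, -47.164, -50.78, -49.684, -43.613)
REFERENCE_D1 = (28.55, 31.902, 29.342, 29.225, 32.697, 31.727, 30.733)
REFERENCE_D9 = (17.5, 22.375, 24.286, 21.533, 22.684, 19.454, 16.193)
REFERENCE_D10 = (122.384, 136.216, 131.729, 124.194, 130.113, 116.171, 115.732)

#: the clinical accuracy bound for the coronoid region, mm, per axis
CLINICAL_ERROR_BOUND_MM = 2.0

#: four-point template: one row of four corner points (loftable pairs only)
REFERENCE_TEMPLATE = Template("hmcp4-reference", (("P1", "P2"), ("P38", "P39")))


def reference_model() -> ParametricModel:
    """The published four-point coefficient table as a parametric model."""
    from .template import AXES

    coeffs = np.array(
        [[REFERENCE_COEFFICIENTS[(p, ax)] for ax in AXES] for p in REFERENCE_POINTS]
    )
    return ParametricModel(
        list(REFERENCE_POINTS),
        coeffs,
        REFERENCE_TEMPLATE,
        metadata={
            "template": REFERENCE_TEMPLATE.template_id,
            "source": "published reference table (3-decimal snapshot)",
            "parameter_order": list(PARAMETER_NAMES),
        },
    )


def reference_model_frame() -> pd.DataFrame:
    """The reference table as a point,axis,b0..b10 DataFrame (model CSV layout)."""
    rows = [
        {"point": p, "axis": ax, **dict(zip(COEF_COLUMNS, coefs))}
        for (p, ax), coefs in REFERENCE_COEFFICIENTS.items()
    ]
    return pd.DataFrame(rows)


def reference_measurement_frame() -> pd.DataFrame:
    """The published example measurement columns as a tidy table."""
    return pd.DataFrame(
        {
            "specimen": [f"S{i + 1}" for i in range(7)],
            "Xcoord_P1": REFERENCE_XCOORD_P1,
            "d1": REFERENCE_D1,
            "d9": REFERENCE_D9,
            "d10": REFERENCE_D10,
        }
    )
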