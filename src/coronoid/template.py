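"""Point templates and labeled anatomical point sets.

A template fixes the identity and ordering of the anatomical points the
parametric model predicts, and groups them into ordered curve rows so a
surface can be lofted through them. The default coronoid-process template
has 39 points (P1..P39) arranged as three section rows of 13.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import LabelMismatchError, TemplateError

AXES = ("x", "y", "z")


@dataclass(frozen=True)
class Template:
    """Ordered point labels grouped into loftable curve rows."""

    template_id: str
    rows: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        labels = self.labels
        if len(set(labels)) != len(labels):
            raise TemplateError("template labels must be unique")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for row in self.rows for lab in row)

    @property
    def n_points(self) -> int:
        return len(self.labels)


def _hmcp_rows(n_rows: int = 3, per_row: int = 13) -> tuple[tuple[str, ...], ...]:
    k = iter(range(1, n_rows * per_row + 1))
    return tuple(tuple(f"P{next(k)}" for _ in range(per_row)) for _ in range(n_rows))


#: default coronoid-process template: 39 points on 3 section curves
HMCP_TEMPLATE = Template("hmcp39", _hmcp_rows())


@dataclass
class AnatomicalPointSet:
    """Labeled 3D points (mm), typically in the OCS frame."""

    labels: list[str]
    coordinates: np.ndarray
    frame: str = "ocs"
    template: Template | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = [str(x) for x in self.labels]
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(len(self.labels), 3)
        if len(set(self.labels)) != len(self.labels):
            raise TemplateError("point labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self.coordinates[self.labels.index(label)]
        except ValueError:
            raise KeyError(label) from None

    def transformed(self, func) -> "AnatomicalPointSet":
        return AnatomicalPointSet(
            list(self.labels), func(self.coordinates), self.frame, self.template, dict(self.metadata)
        )

    def reordered_like(self, other: "AnatomicalPointSet") -> "AnatomicalPointSet":
        if set(self.labels) != set(other.labels):
            extra = sorted(set(self.labels) ^ set(other.labels))
            raise LabelMismatchError(f"point sets differ in labels: {extra}")
        idx = [self.labels.index(lab) for lab in other.labels]
        return AnatomicalPointSet(
            list(other.labels), self.coordinates[idx], self.frame, self.template, dict(self.metadata)
        )

    def rows(self) -> list[np.ndarray]:
        """Coordinates grouped into the template's ordered curve rows."""
        if self.template is None:
            raise TemplateError("point set carries no template row structure")
        return [np.array([self[lab] for lab in row]) for row in self.template.rows]

    # -- serialization -----------------------------------------------------

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels, "x": self.coordinates[:, 0], "y": self.coordinates[:, 1], "z": self.coordinates[:, 2]}
        )

    def to_csv(self, path) -> None:
        self.as_dataframe().to_csv(path, index=False, float_format="%.17g")
        meta = {"frame": self.frame, "template": self.template.template_id if self.template else None}
        meta.update(self.metadata)
        Path(path).with_suffix(".meta.json").write_text(json.dumps(meta, indent=1, default=str))

    @classmethod
    def from_csv(cls, path, template: Template | None = None) -> "AnatomicalPointSet":
        df = pd.read_csv(path)
        required = {"label", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise TemplateError(f"point CSV must have columns {sorted(required)}")
        frame = "ocs"
        meta_path = Path(path).with_suffix(".meta.json")
        if meta_path.exists():
            frame = json.loads(meta_path.read_text()).get("frame", "ocs")
        return cls(df["label"].tolist(), df[["x", "y", "z"]].to_numpy(float), frame=frame, template=template)

    def to_ply(self, path) -> None:
        trimesh.PointCloud(self.coordinates).export(path)
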