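"""Pipeline configuration: a validated, serializable set of defaults.

A config file (JSON) can pre-set any pipeline option; explicit command-line
flags always take precedence. The resolved configuration is embedded in
every run-metadata sidecar, so outputs are regenerable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParameterError


@dataclass
class PipelineConfig:
    template_id: str = "hmcp39"
    side: str = "right"
    #: section levels as fractions of the notch-to-condyle height
    levels: tuple[float, ...] = (0.25, 0.5, 0.75)
    points_per_curve: int = 13
    geometric_tolerance: float = 1e-6
    linalg_tolerance: float = 1e-9
    evaluation_mode: str = "insample"
    seed: int = 0
    noise_sd: float = 0.5
    output_format: str = "csv"

    def __post_init__(self):
        self.levels = tuple(float(x) for x in self.levels)
        if self.side not in ("left", "right"):
            raise ParameterError("side must be 'left' or 'right'")
        if self.evaluation_mode not in ("insample", "loo"):
            raise ParameterError("evaluation_mode must be 'insample' or 'loo'")
        if self.output_format not in ("csv", "json", "ply", "stl"):
            raise ParameterError(f"unsupported output format {self.output_format!r}")
        if self.points_per_curve < 2:
            raise ParameterError("points_per_curve must be >= 2")
        if not all(0.0 <= x <= 1.0 for x in self.levels):
            raise ParameterError("levels must be fractions in [0, 1]")
        if self.geometric_tolerance <= 0 or self.linalg_tolerance <= 0:
            raise ParameterError("tolerances must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ParameterError(f"unknown config key(s): {unknown}")
        return cls(**data)

    def override(self, **kwargs) -> "PipelineConfig":
        """New config with non-None keyword overrides applied (CLI wins)."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates)
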