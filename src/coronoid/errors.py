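"""Exception hierarchy for the coronoid toolkit."""


class CoronoidError(Exception):
    """Base class for all toolkit errors."""


class MissingLandmarkError(CoronoidError, KeyError):
    """A required named landmark is absent from the landmark set."""

    def __init__(self, names, context=""):
        if isinstance(names, str):
            names = [names]
        self.names = list(names)
        msg = f"missing landmark(s): {', '.join(self.names)}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)

    def __str__(self):  # KeyError quotes its arg; keep a plain message
        return self.args[0]


class DegenerateConfigurationError(CoronoidError, ValueError):
    """Landmark geometry is degenerate (coincident or collinear points)."""


class TemplateError(CoronoidError, ValueError):
    """Point labels or row structure do not match the template."""


class LabelMismatchError(CoronoidError, ValueError):
    """Two point sets do not carry the same labels."""


class ShapeError(CoronoidError, ValueError):
    """Array dimensions are inconsistent with the model or training set."""


class ModelFormatError(CoronoidError, ValueError):
    """A coefficient file is malformed."""


class ParameterError(CoronoidError, ValueError):
    """An operation parameter is out of its valid domain."""


class MeshUnavailableError(CoronoidError, ValueError):
    """A mesh-based morphometric parameter was requested without a mesh."""
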