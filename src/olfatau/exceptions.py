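"""Exception hierarchy shared across the pipeline stages."""


class OlfatauError(Exception):
    """Base class for all package errors."""


class ParameterError(OlfatauError, ValueError):
    """Invalid generator or analysis parameters."""


class SchemaError(OlfatauError, ValueError):
    """Tables or panels that do not match the documented schema."""


class AlignmentError(OlfatauError, ValueError):
    """Volumes that do not share a common grid/affine."""


class AtlasError(OlfatauError, ValueError):
    """Parcellation problems: missing labels, empty regions."""


class DesignError(OlfatauError, ValueError):
    """Design-matrix construction failures (duplicates, rank deficiency)."""


class GeometryError(OlfatauError, ValueError):
    """Degenerate curves or disconnected tract masks."""


class EstimationError(OlfatauError, RuntimeError):
    """Statistical estimation impossible on the given data."""


class MissingInputError(OlfatauError, FileNotFoundError):
    """A stage's required input file is absent from the run directory."""
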