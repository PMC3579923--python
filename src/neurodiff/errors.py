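"""Exception hierarchy shared across the pipeline stages."""


class NeurodiffError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(NeurodiffError, ValueError):
    """A generator or configuration spec violates its invariants."""


class SchemaError(NeurodiffError, ValueError):
    """A tabular input is missing required columns or has malformed values."""


class ValidationError(NeurodiffError, ValueError):
    """An input violates a precondition of an operation."""


class DegenerateInputError(NeurodiffError, ValueError):
    """The input is formally valid but carries no usable signal
    (e.g. a constant image handed to an edge-threshold search)."""


class TransformStateError(NeurodiffError, RuntimeError):
    """A variance-stabilizing transform was applied to an
    already-transformed feature vector."""


class UnsupportedFormatError(NeurodiffError, ValueError):
    """The image file is readable but not a supported grayscale format."""
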