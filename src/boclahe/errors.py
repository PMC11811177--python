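"""Shared exception types."""


class BoClaheError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BoClaheError, ValueError):
    """An invalid configuration or spec field."""


class ArgumentError(BoClaheError, ValueError):
    """An invalid argument to an operation."""


class SizeError(BoClaheError, ValueError):
    """An input too small for the requested operation."""


class ConsistencyError(BoClaheError, ValueError):
    """Mutually inconsistent inputs (shape or count mismatch)."""


class DegenerateInputError(BoClaheError, ValueError):
    """Input with no usable variation (e.g. zero variance)."""


class ModelError(BoClaheError, ValueError):
    """An unusable quality or surrogate model (e.g. singular covariance)."""


class StateError(BoClaheError, RuntimeError):
    """Operation called on an object in the wrong state."""


class InputError(BoClaheError, OSError):
    """An unreadable or unsupported input file."""


class FormatError(BoClaheError, ValueError):
    """A malformed serialized document."""
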