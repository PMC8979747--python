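"""Exception types shared across the package."""


class DynDetError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(DynDetError, ValueError):
    """A scalar parameter violates its precondition (e.g. beta <= 0)."""


class InvalidInputError(DynDetError, ValueError):
    """A data input violates its contract (e.g. a zero-area box)."""


class InvalidStateError(DynDetError, RuntimeError):
    """A stateful object is internally inconsistent (e.g. stale b, C)."""


class ShapeError(DynDetError, ValueError):
    """An array has an incompatible shape (e.g. odd channel count)."""


class ConfigError(DynDetError, ValueError):
    """A configuration value or key is invalid."""
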