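"""Exception hierarchy shared across the package."""


class FluctlearnError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(FluctlearnError, ValueError):
    """Raised when an operation receives malformed or non-finite input."""


class InvalidStateError(FluctlearnError, ValueError):
    """Raised when a sampler is asked to step from an inadmissible state."""


class ConfigError(FluctlearnError, ValueError):
    """Raised for inconsistent protocol or pipeline configuration."""


class DegenerateDataError(FluctlearnError, ValueError):
    """Raised when data are too few or too degenerate for an estimator."""


class NumericalError(FluctlearnError, RuntimeError):
    """Raised when a numerical routine fails to converge."""


class FormatError(FluctlearnError, ValueError):
    """Raised for malformed trial-table files."""
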