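"""Exception hierarchy shared across the package."""


class APClampError(Exception):
    """Base class for all package-specific errors."""


class DomainError(APClampError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class DegenerateInputError(APClampError, ValueError):
    """Structurally valid input on which the operation is undefined
    (e.g. alpha + beta = 0, an empty point set after filtering)."""


class WaveformValidationError(APClampError, ValueError):
    """A digitized waveform violates its invariants (non-monotone times,
    non-numeric cells, ...)."""


class GridMismatchError(APClampError, ValueError):
    """Two time series that must share a sample grid do not."""


class SolverError(APClampError, RuntimeError):
    """Numerical integration or optimisation failed to converge."""


class ConfigError(APClampError, ValueError):
    """A model/preset configuration file is malformed."""
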