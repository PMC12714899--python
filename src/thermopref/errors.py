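"""Exception types shared across the package."""


class ThermoprefError(Exception):
    """Base class for all package-specific errors."""


class OutOfArenaError(ThermoprefError, ValueError):
    """A position falls outside the corridor [0, length_cm]."""


class DegenerateDataError(ThermoprefError, ValueError):
    """Input data cannot support the requested computation (too few points,
    no spread, zero variance, ...)."""


class SchemaError(ThermoprefError, ValueError):
    """A trajectory table is missing mandatory columns or contains
    unparseable values."""


class EmptyAnalysisWindowError(ThermoprefError, ValueError):
    """Preprocessing or windowing left no frames to analyze."""


class ConfigError(ThermoprefError, ValueError):
    """Invalid simulation or run configuration."""


class UndefinedTestError(ThermoprefError, ValueError):
    """A statistical test is undefined for the given data (e.g. all
    variances zero)."""
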