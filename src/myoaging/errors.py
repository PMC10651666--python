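"""Exception hierarchy.

Validation failures (bad configuration, malformed input files) raise
:class:`ValidationError` subclasses so the CLI can map them to exit code 2;
everything else propagates as ordinary runtime failures (exit code 1).
"""


class MyoagingError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MyoagingError):
    """Invalid configuration or malformed input data."""


class ConfigError(ValidationError):
    """A configuration value is missing, non-finite or out of range."""


class ParseError(ValidationError):
    """An input file could not be parsed into a valid container."""


class NormalizationError(MyoagingError):
    """Size-factor estimation is impossible (no gene covers all samples)."""


class StatsUndefinedError(MyoagingError):
    """A statistic is undefined for the given input (n too small, zero variance)."""


class GeometryError(MyoagingError):
    """Synthetic section geometry is infeasible for the requested parameters."""
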