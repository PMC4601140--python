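"""Exception hierarchy shared across the package."""


class AcerError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(AcerError, ValueError):
    """A distribution or model parameter violates its constraints."""


class DomainError(AcerError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class DegenerateDataError(AcerError, ValueError):
    """The data carry no information about the quantity being estimated."""


class UndefinedMetricError(AcerError, ValueError):
    """A quality metric is undefined for the given regions (e.g. zero spread)."""


class ConfigurationError(AcerError, ValueError):
    """A configuration file or geometry specification is invalid."""
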