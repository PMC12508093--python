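"""Exception hierarchy shared across the package."""


class ShoalmixError(Exception):
    """Base class for all package errors."""


class CatalogError(ShoalmixError):
    """A species label is missing from, or inconsistent with, the catalog."""


class ParseError(ShoalmixError):
    """A delimited-text table could not be parsed into records."""


class ValidationError(ShoalmixError):
    """A record or matrix violates a structural invariant."""


class DomainError(ShoalmixError):
    """An operation was called outside its mathematical domain."""


class CapacityError(ShoalmixError):
    """An exact computation was requested beyond its enumerable size."""


class FittingError(ShoalmixError):
    """A statistical model could not be fitted on the given data."""


class ConfigError(ShoalmixError):
    """A pipeline configuration is invalid or incomplete."""
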