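"""Exception hierarchy shared across the pipeline."""


class NatriError(Exception):
    """Base class for all package errors."""


class ValidationError(NatriError, ValueError):
    """An input table or configuration violates a documented invariant."""


class SchemaError(ValidationError):
    """A flat file is missing a required column or has a malformed header."""


class ParseError(ValidationError):
    """A cell could not be coerced to its declared type."""


class DomainError(NatriError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class IdentifiabilityError(NatriError):
    """The data cannot identify a model parameter (e.g. no repeat recall days)."""


class DesignError(NatriError):
    """The survey design is degenerate for variance estimation (lonely PSU etc.)."""
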