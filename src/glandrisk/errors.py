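"""Exception hierarchy shared by all glandrisk modules."""


class GlandRiskError(Exception):
    """Base class for all package errors."""


class FormatError(GlandRiskError):
    """A file exists but is not in a supported format."""


class SchemaError(GlandRiskError):
    """A table or model is missing required columns/fields."""


class ValidationError(GlandRiskError):
    """An object violates a domain invariant (bad polygon, negative time...)."""


class DomainError(GlandRiskError):
    """An argument is outside the mathematical domain of an operation."""


class PackingError(GlandRiskError):
    """The synthetic layout sampler could not place the requested glands."""
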