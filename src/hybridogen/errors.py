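"""Exception hierarchy shared across the package."""


class HybridogenError(Exception):
    """Base class for all package errors."""


class FormatError(HybridogenError):
    """A file could not be parsed in the expected format."""


class ValidationError(HybridogenError):
    """Parsed data violate an invariant of the data model."""


class ConfigurationError(HybridogenError):
    """Inconsistent or incomplete analysis configuration."""


class ModelError(HybridogenError):
    """A genetic model rule was applied to a genotype it cannot act on."""
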