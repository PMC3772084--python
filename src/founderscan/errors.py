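"""Exception hierarchy shared across modules."""


class FounderscanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FounderscanError):
    """A file could not be parsed in the expected format."""


class ConfigurationError(FounderscanError):
    """Inconsistent or invalid user-supplied configuration."""


class ValidationError(FounderscanError):
    """A data structure violates one of its invariants."""


class FittingError(FounderscanError):
    """A model could not be fitted (degenerate or insufficient data)."""
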