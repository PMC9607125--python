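"""Exception hierarchy shared across the package."""


class LncSiftError(Exception):
    """Base class for all package-specific errors."""


class ParseError(LncSiftError):
    """A file could not be parsed; the message names the offending line."""


class IntegrityError(LncSiftError):
    """Parsed data violates a structural invariant (e.g. mixed-strand exons)."""


class ConfigurationError(LncSiftError):
    """The requested run configuration is invalid or incomplete."""


class FeatureContractError(LncSiftError):
    """A feature table does not match the contract a model was trained with."""
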