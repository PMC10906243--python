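"""Exception hierarchy shared across the package."""


class PepcatError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PepcatError):
    """A required setting or input column is missing or malformed."""


class ValidationError(PepcatError):
    """Input data violates a documented invariant."""


class ChemistryError(PepcatError):
    """A molecular operation (parsing, assembly, embedding) failed."""
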