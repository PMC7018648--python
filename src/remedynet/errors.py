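"""Exception hierarchy shared across the package."""


class RemedyNetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RemedyNetError):
    """A file could not be parsed in the expected dialect."""


class ValidationError(RemedyNetError):
    """Input violates a documented precondition or invariant."""


class CapabilityError(RemedyNetError):
    """The requested computation exceeds a hard size limit."""
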