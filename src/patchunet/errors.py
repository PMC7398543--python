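"""Exception types shared across the package."""


class PatchUnetError(Exception):
    """Base class for all package errors."""


class ValidationError(PatchUnetError, ValueError):
    """Raised when inputs violate a documented precondition."""


class FormatError(PatchUnetError, IOError):
    """Raised when a file cannot be read as the expected image format."""
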