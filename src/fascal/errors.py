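"""Exception types shared across the package."""


class FascalError(Exception):
    """Base class for all package errors."""


class ValidationError(FascalError):
    """An input violates a documented invariant; the message names the rule."""


class FormatError(FascalError):
    """A file on disk does not conform to the expected layout."""
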