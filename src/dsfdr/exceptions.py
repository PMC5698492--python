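"""Exception hierarchy.

All user-facing validation failures raise :class:`ValidationError` (a
``ValueError``), so callers can catch one type for bad inputs while
programming errors still surface as ordinary exceptions.
"""


class ValidationError(ValueError):
    """An input violated a documented precondition or invariant."""


class FormatError(ValidationError):
    """A file could not be parsed as the declared format."""
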