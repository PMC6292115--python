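"""Exception hierarchy.

All failures raised by this package derive from :class:`MutPathError` so
callers can catch one type at pipeline boundaries.
"""


class MutPathError(Exception):
    """Base class for all mutpath errors."""


class ParseError(MutPathError):
    """A file could not be parsed (malformed line, non-numeric cell, ...)."""


class ValidationError(MutPathError):
    """An input violates a domain contract (duplicates, zero variance, ...)."""
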