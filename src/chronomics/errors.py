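"""Typed exceptions shared across the package."""


class ChronomicsError(Exception):
    """Base class for all package errors."""


class FormatError(ChronomicsError):
    """A file could not be parsed into a valid domain object."""


class ValidationError(ChronomicsError):
    """An in-memory object or parameter violates its invariants."""
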