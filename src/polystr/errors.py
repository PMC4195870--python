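"""Exception hierarchy for polystr.

All data-level failures raise :class:`PolystrError` subclasses so callers
(and the CLI) can distinguish bad input from programming errors.
"""


class PolystrError(Exception):
    """Base class for all polystr data errors."""


class ParseError(PolystrError):
    """Malformed input file; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DataError(PolystrError):
    """Inconsistent data (e.g. VCF ref allele disagrees with the assembly)."""


class ConfigError(PolystrError):
    """Invalid configuration values."""
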