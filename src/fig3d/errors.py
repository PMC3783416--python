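"""Exception types shared across the package.

Exit-code mapping used by the CLI: ValidationError -> 1, ParseError -> 2.
"""


class Fig3DError(Exception):
    """Base class for all package errors."""


class ValidationError(Fig3DError, ValueError):
    """Invalid argument or contract violation on otherwise well-formed data."""


class ParseError(Fig3DError, ValueError):
    """Malformed input file or byte stream."""
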