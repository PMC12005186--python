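"""Exception hierarchy.

All user-facing failures derive from :class:`CGLineError` so callers (and the
CLI) can catch one type.  Parse errors carry the offending position in the
input text whenever it is known.
"""


class CGLineError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(CGLineError):
    """Malformed notation text."""

    def __init__(self, message, position=None, text=None):
        self.position = position
        self.text = text
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class ResolutionError(CGLineError):
    """A coarse graph could not be refined with the given fragments."""


class AromaticityError(CGLineError):
    """Aromatic flags could not be normalized unambiguously."""


class WildcardError(CGLineError):
    """Invalid or unresolved wildcard / selection annotation."""


class SamplerError(CGLineError):
    """The stochastic growth loop could not reach its target."""


class FingerprintError(CGLineError):
    """Missing bead types or malformed interaction table."""
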