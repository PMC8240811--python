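"""Exception hierarchy shared across modules."""


class JunctionLabError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(JunctionLabError):
    """A sequence contains a character outside {A, C, G, T, N}."""


class ParseError(JunctionLabError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(JunctionLabError):
    """An argument or record violates a documented precondition."""


class GenerationError(JunctionLabError):
    """A synthetic construct cannot be placed with the requested parameters."""


class UnresolvableJunctionError(JunctionLabError):
    """A junction consensus could not be anchored to both reference flanks."""


class DegenerateTestError(JunctionLabError):
    """A statistical test is undefined for the given inputs (zero variance)."""
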