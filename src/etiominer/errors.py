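"""Exception hierarchy shared across the package."""


class EtiominerError(Exception):
    """Base class for all package-specific errors."""


class ConlluParseError(EtiominerError):
    """A CoNLL-U block is malformed (bad column count, bad integer, ...)."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class TreeInvariantError(EtiominerError):
    """A sentence's head links do not form a single rooted acyclic tree."""


class AmbiguousSpanHeadError(EtiominerError):
    """A token span has zero or multiple tokens whose head lies outside it."""


class PatternParseError(EtiominerError):
    """A linearized pattern string cannot be parsed."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"element {position}: {message}"
        super().__init__(message)


class EmptyFingerprintError(EtiominerError):
    """A mention normalizes to the empty string (e.g. all punctuation)."""


class ConfigError(EtiominerError):
    """Invalid generator or pipeline configuration."""
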