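"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`ProtfeatError`, so callers can catch one type at a pipeline
boundary.  The subclasses distinguish the three failure modes the library
recognizes: a file that does not match its dialect, a symbol outside an
alphabet, and a value outside a function's mathematical domain.
"""


class ProtfeatError(Exception):
    """Base class for all errors raised by protfeat."""


class FileFormatError(ProtfeatError, ValueError):
    """Input text does not conform to the expected file dialect."""


class AlphabetError(ProtfeatError, ValueError):
    """A symbol is not legal for the requested alphabet/encoding space."""


class DomainError(ProtfeatError, ValueError):
    """A numeric argument lies outside the function's domain."""


class UndefinedCorrelationError(DomainError):
    """Pearson correlation requested for a zero-variance vector."""


class RecipeError(ProtfeatError, ValueError):
    """A feature recipe references an unknown block or a missing input."""
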