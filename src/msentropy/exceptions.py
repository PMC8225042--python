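"""Exception hierarchy.

Two broad families matter for the CLI exit codes: :class:`InputError`
(bad files, bad specs, series too short — exit code 2) and
:class:`NumericError` (domain violations, quadrature failure — exit
code 3).
"""


class MSEntropyError(Exception):
    """Base class for all package errors."""


class InputError(MSEntropyError):
    """User-supplied data or configuration is unusable."""


class InvalidSpecError(InputError, ValueError):
    """A signal specification violates its invariants."""


class UnsupportedExponentError(InvalidSpecError):
    """Spectral exponent outside the supported [0, 2] range."""


class SeriesTooShortError(InputError, ValueError):
    """Series shorter than the embedding requires."""


class InvalidInputError(InputError, ValueError):
    """Non-finite or malformed sample values."""


class ParseError(InputError, ValueError):
    """A text input file could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class EmptyInputError(InputError, ValueError):
    """An input file contained no numeric values."""


class OracleSizeExceededError(InputError, ValueError):
    """Brute-force oracle refused a series too long for quadratic counting."""


class NumericError(MSEntropyError):
    """Numerical computation failed or was requested outside its domain."""


class DomainError(NumericError, ValueError):
    """Argument outside a function's mathematical domain."""


class QuadratureError(NumericError, ArithmeticError):
    """Adaptive quadrature failed to reach the requested accuracy."""
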