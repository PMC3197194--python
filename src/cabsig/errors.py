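"""Exception hierarchy shared across the toolkit.

Every error raised on bad user input derives from :class:`CabsigError`, so
callers (and the CLI) can distinguish domain failures from bugs.
"""


class CabsigError(Exception):
    """Base class for all toolkit errors."""


class MatrixFormatError(CabsigError):
    """Malformed expression-matrix file (duplicates, ragged rows, bad cells)."""


class UnknownIDError(CabsigError, KeyError):
    """A requested gene or sample ID is not present."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return CabsigError.__str__(self)


class SignatureTooSmallError(CabsigError):
    """Fewer than two usable signature genes."""


class DegenerateInputError(CabsigError):
    """Input on which the requested statistic is undefined (constant vector,
    empty filter result, single-gene matrix, ...)."""


class NoInformationError(CabsigError):
    """A paired test was requested but every difference is zero."""
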