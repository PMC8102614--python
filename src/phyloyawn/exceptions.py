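"""Exception hierarchy used across the package.

Exit-code mapping in the CLI: InputError subclasses -> 2,
ConvergenceError -> 3, everything else -> 1.
"""


class PhyloYawnError(Exception):
    """Base class for all package errors."""


class InputError(PhyloYawnError):
    """Invalid or malformed user input."""


class FormatError(InputError):
    """A delimited file is missing required structure (e.g. a column)."""


class EmptyInputError(InputError):
    """An input file or table contained no usable rows."""


class DomainError(InputError):
    """A numeric argument is outside its mathematical domain."""


class InsufficientDataError(InputError):
    """Too few species for the requested analysis to be identifiable."""


class DegenerateDataError(InputError):
    """Data with no variation where variation is required."""


class CollinearityError(InputError):
    """A design matrix is rank deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class ConvergenceError(PhyloYawnError):
    """MCMC run failed its convergence gate; carries the diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
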