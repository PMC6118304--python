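"""Exception hierarchy.

``InputError`` covers malformed user input (exit code 2 from the CLI);
``NumericalError`` covers numerical failures such as non-PSD kernels or
degenerate data (exit code 3).
"""


class GepredError(Exception):
    """Base class for all package errors."""


class InputError(GepredError, ValueError):
    """Malformed or inconsistent user input."""


class NumericalError(GepredError, ValueError):
    """Numerical problem: asymmetry, negative eigenvalues, degenerate data."""


class NotPSDError(NumericalError):
    """Matrix is not positive semi-definite within tolerance."""


class DegenerateDataError(NumericalError):
    """Data carry no usable signal (e.g. constant phenotype, zero distances)."""
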