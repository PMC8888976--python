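"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class CardioBCGError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CardioBCGError):
    """Invalid parameter values, invariant violations, bad option combinations."""


class AssemblyError(ConfigurationError):
    """The model network cannot be assembled (missing element, bad topology)."""


class DataError(CardioBCGError):
    """Malformed or physically inconsistent input data."""


class NumericalError(CardioBCGError):
    """Solver non-convergence or degenerate numerical problem."""


class FitError(CardioBCGError):
    """Regression cannot be performed (too few points, singular design)."""
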