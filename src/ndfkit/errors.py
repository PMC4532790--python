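"""Exception hierarchy shared across the package."""


class NdfkitError(Exception):
    """Base class for all package errors."""


class InputError(NdfkitError, ValueError):
    """Malformed or inconsistent user input (shapes, labels, file contents)."""


class NumericalError(NdfkitError, ArithmeticError):
    """A numerical failure (non-PSD covariance, singular system, loglik decrease)."""


class ConvergenceError(NumericalError):
    """An iterative routine failed to converge within its budget."""
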