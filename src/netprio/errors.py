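"""Exception hierarchy.

Validation problems (bad inputs, bad parameters) and runtime problems
(non-convergence) are distinguished so the CLI can map them to distinct
exit codes.
"""


class NetprioError(Exception):
    """Base class for all package errors."""


class ValidationError(NetprioError, ValueError):
    """Invalid input data or out-of-range parameter."""


class ParseError(ValidationError):
    """Malformed input file; carries the offending line number in the message."""


class ConvergenceError(NetprioError, RuntimeError):
    """Iterative solver exhausted its iteration budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
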