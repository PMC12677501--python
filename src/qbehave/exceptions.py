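"""Named errors raised across the package."""


class QBehaveError(Exception):
    """Base class for package errors."""


class UnknownActionError(QBehaveError):
    """An action id or label outside the environment's action set."""


class ShapeMismatchError(QBehaveError):
    """Input array shape incompatible with a network or pipeline contract."""


class DegenerateTargetError(QBehaveError):
    """A regression target with zero variance (e.g. an action never pressed)."""


class DegenerateStatisticError(QBehaveError):
    """A statistic that is undefined on the given data (zero variance, n too small)."""


class ConvergenceError(QBehaveError):
    """Iterative fit failed to converge within the iteration cap."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DivergenceError(QBehaveError):
    """Non-finite loss encountered during agent training."""
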