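"""Exception types shared across the analysis modules."""


class RetsigError(Exception):
    """Base class for errors raised by this package."""


class DegenerateInputError(RetsigError):
    """Input carries no usable signal (all-zero STA, empty spike train, ...)."""


class EmptyResultError(RetsigError):
    """An operation produced nothing to return (e.g. no usable spikes)."""


class FitError(RetsigError):
    """A nonlinear fit failed to converge.

    Carries ``residual_norm`` when the optimiser got far enough to report one.
    """

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


class CoverageError(RetsigError):
    """A spatial mask required by a metric is empty (e.g. RF fills the frame)."""
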