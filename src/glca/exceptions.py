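"""Exception types raised by the glca package."""


class GlcaError(Exception):
    """Base class for all package-specific errors."""


class DomainError(GlcaError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DimensionError(GlcaError, ValueError):
    """A vector or array has a length inconsistent with the model dimension."""


class DegenerateCovarianceError(GlcaError, ValueError):
    """The transition covariance is not positive definite.

    Typically signals a zero lag (the transition density degenerates to a
    product of delta functions) or invalid parameters.
    """


class SimulationDivergedError(GlcaError, RuntimeError):
    """A simulated trajectory left the admissible region (|x| > bound)."""

    def __init__(self, series_index: int, step: int, bound: float):
        self.series_index = series_index
        self.step = step
        self.bound = bound
        super().__init__(
            f"series {series_index} diverged at step {step}: |x| exceeded {bound:g} "
            "(unstable parameter regime?)"
        )


class NonUniformGridError(GlcaError, ValueError):
    """A time grid is not uniformly spaced, so the single-lag likelihood is undefined."""


class InsufficientDataError(GlcaError, ValueError):
    """Too few converged fits to aggregate."""


class SeriesFormatError(GlcaError, ValueError):
    """A series file violates the CSV/sidecar contract."""
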