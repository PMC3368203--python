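"""Exception hierarchy for fluxmap.

Every error raised deliberately by the package derives from :class:`FluxmapError`,
so callers (and the CLI) can distinguish domain failures from programming bugs.
"""


class FluxmapError(Exception):
    """Base class for all fluxmap domain errors."""


class ConfigurationError(FluxmapError):
    """Invalid configuration value (non-positive baseline, zero subjects, ...)."""


class StructuralError(FluxmapError):
    """Data violates a structural contract (missing phase, length mismatch, ...)."""


class PositivityError(FluxmapError):
    """Generation could not produce a positive perfusion value within the redraw budget."""


class RankDeficiencyError(FluxmapError):
    """Regression design matrix is (numerically) rank deficient."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        #: indices of the offending (collinear) design columns, when identifiable
        self.columns = tuple(columns) if columns is not None else ()


class NoRootError(FluxmapError):
    """Bracketed root search exhausted its expansion without finding a sign change."""

    def __init__(self, message: str, interval=None, k=None):
        super().__init__(message)
        #: the widest interval that was searched
        self.interval = interval
        #: sample index at which the inversion failed, when mapping a series
        self.k = k


class PerfectFitError(FluxmapError):
    """Signal-to-noise ratio is undefined because the error series is identically zero."""
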