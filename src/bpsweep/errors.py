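"""Exception hierarchy.

All bpsweep-specific failures derive from :class:`BPSweepError` so callers can
catch the whole family; most also derive from :class:`ValueError` because they
signal bad inputs rather than internal faults.
"""


class BPSweepError(Exception):
    """Base class for all bpsweep errors."""


class MalformedInputError(BPSweepError, ValueError):
    """Input data violates a structural invariant (ordering, sign, shape)."""


class InsufficientDataError(BPSweepError, ValueError):
    """Too few observations for the requested operation."""


class SingularDesignError(BPSweepError, ValueError):
    """The sampled timepoints produce a (near-)singular design matrix.

    Signals that the caller should resample timepoints; it is not a fault of
    the data as a whole.
    """


class TrajectoryEscapeError(BPSweepError, RuntimeError):
    """Forward simulation left the configured volume guard bounds."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class NoFitError(BPSweepError, ValueError):
    """Every grid point failed; the accuracy surface has no finite minimum."""


class UndefinedMetricError(BPSweepError, ValueError):
    """The narrowing fraction is undefined (true pair has no finite SSE)."""


class RegionInfeasibleError(BPSweepError, ValueError):
    """Parameter sampling exhausted its retry budget without a viable draw."""


class ConfigurationError(BPSweepError, ValueError):
    """Invalid grid or run configuration (e.g. an empty exponent grid)."""
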