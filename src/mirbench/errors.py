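"""Exception hierarchy for mirbench.

All errors raised on bad user input derive from :class:`MirbenchError` so
callers can catch one type; they also derive from ``ValueError`` where the
failure is an invalid argument, matching numpy/pandas conventions.
"""


class MirbenchError(Exception):
    """Base class for all mirbench errors."""


class InvalidArgumentError(MirbenchError, ValueError):
    """An argument violates a documented precondition."""


class GenerationError(MirbenchError, RuntimeError):
    """Synthetic pool generation could not satisfy its constraints."""


class InsufficientDepthError(MirbenchError, ValueError):
    """A subsampling target exceeds the number of available reads."""


class EmptyLibraryError(MirbenchError, ValueError):
    """A count table has zero assigned depth where depth > 0 is required."""


class DataConsistencyError(MirbenchError, KeyError):
    """Cross-referenced tables disagree on their reference universe."""


class DegenerateVarianceError(MirbenchError, ValueError):
    """A statistical test is undefined because both samples are constant."""


class StandardCurveError(MirbenchError, ValueError):
    """A qPCR standard curve is unusable (e.g. non-negative slope)."""
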