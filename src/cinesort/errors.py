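"""Exception hierarchy.

Every failure mode the pipeline can signal deliberately derives from
:class:`CineSortError`, so callers (and the CLI) can distinguish data
problems (exit 1) from usage problems (exit 2, handled by click).
"""


class CineSortError(Exception):
    """Base class for all package-specific errors."""


class InsufficientCyclesError(CineSortError):
    """The breathing trace is too short for phase analysis (< 2 cycles / peaks)."""


class ConfigError(CineSortError):
    """Inconsistent or invalid configuration values."""


class PhantomSupportError(CineSortError):
    """Requested z-range or displacement is outside the phantom's support."""


class MaskError(CineSortError):
    """A body or ROI mask is empty or could not be derived."""


class ZeroVarianceError(CineSortError):
    """A similarity index is undefined because a slice has no in-mask variance."""


class ZeroDenominatorError(CineSortError):
    """The normalisation denominator of a boundary index is zero."""


class FlatTraceError(CineSortError):
    """Amplitude error is undefined because the trace has zero amplitude range."""


class RankDeficiencyError(CineSortError):
    """The sinusoidal-series fit is rank deficient (phases clustered; lower K)."""


class SortingError(CineSortError):
    """No feasible candidate selection exists for some couch position / bin."""


class SchemaError(CineSortError):
    """A study bundle on disk does not match the expected schema."""
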