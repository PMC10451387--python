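"""Exception hierarchy for the ictsib package.

All package-raised errors derive from :class:`IctsibError` so callers can
catch domain failures without masking programming errors.
"""


class IctsibError(Exception):
    """Base class for all ictsib errors."""


class FormatError(IctsibError):
    """A file does not conform to the expected dialect (missing columns, bad header)."""


class SamplingError(IctsibError):
    """Timestamps are not uniform within tolerance, or sampling rate is invalid."""


class EmptyTrialError(IctsibError):
    """A trial (or frame series) contains too few usable samples."""


class InsufficientDataError(IctsibError):
    """An operation needs more samples than the trial provides."""


class NyquistError(IctsibError):
    """A filter band edge is at or above the Nyquist frequency."""


class DomainError(IctsibError):
    """A parameter is outside its mathematical domain."""


class DegenerateLoadError(IctsibError):
    """A load-cell frame has non-positive total load."""


class UndefinedSpectrumError(IctsibError):
    """A spectrum has zero total band power; percentile frequencies are undefined."""


class CalibrationError(IctsibError):
    """Synthetic-generator calibration targets are jointly infeasible."""


class EmptyReportError(IctsibError):
    """A session report contains no per-condition results."""


class ConfigurationError(IctsibError):
    """Mismatched or missing configuration (e.g. model for a condition)."""


class UndefinedCorrelationError(IctsibError):
    """Pearson correlation is undefined (zero variance in an input vector)."""
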