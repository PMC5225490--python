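"""Exception hierarchy for unitlfp.

All package-specific failures derive from :class:`UnitLfpError` so callers can
catch one base class; subclasses distinguish bad parameters from bad data from
degenerate numerical situations.
"""


class UnitLfpError(Exception):
    """Base class for all unitlfp errors."""


class GeometryError(UnitLfpError):
    """Unmapped channel, empty shells, or other array-layout problems."""


class FormatError(UnitLfpError):
    """A session file/directory is missing a required field or is malformed."""


class ParameterError(UnitLfpError):
    """An argument is outside its valid range (e.g. band beyond Nyquist)."""


class DataError(UnitLfpError):
    """Input arrays contain NaN/Inf or are otherwise unusable."""


class EmptyResultError(UnitLfpError):
    """An operation produced nothing (zero usable spikes, empty selection)."""


class AlignmentError(UnitLfpError):
    """Channel orders of two objects do not match."""


class DegenerateCovarianceError(UnitLfpError):
    """All covariance eigenvalues fell below the regularisation floor."""


class FitError(UnitLfpError):
    """A nonlinear or linear fit could not be performed or did not converge."""


class FeatureError(UnitLfpError):
    """A spike waveform lacks a phase required for feature extraction."""


class ClassificationError(UnitLfpError):
    """Unit classification refused (degenerate feature matrix)."""
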