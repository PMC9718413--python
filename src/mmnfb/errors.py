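"""Exception hierarchy.

All errors raised by the package derive from :class:`MMNFBError` so callers
can catch package failures with a single clause.
"""


class MMNFBError(Exception):
    """Base class for all package errors."""


class ParameterError(MMNFBError, ValueError):
    """An argument is invalid (bad band edges, mismatched lengths, ...)."""


class BoundaryError(MMNFBError):
    """An epoch window falls outside the recorded signal."""


class EstimationError(MMNFBError):
    """An average or estimate was requested from an empty epoch set."""


class CalibrationError(MMNFBError):
    """Maximal-MMN calibration failed or produced an unusable value."""


class ShamError(MMNFBError):
    """Yoked-sham feedback was requested beyond the donor stream."""


class FitError(MMNFBError):
    """A model fit did not converge or its covariance is singular."""


class FormatError(MMNFBError):
    """A file does not conform to the documented CSV/JSON schema."""
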