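"""Exception hierarchy shared across the analysis modules."""


class SalibenchError(Exception):
    """Base class for all package errors."""


class ParameterError(SalibenchError, ValueError):
    """A generator or model parameter violates its invariants."""


class ExtrapolationError(SalibenchError, ValueError):
    """A query point lies outside the measured range; no silent extrapolation."""


class AlignmentError(SalibenchError, ValueError):
    """Replicate curves do not share a common grid (or there are too few)."""


class FitError(SalibenchError, RuntimeError):
    """A model fit failed to converge or produced an inconsistent result."""


class AnalysisError(SalibenchError, RuntimeError):
    """A derived analysis (profile, plateau, saturation) has no valid window."""


class SegmentationError(AnalysisError):
    """A friction curve lacks the structure needed for regime segmentation."""
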