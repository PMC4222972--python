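"""Exception hierarchy shared across the pipeline stages."""


class BandlocError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(BandlocError):
    """Head-model geometry is inconsistent (radii order, sources outside shells...)."""


class FormatError(BandlocError):
    """A file's contents do not match the declared dimensions or value domain."""


class ParameterError(BandlocError):
    """A parameter is outside its admissible range."""


class ProcessingError(BandlocError):
    """A processing step cannot produce a valid result (e.g. all trials rejected)."""


class ReferenceStateError(BandlocError):
    """Data or operator is not in the reference convention the operation requires."""


class UndefinedBaselineError(BandlocError):
    """Baseline power is zero or unavailable at some frequency."""


class BaselineInfeasibleError(BandlocError):
    """The wavelet support does not fit inside the baseline window at this frequency."""


class NumericalError(BandlocError):
    """A numerically invalid intermediate (non-positive standardization, singular solve)."""


class ConvergenceError(BandlocError):
    """A truncated series has not converged to the requested tolerance."""
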