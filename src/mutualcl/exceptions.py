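"""Exception hierarchy shared across the package."""


class MutualCLError(Exception):
    """Base class for all package errors."""


class ValidationError(MutualCLError, ValueError):
    """Malformed or inconsistent input (shape mismatch, bad parameter, ...)."""


class EmptySampleError(ValidationError):
    """An estimator received zero samples."""


class DegenerateCovarianceError(MutualCLError):
    """Effective covariance is singular; the Gaussian density is undefined."""


class MissingClassError(MutualCLError, KeyError):
    """A class required by the computation has no fitted conditional / no samples."""


class SnapshotError(MutualCLError):
    """A teacher snapshot was requested from a model that was never trained."""
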