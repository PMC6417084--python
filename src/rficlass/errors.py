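"""Exceptions raised across the pipeline."""


class RficlassError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RficlassError):
    """Invalid simulation or run configuration."""


class SingularFitError(RficlassError):
    """Rank-deficient regression design; names the offending covariate."""


class EstimabilityError(RficlassError):
    """A factor-combination cell required by a contrast is empty."""


class InfeasibleSelectionError(RficlassError):
    """A design cell is too small for the requested extreme selection."""


class SampleError(RficlassError):
    """A sample violates a precondition (e.g. zero library size)."""


class ValidationError(RficlassError):
    """Input files violate the expected schema."""
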