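"""Exception hierarchy for wpomics."""


class WpomicsError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(WpomicsError):
    """Sample identifiers do not line up across input matrices."""


class ValidationError(WpomicsError):
    """A matrix violates a structural requirement (NaN entries, bad shape, ...)."""


class ZeroVarianceError(ValidationError):
    """A feature column is constant where nonzero variance is required."""


class InsufficientSamplesError(WpomicsError):
    """Too few samples to identify the requested regression model."""


class SingularDesignError(WpomicsError):
    """Rank-deficient design matrix in a least-squares fit."""


class DegenerateRegressorError(WpomicsError):
    """A regressor is constant, so its coefficient is not testable."""


class DomainError(WpomicsError):
    """An argument falls outside its mathematical domain (e.g. p-value > 1)."""
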