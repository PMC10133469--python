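"""Named exception types raised across the package."""


class RumenplsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RumenplsError, ValueError):
    """Invalid configuration or input values."""


class SimulationConfigError(ValidationError):
    """Simulation configuration violates its invariants."""


class EmptyFilterError(ValidationError):
    """A prevalence filter removed every genus; lower the threshold."""


class AllZeroSampleError(ValidationError):
    """A sample contains no non-zero counts."""


class NonPositiveEntryError(ValidationError):
    """A composition contains zeros or negative entries; replace zeros first."""


class DomainTotalError(ValidationError):
    """A sample has a zero archaeal or bacterial total count."""


class ColumnMismatchError(ValidationError):
    """Prediction columns do not match the columns a model was trained on."""


class SingleClassError(ValidationError):
    """Discriminant analysis requires exactly two classes."""


class EstimabilityError(ValidationError):
    """Design matrix is rank deficient after constraints."""


class ChainTooShortError(ValidationError):
    """MCMC chain is too short for the requested diagnostic."""
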