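"""Errors raised by the estimation pipeline."""


class WeightMSMError(RuntimeError):
    """Base class for pipeline errors."""


class SpecificationError(WeightMSMError):
    """A model specification references missing columns or deficient factor levels."""


class PositivityViolation(WeightMSMError):
    """A denominator probability fell below the positivity floor."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = rows


class UnestimableModel(WeightMSMError):
    """A model could not be fit (empty category, no events, or non-convergence)."""
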