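"""Exception hierarchy for pcssreg.

All package errors derive from :class:`PcssError` so callers can catch one
base class at a workflow boundary.
"""


class PcssError(Exception):
    """Base class for all pcssreg errors."""


class SummaryValidationError(PcssError):
    """A summary set violates a structural invariant (symmetry, PSD, ...)."""


class VariableMismatchError(PcssError):
    """Summary sets being combined do not share the same variable list."""


class DuplicateLabelError(PcssError):
    """Two summary sets carry the same (cohort, stratum) label."""


class UnknownVariableError(PcssError):
    """A referenced variable name is not present in the summary set."""


class NameCollisionError(PcssError):
    """A derived variable name collides with an existing variable."""


class InsufficientSampleSizeError(PcssError):
    """Model fit requested with n <= p + 1."""


class InsufficientCellError(PcssError):
    """A cohort x stratum cell has fewer than 2 observations."""


class ZeroVariancePredictorError(PcssError):
    """A model predictor has zero sample variance."""


class SingularDesignError(PcssError):
    """The predictor covariance block is numerically singular."""


class NonNestedModelError(PcssError):
    """F-test requested for models that are not nested."""


class SchemaError(PcssError):
    """A PCSS file violates the on-disk schema."""
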