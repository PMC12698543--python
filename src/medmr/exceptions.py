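"""Exception hierarchy for medmr.

All medmr-specific failures derive from :class:`MedMRError` so callers can
catch the package's errors with a single except clause.
"""


class MedMRError(Exception):
    """Base class for all medmr errors."""


class SchemaError(MedMRError):
    """A summary-statistics table is missing a mandatory column."""


class EmptyInputError(MedMRError):
    """An input table or family contained no usable rows."""


class MissingLDError(MedMRError):
    """A candidate variant shares a chromosome with another candidate but is
    absent from the supplied LD matrix."""


class InsufficientInstrumentsError(MedMRError):
    """An estimator was asked to run with fewer instruments than it needs."""


class UndefinedRatioError(MedMRError):
    """Wald ratio requested with a zero exposure effect."""


class DegenerateDesignError(MedMRError):
    """All exposure effects are zero; the IVW design matrix has no signal."""


class DegenerateVarianceError(MedMRError):
    """Paired differences have zero variance; the t statistic is undefined.

    Carries ``mean_diff`` so the caller still learns the mean difference.
    """

    def __init__(self, message: str, mean_diff: float = 0.0):
        super().__init__(message)
        self.mean_diff = mean_diff


class InsufficientDataError(MedMRError):
    """Not enough observations (or missing allele frequency with tiny n)."""


class DomainError(MedMRError):
    """A numeric argument is outside its mathematical domain."""
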