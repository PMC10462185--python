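"""Exception hierarchy for homtest."""


class HomtestError(Exception):
    """Base class for all homtest errors."""


class FormatError(HomtestError):
    """Input file or table does not conform to the expected layout."""


class StudyValidationError(HomtestError):
    """Study content violates a structural invariant (groups, duplicates, ...)."""


class PairExtractionError(HomtestError):
    """An adjacent-time-point pair cannot be formed."""


class SingularDesignError(HomtestError):
    """The regression design matrix is rank deficient.

    Parameters
    ----------
    message : str
        Human-readable diagnostic.
    column : str or None
        Name of the (first) design column implicated in the collinearity.
    """

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class InsufficientDataError(HomtestError):
    """Too few animals for the requested degrees of freedom."""


class NoClosedFormError(HomtestError):
    """No closed-form power expression exists for the requested setting."""
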