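"""Exception hierarchy shared across the package."""


class EmergepdError(Exception):
    """Base class for package errors."""


class InvalidParameterError(EmergepdError, ValueError):
    """A model or solver parameter violates its constraints."""


class InvalidInputError(EmergepdError, ValueError):
    """Input data violate a precondition (negative concentration, unordered times, ...)."""


class DataConsistencyError(EmergepdError, ValueError):
    """Cross-record inconsistency, e.g. regained response recorded before loss of response."""


class DegenerateFitError(EmergepdError, ValueError):
    """A model fit is impossible, e.g. only one outcome class present."""


class SeparationWarning(UserWarning):
    """Emitted when a logistic fit shows (quasi-)complete separation and did not converge."""
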