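"""Exception hierarchy shared across the package."""


class MbooiError(Exception):
    """Base class for package errors."""


class ValidationError(MbooiError):
    """An input value violates a domain invariant."""


class MissingDataError(MbooiError):
    """A required measurement or column is absent."""


class UngradeableRecordError(MbooiError):
    """A record cannot be graded (e.g. baseline IPSS total of zero)."""


class SeparationError(MbooiError):
    """Perfect separation detected while fitting a logistic model."""


class AnalysisError(MbooiError):
    """A statistical routine received input it cannot analyse."""
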