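"""Typed errors raised across the package."""


class TransportcError(Exception):
    """Base class for all package errors."""


class DataValidationError(TransportcError):
    """A dataset failed structural validation (shape, missingness, types)."""


class NonBinaryOutcomeError(DataValidationError):
    """The outcome column contains values other than 0 and 1."""


class MissingValueError(DataValidationError):
    """Missing values in columns used by the analysis."""


class MissingColumnError(DataValidationError):
    """A required column is absent from the input."""


class DegenerateOutcomeError(TransportcError):
    """All outcomes are 0 or all are 1; the model cannot be fitted."""


class CollinearPredictorsError(TransportcError):
    """The design matrix is rank deficient."""


class SpecMismatchError(TransportcError):
    """Dataset columns do not match the model's predictor names."""


class UndefinedCStatisticError(TransportcError):
    """The c-statistic needs at least one event and one non-event."""
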