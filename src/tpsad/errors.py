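"""Exception types shared across the package."""


class TpsadError(Exception):
    """Base class for package errors."""


class ValidationError(TpsadError, ValueError):
    """Input violates a documented precondition or invariant."""


class MissingDataError(TpsadError):
    """A required field (e.g. pre-operative serum PSA) is absent."""


class UndefinedStatisticError(TpsadError):
    """The requested statistic is undefined for this input (e.g. zero tumour volume)."""


class CalibrationError(TpsadError):
    """A simulator calibration target is unreachable with the given parameters."""
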