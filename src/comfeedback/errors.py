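"""Exception hierarchy for the comfeedback package.

Every contract violation raises a subclass of :class:`ComfeedbackError` so
callers (and the CLI) can catch package errors in one clause.
"""


class ComfeedbackError(Exception):
    """Base class for all package errors."""


# --- dataset / IO -----------------------------------------------------------

class SchemaError(ComfeedbackError):
    """A required column or header key is missing or malformed."""


class SamplingError(ComfeedbackError):
    """The time vector is not uniformly sampled within tolerance."""


class ValidationError(ComfeedbackError):
    """A Trial or Dataset invariant is violated."""


class ImportFormatError(ComfeedbackError):
    """A supplementary .mat file does not match the declared mapping."""


# --- preprocessing ----------------------------------------------------------

class EventDetectionError(ComfeedbackError):
    """Gait events could not be detected (e.g. force never crosses threshold)."""


class EventOrderError(ComfeedbackError):
    """Gait events are out of order or do not alternate."""


class ReferenceBuildError(ComfeedbackError):
    """No usable unperturbed data to build a reference trajectory."""


class PhaseDomainError(ComfeedbackError):
    """A queried phase lies outside the reference domain."""


class NormalizationError(ComfeedbackError):
    """A required normalization constant (MVC / EMG peak) is missing."""


class DelayError(ComfeedbackError):
    """Requested delay is invalid for the given signal."""


# --- identification ---------------------------------------------------------

class ConditioningError(ComfeedbackError):
    """Regressor matrix is (near-)rank-deficient."""

    def __init__(self, message: str, condition_number: float = float("inf")):
        super().__init__(message)
        self.condition_number = condition_number


class InsufficientDataError(ComfeedbackError):
    """Too few usable rows for the requested regression."""


class UndefinedR2Error(ComfeedbackError):
    """Uncentered R^2 undefined because the measured signal is identically zero."""


class DegenerateModulatorError(ComfeedbackError):
    """Gain modulator is identically zero over the fitted samples."""


# --- statistics -------------------------------------------------------------

class DegenerateTestError(ComfeedbackError):
    """Statistical test is degenerate (zero variance, too few pairs)."""


class IncompleteDesignError(ComfeedbackError):
    """Repeated-measures design has missing cells or mismatched subjects."""


# --- simulation -------------------------------------------------------------

class InstabilityError(ComfeedbackError):
    """Closed-loop simulation diverged for the given gains."""
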