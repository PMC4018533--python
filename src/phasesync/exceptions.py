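"""Labelled error types raised across the pipeline."""


class PhaseSyncError(ValueError):
    """Base class for all pipeline errors."""


class UnknownROIError(PhaseSyncError):
    """A referenced ROI label is not present in the data."""


class WindowError(PhaseSyncError):
    """A time window is empty, misaligned, or outside the epoch."""


class FrequencyGridError(PhaseSyncError):
    """The requested frequency grid is ambiguous or unusable."""


class AllTrialsRejectedError(PhaseSyncError):
    """Amplitude rejection removed every trial; downstream is undefined."""


class InsufficientTrialsError(PhaseSyncError):
    """An operation requires more trials than are available."""


class UndefinedStatisticError(PhaseSyncError):
    """The observed statistic is undefined (e.g. 0/0 WPLI)."""


class ConvergenceError(PhaseSyncError):
    """Numerical model fitting failed to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ModelSpecError(PhaseSyncError):
    """A structural model specification is invalid."""
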