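"""Exception hierarchy for phenofill."""


class PhenofillError(Exception):
    """Base class for all phenofill errors."""


class InvalidInputError(PhenofillError):
    """Inputs violate a precondition (non-finite values, mismatched shapes...)."""


class InsufficientDataError(PhenofillError):
    """Too few valid observations to fit a model."""


class NumericalError(PhenofillError):
    """Linear-algebra conditioning failure that jitter could not rescue."""


class TrainingFailureError(PhenofillError):
    """All optimizer restarts failed; carries per-restart diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class UndefinedResultError(PhenofillError):
    """A statistic is undefined for the given inputs (no overlap, zero range)."""


class ConfigError(PhenofillError):
    """Invalid or incomplete run configuration."""
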