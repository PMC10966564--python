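"""Exception hierarchy shared by all analysis stages.

Each analysis stage raises a distinct subclass so that pipeline drivers and
the CLI can map failures to stable exit codes and name the failing stage.
"""


class EvanstimError(Exception):
    """Base class for all package errors."""


class ValidationError(EvanstimError, ValueError):
    """Invalid input value or configuration, detected before computation."""


class NoEvanescentRegime(EvanstimError, ValueError):
    """The requested field is not evanescent (n_eff at or below the cladding
    index, or incidence below the critical angle)."""


class LocalizationFailure(EvanstimError, RuntimeError):
    """Bead localization failed: no dominant blob, divergent fit, or
    amplitude indistinguishable from the background noise."""


class FitFailure(EvanstimError, RuntimeError):
    """A nonlinear or linear fit did not converge or is degenerate."""


class StageError(EvanstimError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str, *, cause: Exception | None = None):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {message}")


#: CLI exit codes, one per error class (0 is success, 1 is an unexpected error).
EXIT_CODES = {
    ValidationError: 2,
    LocalizationFailure: 3,
    FitFailure: 4,
    NoEvanescentRegime: 5,
    StageError: 6,
}
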