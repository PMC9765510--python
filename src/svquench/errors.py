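"""Exception hierarchy for the svquench pipeline."""


class SVQuenchError(Exception):
    """Base class for all pipeline errors."""


class DomainError(SVQuenchError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class UnitMismatchError(SVQuenchError, ValueError):
    """Molar and fold-dilution quantities were mixed in one computation."""


class SchemaError(SVQuenchError, ValueError):
    """A plate or trace file does not conform to the expected schema."""


class InsufficientReplicationError(SVQuenchError, ValueError):
    """Too few blank or control wells to estimate a variance."""


class InvalidBaselineError(SVQuenchError, ValueError):
    """Sensor-only signal is indistinguishable from (or below) the blank."""


class EmptySeriesError(SVQuenchError, ValueError):
    """Every point in a dilution series was excluded."""


class InsufficientPointsError(SVQuenchError, ValueError):
    """Fewer included points than the slope fit requires."""


class RankDeficiencyError(SVQuenchError, ValueError):
    """All quencher concentrations identical; the slope is unidentifiable."""


class FitConvergenceError(SVQuenchError, RuntimeError):
    """A nonlinear fit failed to converge; carries initializer diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
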