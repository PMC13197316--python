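"""Exception hierarchy for the breath-profiling pipeline."""


class BreathomicsError(Exception):
    """Base class for all pipeline errors."""


class FormulaError(BreathomicsError):
    """Raised when an elemental formula string cannot be parsed."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class MzmlError(BreathomicsError):
    """Raised for malformed or unusable mzML input."""


class EmptyRunError(MzmlError):
    """Raised when an acquisition contains fewer than two scans."""


class SchemaError(BreathomicsError):
    """Raised when a tabular input or a config violates its schema."""


class CalibrationError(BreathomicsError):
    """Raised when no calibration reference can be located in a run."""


class NoBreathDetectedError(BreathomicsError):
    """Raised when the phase detector finds a degenerate marker trace."""


class PhaseQuantError(BreathomicsError):
    """Raised when an exhalation phase contains no scans."""

    def __init__(self, message: str, phase_index: int | None = None):
        super().__init__(message)
        self.phase_index = phase_index


class ImputationError(BreathomicsError):
    """Raised when a participant column cannot be imputed."""
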