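"""Package-wide exception types."""


class PepchargeError(Exception):
    """Base class for all pepcharge errors."""


class InvalidHarmonicError(ValueError, PepchargeError):
    """Harmonic order is not an odd positive integer."""


class InsufficientDataError(ValueError, PepchargeError):
    """Fewer data points/harmonics than an operation requires."""


class UndefinedRatioError(ZeroDivisionError, PepchargeError):
    """Dissipation-to-frequency ratio undefined (zero normalized shift)."""


class DegenerateNormalizationError(ValueError, PepchargeError):
    """Isotherm normalization denominator is (numerically) zero."""


class DegenerateFitError(ValueError, PepchargeError):
    """Fit input carries no signal (e.g. all-zero potential and charge)."""


class NonUniformGridError(ValueError, PepchargeError):
    """Profile z-grid is not uniform; resample before integrating."""


class PipelineError(PepchargeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
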