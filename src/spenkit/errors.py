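"""Exception hierarchy for spenkit."""


class SpenError(Exception):
    """Base class for all spenkit errors."""


class InvalidDesignError(SpenError, ValueError):
    """A pulse or encoding design violates its constraints."""


class CalibrationError(SpenError, RuntimeError):
    """Numeric flip-angle calibration failed to converge.

    Carries the residual flip-angle error (rad) in ``residual``.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class CorrectionError(SpenError, RuntimeError):
    """Bandwidth correction did not converge within the iteration cap."""


class TimingError(SpenError, ValueError):
    """A sequence timing constraint (e.g. requested TE) cannot be met."""


class RankDeficientError(SpenError, RuntimeError):
    """Unregularized normal equations are numerically singular."""


class PulseqParseError(SpenError, ValueError):
    """Malformed .seq file; ``line`` holds the 1-based offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class UnsupportedPulseqFeatureError(SpenError, ValueError):
    """A .seq file uses a section outside the supported subset."""
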