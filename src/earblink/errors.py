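"""Exception hierarchy.

Distinct classes let the CLI map failure modes to distinct exit codes
(parse vs configuration vs data errors).
"""


class EarBlinkError(Exception):
    """Base class for all package errors."""


class DegenerateEyeError(EarBlinkError):
    """Eye-corner distance is zero: the aspect ratio is undefined."""


class CalibrationError(EarBlinkError):
    """Threshold calibration impossible (no valid frames, degenerate widths)."""


class AnnotationParseError(EarBlinkError):
    """Malformed annotation or landmark file; carries line context."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ConfigError(EarBlinkError):
    """Invalid or infeasible run/simulation configuration."""


class DataError(EarBlinkError):
    """Inconsistent or insufficient data (disjoint indices, single-class truth)."""


class UndefinedAUCError(DataError):
    """ROC AUC undefined: ground truth contains a single class."""
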