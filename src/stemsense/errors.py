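"""Exception hierarchy shared across the package."""


class StemSenseError(Exception):
    """Base class for all stemsense errors."""


class InvalidArgumentError(StemSenseError, ValueError):
    """An argument violates a precondition (non-positive length, bad rate...)."""


class OrderingError(StemSenseError, ValueError):
    """A sequence that must be sorted by encoder (or by position) is not."""


class FormatError(StemSenseError, ValueError):
    """A value violates a structural constraint (angle span, field count...)."""


class ParseError(StemSenseError, ValueError):
    """A log file row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NoTreeLineError(StemSenseError, RuntimeError):
    """Tree-line estimation found no points in any node window."""


class CalibrationError(StemSenseError, ValueError):
    """Threshold calibration was given too few samples."""


class StatisticsError(StemSenseError, ValueError):
    """A statistic requires more observations than were provided."""


class ConsistencyError(StemSenseError, ValueError):
    """Cross-referenced inputs disagree (e.g. a detection without a status)."""
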