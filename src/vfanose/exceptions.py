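"""Exception hierarchy for vfanose."""


class VfanoseError(Exception):
    """Base class for all vfanose errors."""


class ScheduleError(VfanoseError):
    """Invalid valve-switching schedule (non-alternating, non-increasing, ...)."""


class DegenerateInputError(VfanoseError):
    """Input carries no usable signal (flat curve, empty data, ...)."""


class NoRiseError(VfanoseError):
    """Onset detection found no signal rise; distinct from degenerate input."""


class CurveFormatError(VfanoseError):
    """Malformed curve/labels file; carries a line number when available."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
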