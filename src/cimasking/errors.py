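"""Exception hierarchy for the masking-analysis pipeline."""


class CimaskingError(Exception):
    """Base class for all package errors."""


class DomainError(CimaskingError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class AlignmentError(CimaskingError):
    """Masked and unmasked thresholds do not share the same probe places."""

    def __init__(self, message: str, offending_places=()):
        super().__init__(message)
        self.offending_places = tuple(offending_places)


class DegenerateFunctionError(CimaskingError):
    """A shift function is constant and carries no tuning information."""


class ExtrapolationError(CimaskingError):
    """A value was requested outside the measured place span."""


class WindowError(CimaskingError):
    """The analysis window does not intersect the measured span."""


class NoPeakError(CimaskingError):
    """A shift function has no positive peak to fit or locate."""


class UndefinedRatioError(CimaskingError):
    """A difference-measure denominator is zero or non-positive."""


class SafetyLimitError(CimaskingError):
    """An adaptive procedure would exceed the configured maximum level.

    Carries the partial per-sequence (or per-staircase) logs collected up to
    the abort so a session can be audited.
    """

    def __init__(self, message: str, partial_logs=()):
        super().__init__(message)
        self.partial_logs = list(partial_logs)


class ValidationError(CimaskingError):
    """A data table violates the threshold-table schema.

    ``problems`` lists every offending row/column diagnostic, not just the
    first one found.
    """

    def __init__(self, message: str, problems=()):
        self.problems = list(problems)
        detail = "\n  ".join(str(p) for p in self.problems)
        super().__init__(f"{message}\n  {detail}" if detail else message)
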