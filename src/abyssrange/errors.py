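"""Exception hierarchy shared across the pipeline.

Validation problems (bad rows, bad config) are distinguished from stage
failures so the CLI can map them onto distinct exit codes.
"""


class AbyssRangeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AbyssRangeError):
    """A required option, column or parameter is missing or inconsistent."""


class ValidationError(AbyssRangeError):
    """Input data violates a documented invariant.

    ``rows`` optionally carries the offending 1-based row numbers.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class AlignmentFormatError(AbyssRangeError):
    """Sequence input is not a valid alignment (ragged rows, duplicate ids)."""


class UndefinedStatisticError(AbyssRangeError):
    """A statistic was requested on input too small to define it."""


class StageError(AbyssRangeError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
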