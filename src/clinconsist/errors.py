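"""Exception hierarchy for clinconsist.

All library errors derive from :class:`ClinConsistError` so callers can catch
one base class at pipeline boundaries.
"""

from __future__ import annotations


class ClinConsistError(Exception):
    """Base class for all clinconsist errors."""


class ValidationError(ClinConsistError):
    """One or more records failed validation.

    Attributes
    ----------
    problems : list of (row_number, message)
        1-based file row numbers (header = row 1) with a description of
        what was wrong in each rejected row.
    """

    def __init__(self, message: str, problems: list[tuple[int, str]] | None = None):
        super().__init__(message)
        self.problems: list[tuple[int, str]] = problems or []


class IntegrityError(ClinConsistError):
    """Records that must agree (e.g. within one restoration) conflict."""


class UndefinedStatisticError(ClinConsistError):
    """A statistic was requested on an empty set where it is undefined."""


class ConfigError(ClinConsistError):
    """A simulation or analysis configuration is invalid."""


class DegenerateDataError(ClinConsistError):
    """Data are degenerate for the requested statistical test (e.g. zero
    variance everywhere, or a group with fewer than two values)."""


class PipelineError(ClinConsistError):
    """A pipeline stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
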