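"""Case-mix difficulty classification.

A restoration is classed as relatively difficult when any of three clauses
fires: it is approximal (either approximal surface class), it sits on an
upper posterior tooth (FDI quadrant 1 or 2, positions 4-8), or the
supervising staff member tagged it difficult for another reason. Each
student's difficulty exposure is the number of difficult restorations and
that number as a percentage of all their restorations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import UndefinedStatisticError
from .records import Restoration, SurfaceClass

__all__ = ["DifficultySummary", "is_difficult", "difficulty_summary",
           "summarize_difficulty", "difficult_mask"]


@dataclass(frozen=True)
class DifficultySummary:
    """Difficulty exposure for one student."""

    student_id: str
    n_total: int
    n_difficult: int

    def __post_init__(self):
        if not 0 <= self.n_difficult <= self.n_total or self.n_total < 1:
            raise ValueError("need 1 <= n_total and 0 <= n_difficult <= n_total")

    @property
    def pct_difficult(self) -> float:
        return 100.0 * self.n_difficult / self.n_total


def is_difficult(restoration: Restoration) -> bool:
    """Binary difficulty rule: approximal OR upper posterior OR staff tag."""
    return (restoration.surface.is_approximal
            or restoration.site.is_upper_posterior
            or restoration.staff_difficult_flag)


def difficult_mask(rest_table: pd.DataFrame) -> pd.Series:
    """Vectorized difficulty rule over a restoration-level table."""
    approximal = rest_table["surface"].isin(
        [SurfaceClass.APPROXIMAL_ANTERIOR.value, SurfaceClass.APPROXIMAL_POSTERIOR.value])
    upper_posterior = rest_table["quadrant"].isin([1, 2]) & rest_table["tooth"].between(4, 8)
    return approximal | upper_posterior | rest_table["staff_difficult_flag"].astype(bool)


def difficulty_summary(restorations: Sequence[Restoration]) -> DifficultySummary:
    """Counts and percentage of difficult restorations for one student.

    A restoration satisfying several clauses (e.g. staff-tagged and
    approximal) is counted once. All restorations must belong to the same
    student.
    """
    if len(restorations) == 0:
        raise UndefinedStatisticError("difficulty is undefined on an empty restoration set")
    students = {r.student_id for r in restorations}
    if len(students) > 1:
        raise ValueError(f"restorations span several students: {sorted(students)}")
    n_difficult = sum(1 for r in restorations if is_difficult(r))
    return DifficultySummary(student_id=restorations[0].student_id,
                             n_total=len(restorations), n_difficult=n_difficult)


def summarize_difficulty(restorations: Sequence[Restoration]) -> list[DifficultySummary]:
    """One DifficultySummary per student, sorted by student id."""
    by_student: dict[str, list[Restoration]] = {}
    for r in restorations:
        by_student.setdefault(r.student_id, []).append(r)
    return [difficulty_summary(by_student[s]) for s in sorted(by_student)]
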