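"""The consistency statistic.

A restoration counts as placed independently when its lowest stage DI meets
the independence threshold (DI 5 by default: "able to do this independently
at the required quality"). A student's consistency C over a period is the
fraction of their restorations placed independently; e.g. ten restorations
with lowest stage DIs 4, 3, 5, 5, 6, 6, 4, 5, 4, 6 give the indicator string
0, 0, 1, 1, 1, 1, 0, 1, 0, 1 and C = 6/10 = 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import UndefinedStatisticError
from .records import DI_MAX, DI_MIN, Restoration, restorations_to_table

__all__ = [
    "AnalysisConfig",
    "StudentYearSummary",
    "independence_indicator",
    "consistency_score",
    "summarize_student_years",
    "student_year_table",
    "cumulative_consistency_distribution",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis parameters; ``di_threshold`` is the independence reference."""

    di_threshold: int = 5

    def __post_init__(self):
        if not DI_MIN <= self.di_threshold <= DI_MAX:
            raise ValueError(f"di_threshold must be in {DI_MIN}..{DI_MAX}")


_DEFAULT = AnalysisConfig()


@dataclass(frozen=True)
class StudentYearSummary:
    """Per student, per year of study: volume and consistency.

    ``year_of_study`` is None for the pooled (all-years) variant.
    """

    student_id: str
    cohort_id: str
    year_of_study: int | None
    n_restorations: int
    n_independent: int

    def __post_init__(self):
        if not 0 <= self.n_independent <= self.n_restorations:
            raise ValueError("need 0 <= n_independent <= n_restorations")
        if self.n_restorations < 1:
            raise ValueError("a summary needs at least one restoration")

    @property
    def consistency(self) -> float:
        return self.n_independent / self.n_restorations


def independence_indicator(restoration: Restoration, config: AnalysisConfig = _DEFAULT) -> int:
    """1 if the restoration's lowest stage DI is at/above the threshold, else 0."""
    return 1 if restoration.min_di >= config.di_threshold else 0


def consistency_score(restorations: Sequence[Restoration], config: AnalysisConfig = _DEFAULT) -> float:
    """Mean independence indicator over a non-empty list of restorations."""
    if len(restorations) == 0:
        raise UndefinedStatisticError("consistency is undefined on an empty restoration set")
    return sum(independence_indicator(r, config) for r in restorations) / len(restorations)


def student_year_table(rest_table: pd.DataFrame, di_threshold: int = 5, *,
                       pool_years: bool = False) -> pd.DataFrame:
    """Vectorized per-student(-year) consistency over a restoration table.

    Returns one row per (student, year) — or per student when pooling —
    with n_restorations, n_independent and consistency columns.
    """
    keys = ["student_id", "cohort_id"] + ([] if pool_years else ["year_of_study"])
    g = (rest_table.assign(independent=rest_table["min_di"] >= di_threshold)
         .groupby(keys, sort=True)
         .agg(n_restorations=("min_di", "size"), n_independent=("independent", "sum"))
         .reset_index())
    g["consistency"] = g["n_independent"] / g["n_restorations"]
    if pool_years:
        g.insert(2, "year_of_study", pd.NA)
    return g


def summarize_student_years(restorations: Sequence[Restoration],
                            config: AnalysisConfig = _DEFAULT, *,
                            pool_years: bool = False) -> list[StudentYearSummary]:
    """One summary per (student, year of study) with at least one restoration.

    The grouping partitions the input, so summed volumes equal the input
    size. With ``pool_years=True`` a single all-years summary per student is
    produced (the "overall consistency" variant).
    """
    table = restorations_to_table(restorations)
    if table.empty:
        return []
    rows = student_year_table(table, config.di_threshold, pool_years=pool_years)
    return [
        StudentYearSummary(
            student_id=r.student_id,
            cohort_id=r.cohort_id,
            year_of_study=None if pool_years else int(r.year_of_study),
            n_restorations=int(r.n_restorations),
            n_independent=int(r.n_independent),
        )
        for r in rows.itertuples()
    ]


def cumulative_consistency_distribution(summaries: Sequence[StudentYearSummary],
                                        year: int) -> list[tuple[float, float]]:
    """Empirical cumulative distribution of consistency for one year of study.

    Returns (consistency level, cumulative % of students at or below that
    level) at each distinct observed level; percentages are non-decreasing
    and end at 100.
    """
    values = sorted(s.consistency for s in summaries if s.year_of_study == year)
    if not values:
        raise UndefinedStatisticError(f"no summaries for year {year}")
    n = len(values)
    out = []
    for level in sorted(set(values)):
        cum = sum(1 for v in values if v <= level)
        out.append((level, 100.0 * cum / n))
    return out
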