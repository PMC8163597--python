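"""Experience-group stratification and grouped descriptive statistics.

Students are binned by their total restorations across all years and both
cohorts: group 1 = 40-49, group 2 = 50-59, group 3 = 60-69, group 4 = 70+;
totals below 40 are excluded from group-level analysis. The group table
reports, per group and overall, median (min-max) per-student counts for each
surface class and quadrant, and mean +/- SD difficulty counts and
percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .difficulty import difficult_mask
from .errors import UndefinedStatisticError
from .records import Restoration, SurfaceClass, restorations_to_table

__all__ = ["EXCLUDED", "GROUP_LABELS", "GroupAssignment", "GroupTable",
           "assign_group", "assign_groups", "per_student_counts", "group_descriptives"]

EXCLUDED = "excluded"
GROUP_LABELS = ("1", "2", "3", "4")

_SURFACES = [s.value for s in SurfaceClass]
_QUADRANTS = [1, 2, 3, 4]


@dataclass(frozen=True)
class GroupAssignment:
    student_id: str
    total_restorations: int
    group: str


def assign_group(total_restorations: int) -> str:
    """Experience-group label for a total restoration count.

    40-49 -> "1", 50-59 -> "2", 60-69 -> "3", 70+ -> "4", below 40 ->
    "excluded". Negative totals are an error.
    """
    t = int(total_restorations)
    if t < 0:
        raise ValueError(f"total restorations cannot be negative: {total_restorations}")
    if t < 40:
        return EXCLUDED
    if t < 50:
        return "1"
    if t < 60:
        return "2"
    if t < 70:
        return "3"
    return "4"


def _as_table(restorations) -> pd.DataFrame:
    if isinstance(restorations, pd.DataFrame):
        return restorations
    return restorations_to_table(restorations)


def assign_groups(restorations) -> list[GroupAssignment]:
    """Group assignment per student from their pooled restoration totals."""
    table = _as_table(restorations)
    totals = table.groupby("student_id", sort=True).size()
    return [GroupAssignment(student_id=s, total_restorations=int(t), group=assign_group(t))
            for s, t in totals.items()]


def per_student_counts(restorations) -> pd.DataFrame:
    """Per-student tallies backing the group table.

    One row per student: count per surface class, count per quadrant,
    n_total, n_difficult and pct_difficult. A student's surface counts and
    quadrant counts each sum to their total.
    """
    table = _as_table(restorations)
    if table.empty:
        raise UndefinedStatisticError("no restorations to tally")
    surf = (pd.crosstab(table["student_id"], table["surface"])
            .reindex(columns=_SURFACES, fill_value=0))
    quad = (pd.crosstab(table["student_id"], table["quadrant"])
            .reindex(columns=_QUADRANTS, fill_value=0))
    quad.columns = [f"quadrant_{q}" for q in quad.columns]
    out = surf.join(quad)
    out["n_total"] = table.groupby("student_id").size()
    out["n_difficult"] = (table.assign(difficult=difficult_mask(table))
                          .groupby("student_id")["difficult"].sum().astype(int))
    out["pct_difficult"] = 100.0 * out["n_difficult"] / out["n_total"]
    out["group"] = [assign_group(t) for t in out["n_total"]]
    return out.sort_index()


@dataclass
class GroupTable:
    """Stratified descriptives: tidy numbers plus a display table.

    ``per_student`` holds the per-student tallies (with group labels);
    ``summary`` is tidy numeric (measure, group, stat, value); ``display``
    mirrors the printed layout: rows = measures, columns = groups + Total,
    cells "median (min-max)" or "mean (+/- sd)".
    """

    per_student: pd.DataFrame
    summary: pd.DataFrame
    display: pd.DataFrame
    n_students: dict[str, int]


def _fmt_count(x: float) -> str:
    return f"{x:.0f}" if float(x).is_integer() else f"{x:.1f}"


def group_descriptives(restorations, assignments: Sequence[GroupAssignment] | None = None,
                       *, include_excluded_in_total: bool = False) -> GroupTable:
    """Build the grouped descriptive table.

    Per-student counts are computed first, then group-level median/min/max
    (surfaces, quadrants) and mean +/- sample SD (difficulty count and
    percentage) over the students of each group. Excluded students (<40
    total restorations) appear in no group column and, by default, not in
    the Total column either.
    """
    counts = per_student_counts(restorations)
    if assignments is not None:
        mapping = {a.student_id: a.group for a in assignments}
        counts["group"] = [mapping.get(s, EXCLUDED) for s in counts.index]
    included = counts[counts["group"] != EXCLUDED]
    if included.empty:
        raise UndefinedStatisticError("no students with 40+ restorations to stratify")
    total_pool = counts if include_excluded_in_total else included

    groups = [g for g in GROUP_LABELS if (included["group"] == g).any()]
    pools: dict[str, pd.DataFrame] = {g: included[included["group"] == g] for g in groups}
    pools["Total"] = total_pool

    measures = ([("surface", s) for s in _SURFACES]
                + [("quadrant", q) for q in _QUADRANTS])
    tidy_rows = []
    display: dict[str, dict[str, str]] = {}
    for gname, pool in pools.items():
        col: dict[str, str] = {}
        for section, m in measures:
            key = m if section == "surface" else f"quadrant_{m}"
            vals = pool[key]
            med, lo, hi = float(vals.median()), int(vals.min()), int(vals.max())
            label = f"{section}:{m}"
            tidy_rows += [(label, gname, "median", med), (label, gname, "min", lo),
                          (label, gname, "max", hi)]
            col[label] = f"{_fmt_count(med)} ({lo}-{hi})"
        for label, key, digits in (("difficulty_n", "n_difficult", 2),
                                   ("difficulty_pct", "pct_difficult", 2)):
            mean = float(pool[key].mean())
            sd = float(pool[key].std(ddof=1)) if len(pool) > 1 else 0.0
            tidy_rows += [(label, gname, "mean", mean), (label, gname, "sd", sd)]
            col[label] = f"{mean:.{digits}f} (± {sd:.{digits}f})"
        col["n_students"] = str(len(pool))
        tidy_rows.append(("n_students", gname, "n", float(len(pool))))
        display[gname] = col

    summary = pd.DataFrame(tidy_rows, columns=["measure", "group", "stat", "value"])
    display_df = pd.DataFrame(display)[list(pools)]
    display_df.index.name = "measure"
    return GroupTable(
        per_student=counts,
        summary=summary,
        display=display_df,
        n_students={g: len(p) for g, p in pools.items()},
    )
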