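"""Experience-group assignment and grouped descriptive statistics."""

import math

import numpy as np
import pytest

from clinconsist.difficulty import is_difficult
from clinconsist.errors import UndefinedStatisticError
from clinconsist.records import SurfaceClass
from clinconsist.stratify import (
    EXCLUDED,
    assign_group,
    assign_groups,
    group_descriptives,
    per_student_counts,
)
from conftest import make_restoration

SURFACES = list(SurfaceClass)


@pytest.mark.parametrize("total, expected", [
    (0, EXCLUDED), (39, EXCLUDED),          # below 40: excluded from group analysis
    (40, "1"), (49, "1"),
    (50, "2"), (55, "2"), (59, "2"),
    (60, "3"), (69, "3"),
    (70, "4"), (120, "4"),
])
def test_group_bins(total, expected):
    assert assign_group(total) == expected


def test_negative_total_is_an_error():
    with pytest.raises(ValueError):
        assign_group(-1)


def random_cohort(rng, n_students=8, lo=30, hi=90):
    rests = []
    for j in range(n_students):
        for i in range(rng.integers(lo, hi)):
            rests.append(make_restoration(
                min_di=int(rng.integers(1, 7)),
                restoration_id=f"s{j}r{i}", student_id=f"s{j:02d}",
                quadrant=int(rng.integers(1, 5)), tooth=int(rng.integers(1, 9)),
                surface=SURFACES[rng.integers(0, 5)], flag=bool(rng.random() < 0.1),
            ))
    return rests


def test_assignment_uses_pooled_totals_and_partitions_students():
    rng = np.random.default_rng(1)
    rests = random_cohort(rng)
    assignments = assign_groups(rests)
    totals = {}
    for r in rests:
        totals[r.student_id] = totals.get(r.student_id, 0) + 1
    assert {a.student_id: a.total_restorations for a in assignments} == totals
    assert all(a.group == assign_group(a.total_restorations) for a in assignments)


def test_per_student_count_conservation():
    """Surface counts and quadrant counts each sum to the student's total."""
    rng = np.random.default_rng(2)
    counts = per_student_counts(random_cohort(rng))
    surf_cols = [s.value for s in SurfaceClass]
    quad_cols = [f"quadrant_{q}" for q in (1, 2, 3, 4)]
    assert (counts[surf_cols].sum(axis=1) == counts["n_total"]).all()
    assert (counts[quad_cols].sum(axis=1) == counts["n_total"]).all()


def test_singleton_group_statistics():
    rests = ([make_restoration(restoration_id=f"o{i}", quadrant=3) for i in range(3)]
             + [make_restoration(restoration_id=f"m{i}", quadrant=3,
                                 surface=SurfaceClass.SMOOTH_SURFACE) for i in range(2)]
             + [make_restoration(restoration_id=f"f{i}", quadrant=4,
                                 surface=SurfaceClass.INCISAL_EDGE) for i in range(40)])
    table = group_descriptives(rests)
    s = table.summary
    occl = s[(s.measure == "surface:occlusal_surface") & (s.group == "1")]
    assert dict(zip(occl.stat, occl.value)) == {"median": 3.0, "min": 3.0, "max": 3.0}
    assert table.display.loc["surface:occlusal_surface", "1"] == "3 (3-3)"


def test_sample_sd_for_difficulty_cells():
    """Two students with difficulty 40% and 60% -> mean 50.0, sample SD."""
    def student(sid, n_difficult, n_total=50):
        out = []
        for i in range(n_total):
            difficult = i < n_difficult
            out.append(make_restoration(
                restoration_id=f"{sid}r{i}", student_id=sid,
                quadrant=1 if difficult else 3, tooth=6,
                surface=SurfaceClass.OCCLUSAL_SURFACE))
        return out

    table = group_descriptives(student("a", 20) + student("b", 30))
    s = table.summary
    cell = s[(s.measure == "difficulty_pct") & (s.group == "2")]
    stats = dict(zip(cell.stat, cell.value))
    assert stats["mean"] == pytest.approx(50.0)
    assert stats["sd"] == pytest.approx(math.sqrt(((40 - 50) ** 2 + (60 - 50) ** 2) / 1))


def test_excluded_students_in_no_group_column():
    rests = ([make_restoration(restoration_id=f"a{i}", student_id="small") for i in range(10)]
             + [make_restoration(restoration_id=f"b{i}", student_id="big") for i in range(45)])
    table = group_descriptives(rests)
    assert table.n_students == {"1": 1, "Total": 1}
    both = group_descriptives(rests, include_excluded_in_total=True)
    assert both.n_students["Total"] == 2


def test_no_included_students_is_an_error():
    rests = [make_restoration(restoration_id=f"r{i}") for i in range(5)]
    with pytest.raises(UndefinedStatisticError):
        group_descriptives(rests)


def test_descriptives_match_brute_force_recount():
    """Every group cell agrees with an independent per-student tally."""
    rng = np.random.default_rng(3)
    rests = random_cohort(rng, n_students=10)
    table = group_descriptives(rests)

    # independent recount with plain dicts
    tallies = {}
    for r in rests:
        t = tallies.setdefault(r.student_id, {"surface": {}, "quadrant": {}, "total": 0,
                                              "difficult": 0})
        t["surface"][r.surface.value] = t["surface"].get(r.surface.value, 0) + 1
        t["quadrant"][r.site.quadrant] = t["quadrant"].get(r.site.quadrant, 0) + 1
        t["total"] += 1
        t["difficult"] += is_difficult(r)

    groups = {}
    for sid, t in tallies.items():
        g = assign_group(t["total"])
        if g != EXCLUDED:
            groups.setdefault(g, []).append(t)

    s = table.summary
    for g, members in groups.items():
        for surface in SurfaceClass:
            vals = [m["surface"].get(surface.value, 0) for m in members]
            cell = s[(s.measure == f"surface:{surface.value}") & (s.group == g)]
            stats = dict(zip(cell.stat, cell.value))
            assert stats["median"] == pytest.approx(float(np.median(vals)))
            assert stats["min"] == min(vals) and stats["max"] == max(vals)
        for q in (1, 2, 3, 4):
            vals = [m["quadrant"].get(q, 0) for m in members]
            cell = s[(s.measure == f"quadrant:{q}") & (s.group == g)]
            stats = dict(zip(cell.stat, cell.value))
            assert stats["median"] == pytest.approx(float(np.median(vals)))
        pct = [100.0 * m["difficult"] / m["total"] for m in members]
        cell = s[(s.measure == "difficulty_pct") & (s.group == g)]
        stats = dict(zip(cell.stat, cell.value))
        assert stats["mean"] == pytest.approx(float(np.mean(pct)))
        expected_sd = float(np.std(pct, ddof=1)) if len(pct) > 1 else 0.0
        assert stats["sd"] == pytest.approx(expected_sd)
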