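# clinconsist

Consistency analytics for longitudinal workplace-based clinical assessment
records.

Dental schools (and health-professions programmes generally) accumulate large
databases of low-stakes observations: every stage of every procedure a
student performs is scored by a supervising staff member on an ordinal
developmental-indicator (DI) scale of independence, where DI 5 means "able to
do this independently at the required quality". Progression decisions are
often justified by procedure counts alone. This package implements the
analysis toolkit for asking whether counts are enough: a per-student
**consistency** statistic, a case-mix **difficulty** rule, experience-group
stratification, and the statistical comparisons that relate them — together
with a seeded synthetic-cohort simulator so the whole pipeline is testable
without access to any real (patient-derived) database.

## The statistic

For a restoration with stage scores DI₁…DI_k, define the independence
indicator

    I = 1  if min(DI₁…DI_k) ≥ θ,   else 0        (θ = 5 by default)

A student's consistency over a period with n restorations is

    C = (Σ I) / n ∈ [0, 1]

For example, ten restorations whose lowest stage DIs are
4, 3, 5, 5, 6, 6, 4, 5, 4, 6 give the indicator string 0,0,1,1,1,1,0,1,0,1
and C = 6/10 = 0.6.

A restoration is classed **difficult** if it is approximal, on an upper
posterior tooth (FDI quadrant 1–2, position 4–8), or staff-tagged difficult.
Students are stratified by pooled totals into experience groups 40–49, 50–59,
60–69 and 70+ (totals below 40 are excluded from group analysis). The
comparison stages are a two-sample Kolmogorov–Smirnov cohort check, a one-way
ANOVA of per-student yearly consistency across years of study with
Bonferroni-adjusted Welch pairwise tests, and the Pearson correlation of
total volume against final-year consistency. See `docs/methods.md` for the
model behind the simulator and all numerical choices.

## Worked example

```python
from clinconsist import (AnalysisConfig, Restoration, SurfaceClass, ToothSite,
                         consistency_score)

lowest_dis = [4, 3, 5, 5, 6, 6, 4, 5, 4, 6]
restorations = [
    Restoration(restoration_id=f"r{i}", student_id="s1", cohort_id="C1",
                year_of_study=5, staff_id="st1", patient_id=f"p{i % 3}",
                site=ToothSite(quadrant=3, position=6),
                surface=SurfaceClass.OCCLUSAL_SURFACE,
                staff_difficult_flag=False, stage_dis=(d, 6))
    for i, d in enumerate(lowest_dis)
]
print(consistency_score(restorations, AnalysisConfig(di_threshold=5)))
```

prints `0.6`: six of the ten restorations have every stage at DI 5 or above.

Running the full pipeline on a simulated two-cohort school (140 students,
years 3–5):

```python
from clinconsist import SimulationConfig, run_pipeline
report = run_pipeline("results/demo", sim_config=SimulationConfig(seed=17))
print(report["consistency_by_year"])
```

```
{'3':   {'mean': 0.465611, 'sd': 0.180231, 'median_restorations': 16.0},
 '4':   {'mean': 0.588515, 'sd': 0.154966, 'median_restorations': 23.0},
 '5':   {'mean': 0.756605, 'sd': 0.144486, 'median_restorations': 15.0},
 'All': {'mean': 0.600038, 'sd': 0.130579, 'median_restorations': 56.0}}
```

Mean consistency rises from 0.47 in year 3 to 0.76 in year 5 while the
restoration volume stays modest — the year effect is in quality, not counts.
The same run reports 4 of 140 students excluded from grouping (< 40 total
restorations), a K-S cohort check supporting pooling (D = 0.157, p = 0.32),
an omnibus year effect (F = 115.8, p < 10⁻⁴⁰) with pairwise consistency gains
of 12.3 (year 3→4) and 16.8 (year 4→5) percentage points, and a weak,
non-significant volume–consistency correlation (r = −0.08, p = 0.32). The
output directory contains `summaries.csv`, `difficulty.csv`, `table2.csv`,
`table3.csv`, `tests.json` and `run.log`.

The same workflow is available from a shell:

```sh
clinconsist simulate --seed 17 --out cohort.csv
clinconsist pipeline --in cohort.csv --out results/
clinconsist consistency --in cohort.csv --threshold 5 --out summaries.csv
```

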