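"""Statistical comparisons.

Three stages mirror the study design around the consistency statistic:

* a two-sample Kolmogorov-Smirnov check that the two cohorts share a
  distribution (pooling them when p > alpha),
* a one-way ANOVA of per-student yearly consistency across years of study,
  with Bonferroni-adjusted pairwise Welch t-tests and mean differences on
  the percentage scale,
* the Pearson correlation between total restorations and final-year
  consistency, with the least-squares line.

The ANOVA treats the years as independent groups — one value per student
per year — deliberately ignoring the repeated-measures structure; the
replicate helpers at the bottom quantify power and type-I behaviour of that
choice on synthetic cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consistency import StudentYearSummary, student_year_table
from .errors import DegenerateDataError
from .synthetic import SimulationConfig, simulate_restorations

__all__ = [
    "TestResult",
    "YearEffectResult",
    "bonferroni",
    "ks_cohort_check",
    "year_effect_anova",
    "volume_consistency_correlation",
    "year_effect_detection_rate",
    "anova_type_one_error",
]


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome."""

    name: str
    statistic: float
    p_value: float
    labels: tuple[str, ...] = ()
    alpha: float = 0.05
    adjusted: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p); never below the raw p."""
    return min(1.0, m * p)


def ks_cohort_check(sample_a: Sequence[float], sample_b: Sequence[float], *,
                    alpha: float = 0.05, labels: tuple[str, str] = ("A", "B"),
                    method: str = "auto") -> TestResult:
    """Two-sample K-S comparison of per-student values between cohorts.

    D = sup |ECDF_A - ECDF_B|; the exact p-value is used for small samples
    (both n <= 25), the asymptotic one otherwise. ``extra['pool']`` records
    the pooling decision (pool iff p > alpha).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateDataError("K-S comparison requires two non-empty samples")
    if method == "auto":
        method = "exact" if max(a.size, b.size) <= 25 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return TestResult(
        name="kolmogorov_smirnov",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        labels=tuple(labels),
        alpha=alpha,
        extra={"pool": bool(res.pvalue > alpha), "n": [int(a.size), int(b.size)],
               "method": method},
    )


@dataclass(frozen=True)
class YearEffectResult:
    """Omnibus ANOVA plus Bonferroni pairwise comparisons across years."""

    anova: TestResult
    pairwise: tuple[TestResult, ...]
    #: Mean consistency difference per pair, in percentage points.
    mean_differences_pct: Mapping[str, float]
    group_means: Mapping[int, float]

    def to_dict(self) -> dict:
        return {
            "anova": self.anova.to_dict(),
            "pairwise": [t.to_dict() for t in self.pairwise],
            "mean_differences_pct": dict(self.mean_differences_pct),
            "group_means": {str(k): v for k, v in self.group_means.items()},
        }


def _year_groups(values) -> dict[int, np.ndarray]:
    if isinstance(values, Mapping):
        return {int(y): np.asarray(v, dtype=float) for y, v in values.items()}
    if isinstance(values, pd.DataFrame):
        return {int(y): g["consistency"].to_numpy(dtype=float)
                for y, g in values.groupby("year_of_study")}
    groups: dict[int, list[float]] = {}
    for s in values:
        if not isinstance(s, StudentYearSummary):
            raise TypeError("expected StudentYearSummary items, a mapping, or a DataFrame")
        groups.setdefault(int(s.year_of_study), []).append(s.consistency)
    return {y: np.asarray(v, dtype=float) for y, v in groups.items()}


def year_effect_anova(values, *, alpha: float = 0.05) -> YearEffectResult:
    """Year-of-study effect on per-student yearly consistency.

    ``values`` may be StudentYearSummary items, a {year: values} mapping, or
    a student-year DataFrame. One-way ANOVA across years, then Welch t-tests
    for every year pair with Bonferroni adjustment (m = number of pairs);
    mean differences are reported in percentage points of consistency.
    """
    groups = _year_groups(values)
    if len(groups) < 2:
        raise DegenerateDataError("ANOVA requires at least two years of study")
    for y, g in groups.items():
        if g.size < 2:
            raise DegenerateDataError(f"year {y} has fewer than two values")
    if all(np.ptp(g) == 0 for g in groups.values()) and len({g[0] for g in groups.values()}) == 1:
        raise DegenerateDataError("all consistency values identical; F is undefined")
    years = sorted(groups)
    f_stat, p = stats.f_oneway(*(groups[y] for y in years))
    anova = TestResult(name="one_way_anova", statistic=float(f_stat), p_value=float(p),
                       labels=tuple(f"year {y}" for y in years), alpha=alpha,
                       extra={"n": [int(groups[y].size) for y in years]})
    pairs = list(combinations(years, 2))
    pairwise = []
    diffs: dict[str, float] = {}
    means = {y: float(groups[y].mean()) for y in years}
    for y1, y2 in pairs:
        t, raw_p = stats.ttest_ind(groups[y2], groups[y1], equal_var=False)
        label = f"{y1} vs {y2}"
        pairwise.append(TestResult(
            name="welch_t_bonferroni", statistic=float(t),
            p_value=bonferroni(float(raw_p), len(pairs)),
            labels=(f"year {y1}", f"year {y2}"), alpha=alpha, adjusted=True,
            extra={"raw_p": float(raw_p), "m": len(pairs)},
        ))
        diffs[label] = 100.0 * (means[y2] - means[y1])
    return YearEffectResult(anova=anova, pairwise=tuple(pairwise),
                            mean_differences_pct=diffs, group_means=means)


def volume_consistency_correlation(totals: Sequence[float],
                                   consistencies: Sequence[float], *,
                                   alpha: float = 0.05) -> TestResult:
    """Pearson correlation of total restorations vs final-year consistency.

    Also fits the least-squares line (slope, intercept in ``extra``) for the
    volume-vs-consistency scatter.
    """
    x = np.asarray(totals, dtype=float)
    y = np.asarray(consistencies, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateDataError("correlation requires >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined when a variable has zero variance")
    r, p = stats.pearsonr(x, y)
    line = stats.linregress(x, y)
    return TestResult(
        name="pearson_correlation", statistic=float(r), p_value=float(p),
        labels=("total restorations", "final-year consistency"), alpha=alpha,
        extra={"slope": float(line.slope), "intercept": float(line.intercept),
               "n": int(x.size)},
    )


# ---------------------------------------------------------------------------
# Replicate studies on synthetic cohorts
# ---------------------------------------------------------------------------


def _replicate_seeds(seed: int, n: int) -> list[int]:
    # Derived seeds stay below 2**31 so they can round-trip through any tool.
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def year_effect_detection_rate(config: SimulationConfig | None = None, *,
                               n_replicates: int = 200, seed: int = 0,
                               p_threshold: float = 1e-3,
                               di_threshold: int = 5) -> float:
    """Fraction of simulated cohorts in which the ANOVA detects the year effect.

    Each replicate simulates a full multi-year cohort from ``config`` (default
    configuration if None), computes per-student yearly consistencies, and
    runs the omnibus ANOVA; a detection is p < ``p_threshold``.
    """
    base = config or SimulationConfig()
    hits = 0
    for s in _replicate_seeds(seed, n_replicates):
        rest = simulate_restorations(replace(base, seed=s))
        table = student_year_table(rest, di_threshold)
        result = year_effect_anova(table)
        hits += result.anova.p_value < p_threshold
    return hits / n_replicates


def anova_type_one_error(config: SimulationConfig | None = None, *,
                         n_replicates: int = 500, seed: int = 1,
                         alpha: float = 0.05, di_threshold: int = 5) -> float:
    """Empirical type-I error of the ANOVA stage under zero year effect.

    Simulates under the test's own null — independent, identically
    distributed per-student values in every year group. Two generator
    features are therefore switched off in the null design because they
    violate the one-way ANOVA's independence assumption rather than encode
    a year effect: the shared per-student intercept (which correlates a
    student's values across years and makes the test conservative) is
    avoided by drawing each year group as a separate single-year cohort,
    and hawk/dove rater offsets (which are shared across the students of a
    cohort through the finite staff pool and inflate between-group
    variance) are set to zero. Returns the fraction of replicates rejecting
    at ``alpha``.
    """
    base = config or SimulationConfig()
    base = replace(base, rater_sd=0.0)
    years = sorted(base.years)
    target = base.year_consistency_targets[years[0]]
    volume = base.restorations_per_year[years[0]]
    rejections = 0
    seeds = _replicate_seeds(seed, n_replicates * len(years))
    for i in range(n_replicates):
        groups = {}
        for j, y in enumerate(years):
            cfg = replace(base, years=(3,), restorations_per_year={3: volume},
                          year_consistency_targets={3: target},
                          seed=seeds[i * len(years) + j])
            rest = simulate_restorations(cfg)
            groups[y] = student_year_table(rest, di_threshold)["consistency"].to_numpy()
        result = year_effect_anova(groups)
        rejections += result.anova.p_value < alpha
    return rejections / n_replicates
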