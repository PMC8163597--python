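# Methods

## The measurement problem

Workplace-based assessment systems in clinical training record one judgement
per procedure stage on an ordinal developmental-indicator (DI) scale of
learner independence (1 = unable even with help … 5 = independent at the
required quality, 6 = exceeds it). Counting procedures completed to an
acceptable standard ("count : quality") does not reveal how performance
develops, so this package implements a longitudinal statistic, consistency:

* a restoration counts as *placed independently* when the **minimum** stage DI
  is at or above the independence threshold (DI 5 by default);
* a student's consistency **C** over a period is the fraction of their
  restorations placed independently.

C is the mean of binary indicators, so C ∈ [0, 1], it is permutation
invariant, monotone non-increasing in the threshold, and pooled-cohort C
equals the volume-weighted mean of per-student C values. An empty restoration
set has no consistency; the library raises rather than returning 0.

Around the statistic sit: a binary case-mix difficulty rule (approximal
surface, OR upper posterior tooth — FDI quadrant 1–2, position 4–8 — OR a
staff "difficult" tag; a restoration satisfying several clauses counts once);
experience groups on pooled totals (40–49, 50–59, 60–69, 70+; totals under 40
are excluded from group-level analysis); and three statistical stages
(two-sample Kolmogorov–Smirnov cohort check, one-way ANOVA of per-student
yearly consistency across years with Bonferroni-adjusted Welch pairwise
tests, and the Pearson correlation of total volume against final-year
consistency with its least-squares line).

## Units of analysis and deliberate simplifications

The ANOVA takes one consistency value per student per year and treats the
years as independent groups. Students contribute to every year, so the data
are really repeated measures; the independent-groups ANOVA mirrors the
classical analysis this package reproduces and is kept deliberately. Because
the within-student correlation shrinks true between-year noise relative to
the within-group mean square, this choice is conservative for detecting a
year effect. Mixed-effects growth modelling is out of scope.

"Overall consistency" can be computed two ways: pooling a student's
restorations across years (`pool_years=True`) or averaging their yearly
values. Per-student yearly values are the default unit for the ANOVA; the
pooled per-student variant feeds the cohort K-S check and the volume
correlation (which uses all students with final-year data, not only
group-included ones).

## The synthetic cohort generator

No real assessment database ships with the package; a seeded generator
produces datasets with the structure the analysis assumes, so every stage is
testable end to end.

Stage scores come from a cumulative-link (latent threshold) model. Each stage
of a restoration has latent performance

    z = μ_year + a_student − λ·difficult − r_staff + ε,   ε ~ N(0, σ_e)

discretized by fixed cut-points (−3, −2, −1, 0, 1) to DI 1–6, so a stage is
independent (DI ≥ 5) exactly when z > 0. Components:

| parameter | default | meaning |
|---|---|---|
| `a_student` (`student_sd`) | SD 0.25 | stable per-student ability intercept |
| `λ` (`difficulty_penalty`) | 0.3 | latent penalty when the restoration meets the difficulty rule |
| `r_staff` (`rater_sd`) | SD 0.15 | per-staff hawk/dove severity offset, shared across a restoration's stages (one rater per occasion) |
| `σ_e` (`di_noise_sd`) | 1.0 | per-stage noise |
| `stages_per_restoration` | 4 | criterion-referenced stages per procedure |

Cohort structure defaults: 2 cohorts × 70 students; Poisson restoration
volumes with means 16/24/16 for years 3/4/5 (medians ≈ 16/24/16); a staff
pool of 40 with each student seeing a clipped-normal 10 ± 3 subset;
case mix proportional to typical per-student counts over the five surface
classes (0.18/0.29/0.12/0.27/0.14), quadrants (0.27/0.29/0.23/0.21), a mildly
anterior-weighted tooth-position distribution, and a 5% staff-tag rate.
Under these independent draws the expected difficult fraction is
1 − P(not approximal)·P(not upper posterior)·P(not tagged) ≈ 0.65 — higher
than real cohorts tend to show, because real surface/site combinations are
not independent; the generator makes no attempt to model that dependence.

**Calibration.** Rather than exposing raw latent year means, the config takes
per-year expected-consistency targets (defaults 0.46/0.60/0.76; the spread of
per-student values arises naturally from the variance components above). At
config resolution the exact expectation

    E[C](μ) = E_d E_u [ Φ((μ − λd + u)/σ_e)^k ],  u ~ N(0, √(σ_s² + σ_r²))

(d the Bernoulli difficulty draw, k the stage count) is inverted for μ by
Gauss–Hermite quadrature (64 nodes) and Brent root finding; the test suite
checks that simulated per-year mean consistencies track the targets.

**Determinism.** One global seed feeds a `SeedSequence`; one child stream
draws the staff-pool offsets and one per student drives all of that student's
draws. Identical config + seed gives byte-identical CSV output. The
observation-level and restoration-level front ends share a single generative
core, so the fast restoration-level path used in replicate studies is the
same draw as the full observation table.

**What the generator does not emulate:** case-mix dependence between surface,
site and patient; drift in rater behaviour over time; within-student learning
inside a year; informative volume (ability-dependent caseload); patient
covariates. Passing tests therefore demonstrate correctness of the analysis
pipeline and sane statistical behaviour under the stated model — not validity
claims about any real cohort.

## Replicate studies: power and type-I behaviour

`year_effect_detection_rate` simulates full multi-year cohorts at the default
calibration (targets 0.46/0.60/0.76, 140 students) and reports the fraction
of replicates in which the omnibus ANOVA attains p < 0.001. The shared
student intercept is retained there; it only helps detection.

`anova_type_one_error` estimates the test's size under zero year effect. A
valid size calculation must simulate under the ANOVA's own null — independent,
identically distributed values in every group — so two generator features are
switched off in the null design because they violate independence rather than
encode a year effect:

* the per-student intercept is decorrelated across groups by drawing each
  year group as an independent single-year cohort (keeping it would correlate
  groups and make the test conservative);
* hawk/dove rater offsets are zeroed, because all students of a cohort share
  the realized finite staff pool, which correlates values *within* a group
  and inflates the between-group mean square (an anti-conservative cluster
  effect).

With those removed the empirical rejection rate at α = 0.05 sits at the
nominal level (the acceptance suite checks 5% ± 3 points over 500 seeded
replicates). The cluster sensitivity itself is a real property of one-way
ANOVA on programmatic-assessment data worth knowing about: shared raters can
masquerade as group effects.

## Numerical and edge-case choices

* Sample (n−1) standard deviations in every "± SD" cell.
* Experience-group totals pool all years and both cohorts; by default the
  "Total" column covers included students only (a flag adds the excluded).
* The K-S p-value is exact when both samples have ≤ 25 values, asymptotic
  otherwise (cohorts are ~70). Pooling is recommended when p > α (0.05).
* Bonferroni adjustment is min(1, m·p) with m the number of year pairs;
  pairwise tests are Welch (unequal-variance) t-tests.
* Degenerate inputs raise typed errors: empty sets for consistency or
  difficulty, a year with < 2 values or all-identical values for the ANOVA,
  zero variance for the correlation.
* Stage order within a restoration is lexicographic `stage_id`; only the
  minimum matters downstream, so ordering never affects results.
* A missing `staff_difficult_flag` parses as false (the tag marks exceptional
  added difficulty).
* Pipeline behaviour on small inputs: data-integrity failures abort with the
  stage name; statistical stages whose preconditions the data cannot meet
  (one cohort, one year, < 3 paired values) are reported as skipped with the
  reason, so a minimal fixture still yields a complete report.
* All pipeline outputs are deterministic: JSON is written with sorted keys
  and the run log carries no timestamps, so reruns are byte-identical.

## Problem sizes used in the test suite

Unit and property tests run on small constructed inputs and 6–20-student
cohorts. The acceptance suite uses the full default cohort size (140
students): 200 replicates for the power study and 500 for the size study,
which completes in well under two minutes via the restoration-level
simulation path.
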