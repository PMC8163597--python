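"""Seeded synthetic-cohort generator for multi-year assessment observations.

The generator emulates the structure of a dental-school workplace-based
assessment database: two graduating cohorts of students observed over clinical
years 3-5, each restoration judged by a single staff member on a 1-6
developmental-indicator (DI) scale at several procedure stages, with a case
mix over five surface classes, four FDI quadrants and eight tooth positions.

Stage DI scores come from a cumulative-link (latent threshold) model: each
stage has a latent performance

    z = mu_year + student_intercept - penalty * difficult - rater_offset + noise

discretized to DIs 1-6 by fixed cut-points, so the DI distribution shifts
upward with year of study. Per-year latent means are calibrated so that the
expected consistency (fraction of restorations with all stage DIs >= 5)
matches configurable per-year targets; the calibration inverts the exact
expectation by Gauss-Hermite quadrature.

One global seed drives all draws; per-student sub-streams are spawned
deterministically, so identical config + seed gives byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import ndtr, roots_hermitenorm

from . import records
from .errors import ConfigError, UndefinedStatisticError
from .records import SurfaceClass, frame_to_observations, Observation

__all__ = [
    "CUTPOINTS",
    "SimulationConfig",
    "difficult_fraction",
    "expected_consistency",
    "simulate_frame",
    "simulate_restorations",
    "simulate_cohorts",
    "summarize_generated",
]

#: Latent cut-points mapping z to DI = 1 + #{c : z > c}. A stage scores
#: DI >= 5 exactly when z > 0, which anchors the independence threshold
#: at latent zero.
CUTPOINTS = (-3.0, -2.0, -1.0, 0.0, 1.0)

_SURFACES = tuple(s.value for s in SurfaceClass)


def _default_surface_probs() -> dict[str, float]:
    # Proportional to typical per-student counts of the five surface classes.
    return {
        "approximal_anterior": 0.18,
        "approximal_posterior": 0.29,
        "incisal_edge": 0.12,
        "smooth_surface": 0.27,
        "occlusal_surface": 0.14,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters.

    Defaults describe a two-cohort school of ~140 students with per-year
    restoration volumes whose medians sit near 16/24/16 for years 3/4/5,
    about 10 +/- 3 distinct supervising staff per student, and per-year
    expected consistency targets of 0.46/0.60/0.76.
    """

    n_students_per_cohort: int = 70
    n_cohorts: int = 2
    years: tuple[int, ...] = (3, 4, 5)
    #: Poisson mean restorations per student for each year of study.
    restorations_per_year: Mapping[int, float] = field(
        default_factory=lambda: {3: 16.0, 4: 24.0, 5: 16.0}
    )
    stages_per_restoration: int = 4
    n_staff_pool: int = 40
    staff_per_student_mean: float = 10.0
    staff_per_student_sd: float = 3.0
    #: SD of the per-student latent ability intercept.
    student_sd: float = 0.25
    #: Target expected consistency per year; inverted to latent year means.
    year_consistency_targets: Mapping[int, float] = field(
        default_factory=lambda: {3: 0.46, 4: 0.60, 5: 0.76}
    )
    #: Explicit latent year means; overrides the targets when given.
    year_latent_effects: Mapping[int, float] | None = None
    #: SD of per-staff hawk/dove severity offsets (hawks positive offsets
    #: subtract from the latent level).
    rater_sd: float = 0.15
    #: SD of the per-stage latent noise.
    di_noise_sd: float = 1.0
    #: Latent penalty applied when a restoration meets the difficulty rule.
    difficulty_penalty: float = 0.3
    surface_probs: Mapping[str, float] = field(default_factory=_default_surface_probs)
    quadrant_probs: tuple[float, ...] = (0.27, 0.29, 0.23, 0.21)
    tooth_position_probs: tuple[float, ...] = (0.15, 0.15, 0.14, 0.14, 0.14, 0.12, 0.10, 0.06)
    #: Probability a restoration is staff-tagged difficult for another reason.
    staff_flag_rate: float = 0.05
    materials: tuple[str, ...] = ("composite", "amalgam", "glass_ionomer")
    material_probs: tuple[float, ...] = (0.60, 0.25, 0.15)
    #: Mean patients per restoration ratio: patient pool size per student is
    #: ceil(total restorations * patient_pool_fraction).
    patient_pool_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_students_per_cohort < 0 or self.n_cohorts < 1:
            raise ConfigError("need n_students_per_cohort >= 0 and n_cohorts >= 1")
        if not self.years:
            raise ConfigError("years must be non-empty")
        if not set(self.years) <= {3, 4, 5}:
            raise ConfigError(f"years must be a subset of {{3,4,5}}, got {self.years}")
        for y in self.years:
            if self.restorations_per_year.get(y, -1) < 0:
                raise ConfigError(f"restorations_per_year missing or negative for year {y}")
        if self.stages_per_restoration < 1:
            raise ConfigError("stages_per_restoration must be >= 1")
        if self.n_staff_pool < 1:
            raise ConfigError("n_staff_pool must be >= 1")
        for name, probs in (
            ("surface_probs", [self.surface_probs.get(s, 0.0) for s in _SURFACES]),
            ("quadrant_probs", self.quadrant_probs),
            ("tooth_position_probs", self.tooth_position_probs),
            ("material_probs", self.material_probs),
        ):
            arr = np.asarray(probs, dtype=float)
            if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name} must be non-negative and sum to 1 (got sum {arr.sum()})")
        if len(self.quadrant_probs) != 4 or len(self.tooth_position_probs) != 8:
            raise ConfigError("quadrant_probs needs 4 entries, tooth_position_probs needs 8")
        if len(self.materials) != len(self.material_probs):
            raise ConfigError("materials and material_probs lengths differ")
        if not 0.0 <= self.staff_flag_rate <= 1.0:
            raise ConfigError("staff_flag_rate must be a probability")
        if self.year_latent_effects is None:
            for y in self.years:
                t = self.year_consistency_targets.get(y)
                if t is None or not 0.0 < t < 1.0:
                    raise ConfigError(f"year_consistency_targets must give a value in (0,1) for year {y}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["restorations_per_year"] = {int(k): float(v) for k, v in self.restorations_per_year.items()}
        d["year_consistency_targets"] = {int(k): float(v) for k, v in self.year_consistency_targets.items()}
        if self.year_latent_effects is not None:
            d["year_latent_effects"] = {int(k): float(v) for k, v in self.year_latent_effects.items()}
        d["surface_probs"] = dict(self.surface_probs)
        d["years"] = list(self.years)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        kwargs = dict(data)
        if "years" in kwargs:
            kwargs["years"] = tuple(int(y) for y in kwargs["years"])
        for key in ("restorations_per_year", "year_consistency_targets", "year_latent_effects"):
            if kwargs.get(key) is not None:
                kwargs[key] = {int(k): float(v) for k, v in kwargs[key].items()}
        for key in ("quadrant_probs", "tooth_position_probs", "material_probs", "materials"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    # -- calibration --------------------------------------------------------

    def resolved_year_effects(self) -> dict[int, float]:
        """Latent per-year means, either explicit or inverted from targets."""
        if self.year_latent_effects is not None:
            return {int(y): float(self.year_latent_effects[y]) for y in self.years}
        p_diff = difficult_fraction(self)
        shift_sd = math.hypot(self.student_sd, self.rater_sd)
        return {
            y: invert_consistency_target(
                self.year_consistency_targets[y],
                stages=self.stages_per_restoration,
                shift_sd=shift_sd,
                noise_sd=self.di_noise_sd,
                penalty=self.difficulty_penalty,
                p_difficult=p_diff,
            )
            for y in self.years
        }


def difficult_fraction(config: SimulationConfig) -> float:
    """Expected fraction of generated restorations meeting the difficulty rule.

    Surface, quadrant, position and the staff tag are drawn independently, so
    P(difficult) = 1 - P(not approximal) P(not upper posterior) P(not tagged).
    """
    p_approx = (config.surface_probs.get("approximal_anterior", 0.0)
                + config.surface_probs.get("approximal_posterior", 0.0))
    p_upper = sum(config.quadrant_probs[:2]) * sum(config.tooth_position_probs[3:])
    return 1.0 - (1.0 - p_approx) * (1.0 - p_upper) * (1.0 - config.staff_flag_rate)


_GH_NODES, _GH_WEIGHTS = roots_hermitenorm(64)
_GH_WEIGHTS = _GH_WEIGHTS / math.sqrt(2.0 * math.pi)


def expected_consistency(mu: float, *, stages: int, shift_sd: float, noise_sd: float,
                         penalty: float, p_difficult: float) -> float:
    """Expected P(all stage DIs >= 5) for latent year mean ``mu``.

    Marginalizes the shared N(0, shift_sd) shift (student intercept + rater
    offset) by Gauss-Hermite quadrature; stage noise is iid N(0, noise_sd)
    so conditional on the shift the stages are independent.
    """
    def branch(delta: float) -> float:
        p = ndtr((mu - delta + shift_sd * _GH_NODES) / noise_sd) ** stages
        return float(p @ _GH_WEIGHTS)

    return (1.0 - p_difficult) * branch(0.0) + p_difficult * branch(penalty)


def invert_consistency_target(target: float, **kwargs) -> float:
    """Latent year mean whose expected consistency equals ``target``."""
    return float(brentq(lambda m: expected_consistency(m, **kwargs) - target, -10.0, 10.0, xtol=1e-10))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _simulate_arrays(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Draw all restoration-level arrays plus the (n, stages) DI matrix.

    Single generative implementation shared by the observation-level and
    restoration-level front ends.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    n_students = cfg.n_cohorts * cfg.n_students_per_cohort
    staff_ss, *student_ss = root.spawn(n_students + 1)

    staff_rng = np.random.default_rng(staff_ss)
    rater_offsets = staff_rng.normal(0.0, cfg.rater_sd, cfg.n_staff_pool)

    year_mu = cfg.resolved_year_effects()
    surface_p = np.array([cfg.surface_probs[s] for s in _SURFACES])
    cuts = np.array(CUTPOINTS)
    k = cfg.stages_per_restoration

    cols: dict[str, list] = {c: [] for c in (
        "student", "cohort", "year", "staff", "patient", "quadrant", "tooth",
        "surface", "material", "flag")}
    di_blocks: list[np.ndarray] = []

    idx = 0
    for ci in range(cfg.n_cohorts):
        for si in range(cfg.n_students_per_cohort):
            rng = np.random.default_rng(student_ss[idx])
            idx += 1
            n_staff = int(np.clip(round(rng.normal(cfg.staff_per_student_mean,
                                                   cfg.staff_per_student_sd)),
                                  1, cfg.n_staff_pool))
            staff_subset = rng.choice(cfg.n_staff_pool, size=n_staff, replace=False)
            intercept = rng.normal(0.0, cfg.student_sd)
            n_by_year = {y: int(rng.poisson(cfg.restorations_per_year[y])) for y in cfg.years}
            total = sum(n_by_year.values())
            pool = max(1, math.ceil(total * cfg.patient_pool_fraction))
            for y in cfg.years:
                n = n_by_year[y]
                if n == 0:
                    continue
                quadrant = rng.choice(4, size=n, p=cfg.quadrant_probs) + 1
                tooth = rng.choice(8, size=n, p=cfg.tooth_position_probs) + 1
                surface = rng.choice(5, size=n, p=surface_p)
                material = rng.choice(len(cfg.materials), size=n, p=cfg.material_probs)
                flag = rng.random(n) < cfg.staff_flag_rate
                staff = staff_subset[rng.integers(0, n_staff, size=n)]
                patient = rng.integers(0, pool, size=n)
                approx = surface <= 1  # first two labels are the approximal classes
                upper = (quadrant <= 2) & (tooth >= 4)
                difficult = approx | upper | flag
                mu = (year_mu[y] + intercept
                      - cfg.difficulty_penalty * difficult
                      - rater_offsets[staff])
                z = mu[:, None] + cfg.di_noise_sd * rng.standard_normal((n, k))
                di = 1 + (z[:, :, None] > cuts).sum(axis=2)
                di_blocks.append(di.astype(np.int64))
                cols["student"].append(np.full(n, ci * cfg.n_students_per_cohort + si))
                cols["cohort"].append(np.full(n, ci))
                cols["year"].append(np.full(n, y))
                cols["staff"].append(staff)
                cols["patient"].append(patient)
                cols["quadrant"].append(quadrant)
                cols["tooth"].append(tooth)
                cols["surface"].append(surface)
                cols["material"].append(material)
                cols["flag"].append(flag)

    if not di_blocks:
        out = {c: np.empty(0, dtype=np.int64) for c in cols}
        out["flag"] = np.empty(0, dtype=bool)
        out["di"] = np.empty((0, k), dtype=np.int64)
        return out
    out = {c: np.concatenate(v) for c, v in cols.items()}
    out["di"] = np.vstack(di_blocks)
    return out


def _student_label(config: SimulationConfig, student: np.ndarray) -> np.ndarray:
    cohort = student // config.n_students_per_cohort if config.n_students_per_cohort else student
    return np.array([f"c{c + 1}s{s % max(config.n_students_per_cohort, 1):03d}"
                     for c, s in zip(cohort, student)], dtype=object)


def _restoration_level_frame(config: SimulationConfig, arr: Mapping[str, np.ndarray]) -> pd.DataFrame:
    n = len(arr["student"])
    student = _student_label(config, arr["student"])
    counter: dict[str, int] = {}
    rest_ids = []
    for s, y in zip(student, arr["year"]):
        key = f"{s}y{y}"
        j = counter.get(key, 0)
        counter[key] = j + 1
        rest_ids.append(f"{key}r{j:03d}")
    return pd.DataFrame({
        "restoration_id": rest_ids,
        "student_id": student,
        "cohort_id": np.array([f"C{c + 1}" for c in arr["cohort"]], dtype=object),
        "year_of_study": arr["year"].astype(int),
        "staff_id": np.array([f"st{int(t):02d}" for t in arr["staff"]], dtype=object),
        "patient_id": np.array([f"{s}p{int(p):02d}" for s, p in zip(student, arr["patient"])],
                               dtype=object),
        "quadrant": arr["quadrant"].astype(int),
        "tooth": arr["tooth"].astype(int),
        "surface": np.array([_SURFACES[i] for i in arr["surface"]], dtype=object),
        "material": np.array([config.materials[i] for i in arr["material"]], dtype=object),
        "staff_difficult_flag": arr["flag"],
    }) if n else pd.DataFrame(columns=[
        "restoration_id", "student_id", "cohort_id", "year_of_study", "staff_id",
        "patient_id", "quadrant", "tooth", "surface", "material", "staff_difficult_flag"])


def simulate_restorations(config: SimulationConfig) -> pd.DataFrame:
    """Simulate directly at restoration level (one row per restoration).

    Same draws as :func:`simulate_frame`; carries ``min_di`` and ``n_stages``
    instead of per-stage rows. This is the fast path for replicate studies.
    """
    arr = _simulate_arrays(config)
    df = _restoration_level_frame(config, arr)
    df["min_di"] = arr["di"].min(axis=1) if len(df) else np.array([], dtype=np.int64)
    df["n_stages"] = config.stages_per_restoration
    return df[records.RESTORATION_COLUMNS]


def simulate_frame(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a full observation-level dataset (one row per stage judgement).

    Deterministic for a fixed config + seed.
    """
    arr = _simulate_arrays(config)
    rest = _restoration_level_frame(config, arr)
    n, k = arr["di"].shape if arr["di"].size else (0, config.stages_per_restoration)
    if n == 0:
        return pd.DataFrame(columns=records.SCHEMA_COLUMNS)
    rep = rest.loc[rest.index.repeat(k)].reset_index(drop=True)
    rep["stage_id"] = np.tile([f"s{m + 1}" for m in range(k)], n)
    rep["di"] = arr["di"].ravel()
    return rep[records.SCHEMA_COLUMNS]


def simulate_cohorts(config: SimulationConfig) -> list[Observation]:
    """Simulate and return validated Observation records."""
    frame = simulate_frame(config)
    if frame.empty:
        return []
    return frame_to_observations(frame)


def summarize_generated(data) -> dict:
    """Summary statistics of a generated dataset.

    Accepts a list of Observations or an observation-level DataFrame; reports
    per-year volume medians, distinct staff per student (mean/sd), surface
    mix fractions, and overall counts.
    """
    if isinstance(data, pd.DataFrame):
        frame = data
    else:
        frame = records.observations_frame(data)
    if frame.empty:
        raise UndefinedStatisticError("cannot summarize an empty dataset")
    rest = records.restorations_table(frame, validate=False)
    per_sy = rest.groupby(["student_id", "year_of_study"], sort=True).size()
    staff_counts = rest.groupby("student_id")["staff_id"].nunique()
    surface_frac = rest["surface"].value_counts(normalize=True).sort_index()
    return {
        "n_observations": int(len(frame)),
        "n_restorations": int(len(rest)),
        "n_students": int(rest["student_id"].nunique()),
        "volume_median_by_year": {int(y): float(v.median())
                                  for y, v in per_sy.groupby("year_of_study")},
        "staff_per_student_mean": float(staff_counts.mean()),
        "staff_per_student_sd": float(staff_counts.std(ddof=1)) if len(staff_counts) > 1 else 0.0,
        "surface_fractions": {k: float(v) for k, v in surface_frac.items()},
    }
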