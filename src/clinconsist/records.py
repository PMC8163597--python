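"""Domain types, validation and CSV I/O for observation-level assessment data.

The atomic record is an :class:`Observation`: one staff judgement, on a six
point developmental-indicator (DI) scale of learner independence, of one stage
of one direct restoration placed by one student. Observations sharing a
``restoration_id`` are assembled into a :class:`Restoration`, the unit on
which the consistency and difficulty statistics operate.

The canonical interchange format is a UTF-8 CSV with one row per
stage-observation and the header::

    student_id,cohort_id,year_of_study,staff_id,patient_id,restoration_id,
    stage_id,di,quadrant,tooth,surface,material,staff_difficult_flag

Booleans are serialized as ``true``/``false``; tooth sites use FDI notation as
two columns (quadrant 1-4, position 1-8), with a reader dialect option for
two-digit FDI codes ("16" = quadrant 1, position 6).

A :class:`pandas.DataFrame` with these columns is the in-memory bulk
container; lists of dataclasses are the validated row-level view.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import IntegrityError, ValidationError

__all__ = [
    "DI_MIN",
    "DI_MAX",
    "SCHEMA_COLUMNS",
    "SurfaceClass",
    "ToothSite",
    "Observation",
    "Restoration",
    "read_observations",
    "write_observations",
    "observations_frame",
    "frame_to_observations",
    "assemble_restorations",
    "restorations_table",
    "restorations_to_table",
]

DI_MIN = 1
DI_MAX = 6

#: Canonical CSV column order.
SCHEMA_COLUMNS = [
    "student_id",
    "cohort_id",
    "year_of_study",
    "staff_id",
    "patient_id",
    "restoration_id",
    "stage_id",
    "di",
    "quadrant",
    "tooth",
    "surface",
    "material",
    "staff_difficult_flag",
]

#: Context fields that must agree across all observations of one restoration.
_RESTORATION_CONTEXT = [
    "student_id",
    "cohort_id",
    "year_of_study",
    "staff_id",
    "patient_id",
    "quadrant",
    "tooth",
    "surface",
    "material",
    "staff_difficult_flag",
]

_VALID_YEARS = (3, 4, 5)


class SurfaceClass(str, enum.Enum):
    """The five most common direct-restoration surface classes."""

    APPROXIMAL_ANTERIOR = "approximal_anterior"
    APPROXIMAL_POSTERIOR = "approximal_posterior"
    INCISAL_EDGE = "incisal_edge"
    SMOOTH_SURFACE = "smooth_surface"
    OCCLUSAL_SURFACE = "occlusal_surface"

    @property
    def is_approximal(self) -> bool:
        """True for either approximal class (a surface between adjacent teeth)."""
        return self in (SurfaceClass.APPROXIMAL_ANTERIOR, SurfaceClass.APPROXIMAL_POSTERIOR)


def validate_di(value: int) -> int:
    """Check an integer is a valid developmental indicator (1-6) and return it."""
    v = int(value)
    if v != value or not DI_MIN <= v <= DI_MAX:
        raise ValueError(f"DI must be an integer in {DI_MIN}..{DI_MAX}, got {value!r}")
    return v


@dataclass(frozen=True)
class ToothSite:
    """A tooth location in FDI notation.

    quadrant 1-4 (1 upper right, 2 upper left, 3 lower left, 4 lower right);
    position 1-8 from central incisor to third molar.
    """

    quadrant: int
    position: int

    def __post_init__(self):
        if self.quadrant not in (1, 2, 3, 4):
            raise ValueError(f"quadrant must be 1-4, got {self.quadrant!r}")
        if self.position not in range(1, 9):
            raise ValueError(f"tooth position must be 1-8, got {self.position!r}")

    @property
    def is_upper_posterior(self) -> bool:
        """Upper posterior tooth: quadrant 1 or 2, positions 4-8."""
        return self.quadrant in (1, 2) and 4 <= self.position <= 8

    @classmethod
    def from_fdi(cls, code: int | str) -> "ToothSite":
        """Parse a two-digit FDI tooth code, e.g. ``"16"`` -> quadrant 1, position 6."""
        s = str(code).strip()
        if len(s) != 2 or not s.isdigit():
            raise ValueError(f"not a two-digit FDI tooth code: {code!r}")
        return cls(quadrant=int(s[0]), position=int(s[1]))


def _as_surface(value) -> SurfaceClass:
    if isinstance(value, SurfaceClass):
        return value
    try:
        return SurfaceClass(str(value))
    except ValueError:
        labels = ", ".join(s.value for s in SurfaceClass)
        raise ValueError(f"unknown surface label {value!r}; expected one of: {labels}") from None


@dataclass(frozen=True)
class Observation:
    """One staff judgement on one stage of one restoration."""

    student_id: str
    cohort_id: str
    year_of_study: int
    staff_id: str
    patient_id: str
    restoration_id: str
    stage_id: str
    di: int
    site: ToothSite
    surface: SurfaceClass
    material: str = ""
    staff_difficult_flag: bool = False

    def __post_init__(self):
        for name in ("student_id", "cohort_id", "staff_id", "patient_id", "restoration_id", "stage_id"):
            if not str(getattr(self, name)):
                raise ValueError(f"{name} must be non-empty")
        if self.year_of_study not in _VALID_YEARS:
            raise ValueError(f"year_of_study must be one of {_VALID_YEARS}, got {self.year_of_study!r}")
        validate_di(self.di)
        object.__setattr__(self, "surface", _as_surface(self.surface))


@dataclass(frozen=True)
class Restoration:
    """An assembled procedure: shared context plus its ordered stage DI scores."""

    restoration_id: str
    student_id: str
    cohort_id: str
    year_of_study: int
    staff_id: str
    patient_id: str
    site: ToothSite
    surface: SurfaceClass
    staff_difficult_flag: bool
    stage_dis: tuple[int, ...]
    material: str = ""

    def __post_init__(self):
        if len(self.stage_dis) == 0:
            raise ValueError("stage_dis must be non-empty")
        for d in self.stage_dis:
            validate_di(d)
        object.__setattr__(self, "surface", _as_surface(self.surface))

    @property
    def min_di(self) -> int:
        """The lowest stage DI — the score that decides independence."""
        return min(self.stage_dis)


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:  # missing flag means "not exceptionally difficult"
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def _load_dialect(dialect) -> dict:
    """Resolve a dialect (mapping, YAML/JSON path, or None) to a dict.

    Recognized keys: ``rename`` (file column -> schema column) and
    ``fdi_tooth`` (name of a two-digit FDI tooth-code column that replaces
    the quadrant/tooth pair).
    """
    if dialect is None:
        return {}
    if isinstance(dialect, Mapping):
        return dict(dialect)
    path = Path(dialect)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def _row_to_observation(row: Mapping) -> Observation:
    return Observation(
        student_id=str(row["student_id"]).strip(),
        cohort_id=str(row["cohort_id"]).strip(),
        year_of_study=int(row["year_of_study"]),
        staff_id=str(row["staff_id"]).strip(),
        patient_id=str(row["patient_id"]).strip(),
        restoration_id=str(row["restoration_id"]).strip(),
        stage_id=str(row["stage_id"]).strip(),
        di=int(row["di"]),
        site=ToothSite(quadrant=int(row["quadrant"]), position=int(row["tooth"])),
        surface=_as_surface(row["surface"]),
        material=str(row.get("material", "") or ""),
        staff_difficult_flag=_parse_bool(row.get("staff_difficult_flag", False)),
    )


def frame_to_observations(df: pd.DataFrame, *, first_data_row: int = 2) -> list[Observation]:
    """Validate a schema-shaped DataFrame row by row into Observations.

    Raises :class:`ValidationError` naming every rejected row (row numbers
    are file-style: header = row 1, first data row = ``first_data_row``).
    """
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns and c != "material"]
    if missing:
        raise ValidationError(f"missing required columns: {', '.join(missing)}")
    observations: list[Observation] = []
    problems: list[tuple[int, str]] = []
    for pos, (_, row) in enumerate(df.iterrows()):
        try:
            observations.append(_row_to_observation(row))
        except (ValueError, TypeError, KeyError) as exc:
            problems.append((pos + first_data_row, str(exc)))
    if problems:
        detail = "; ".join(f"row {n}: {msg}" for n, msg in problems[:10])
        more = "" if len(problems) <= 10 else f" (+{len(problems) - 10} more)"
        raise ValidationError(f"{len(problems)} invalid rows: {detail}{more}", problems)
    return observations


def read_observations(path, dialect=None) -> list[Observation]:
    """Read and validate an observations CSV.

    Parameters
    ----------
    path : path-like
        CSV file in the canonical schema (or mappable to it via *dialect*).
    dialect : mapping or path, optional
        Schema dialect: ``rename`` maps file columns to schema columns;
        ``fdi_tooth`` names a two-digit FDI tooth-code column used instead
        of separate quadrant/tooth columns.

    Returns the validated observations; raises :class:`ValidationError` with
    file row numbers if any row is malformed.
    """
    d = _load_dialect(dialect)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if d.get("rename"):
        df = df.rename(columns=d["rename"])
    fdi_col = d.get("fdi_tooth")
    if fdi_col:
        if fdi_col not in df.columns:
            raise ValidationError(f"dialect names FDI tooth column {fdi_col!r} but it is absent")
        sites = df[fdi_col].astype(str).str.strip()
        df = df.assign(quadrant=sites.str[:1], tooth=sites.str[1:2])
    return frame_to_observations(df)


def observations_frame(observations: Iterable[Observation]) -> pd.DataFrame:
    """Arrange observations into the canonical schema-shaped DataFrame."""
    rows = {c: [] for c in SCHEMA_COLUMNS}
    for o in observations:
        rows["student_id"].append(o.student_id)
        rows["cohort_id"].append(o.cohort_id)
        rows["year_of_study"].append(o.year_of_study)
        rows["staff_id"].append(o.staff_id)
        rows["patient_id"].append(o.patient_id)
        rows["restoration_id"].append(o.restoration_id)
        rows["stage_id"].append(o.stage_id)
        rows["di"].append(o.di)
        rows["quadrant"].append(o.site.quadrant)
        rows["tooth"].append(o.site.position)
        rows["surface"].append(o.surface.value)
        rows["material"].append(o.material)
        rows["staff_difficult_flag"].append(o.staff_difficult_flag)
    return pd.DataFrame(rows, columns=SCHEMA_COLUMNS)


def write_frame(df: pd.DataFrame, path) -> None:
    """Write a schema-shaped DataFrame as canonical CSV (booleans true/false)."""
    out = df.copy()
    flags = out["staff_difficult_flag"]
    if flags.dtype != object or not flags.isin(["true", "false"]).all():
        out["staff_difficult_flag"] = flags.map(lambda b: "true" if _parse_bool(b) else "false")
    out.to_csv(path, index=False, columns=SCHEMA_COLUMNS, lineterminator="\n")


def write_observations(observations: Iterable[Observation], path) -> None:
    """Write observations to canonical CSV; inverse of :func:`read_observations`."""
    write_frame(observations_frame(observations), path)


# ---------------------------------------------------------------------------
# Restoration assembly
# ---------------------------------------------------------------------------


def assemble_restorations(observations: Sequence[Observation]) -> list[Restoration]:
    """Group observations by restoration_id into Restorations.

    Stage DIs are ordered by lexicographic ``stage_id`` (the downstream
    consistency statistic depends only on the minimum, so ordering never
    changes results). All context fields must agree within a restoration —
    one student, one site, one surface, one staff member per occasion —
    otherwise :class:`IntegrityError` names the offending restoration.
    Input is not mutated.
    """
    groups: dict[str, list[Observation]] = {}
    for o in observations:
        groups.setdefault(o.restoration_id, []).append(o)
    restorations = []
    for rid, items in groups.items():
        first = items[0]
        for name in ("student_id", "cohort_id", "year_of_study", "staff_id",
                     "patient_id", "site", "surface", "material", "staff_difficult_flag"):
            values = {getattr(o, name) for o in items}
            if len(values) > 1:
                raise IntegrityError(
                    f"restoration {rid!r}: conflicting {name} across its observations: "
                    f"{sorted(map(str, values))}"
                )
        ordered = sorted(items, key=lambda o: o.stage_id)
        restorations.append(
            Restoration(
                restoration_id=rid,
                student_id=first.student_id,
                cohort_id=first.cohort_id,
                year_of_study=first.year_of_study,
                staff_id=first.staff_id,
                patient_id=first.patient_id,
                site=first.site,
                surface=first.surface,
                staff_difficult_flag=first.staff_difficult_flag,
                stage_dis=tuple(o.di for o in ordered),
                material=first.material,
            )
        )
    return restorations


#: Columns of the restoration-level table produced below.
RESTORATION_COLUMNS = [
    "restoration_id", "student_id", "cohort_id", "year_of_study", "staff_id",
    "patient_id", "quadrant", "tooth", "surface", "material",
    "staff_difficult_flag", "min_di", "n_stages",
]


def restorations_table(obs_frame: pd.DataFrame, *, validate: bool = True) -> pd.DataFrame:
    """Vectorized restoration assembly: one row per restoration_id.

    Equivalent to :func:`assemble_restorations` but operating on the bulk
    DataFrame; carries the minimum stage DI (``min_di``) and stage count.
    With ``validate=True`` conflicting context fields raise IntegrityError.
    """
    df = obs_frame.copy()
    df["di"] = df["di"].astype(int)
    df["year_of_study"] = df["year_of_study"].astype(int)
    df["quadrant"] = df["quadrant"].astype(int)
    df["tooth"] = df["tooth"].astype(int)
    if df["staff_difficult_flag"].dtype != bool:
        df["staff_difficult_flag"] = df["staff_difficult_flag"].map(_parse_bool)
    g = df.groupby("restoration_id", sort=False)
    if validate:
        nun = g[_RESTORATION_CONTEXT].nunique()
        bad = nun.gt(1).any(axis=1)
        if bad.any():
            rid = bad.idxmax()
            cols = nun.columns[nun.loc[rid].gt(1)].tolist()
            raise IntegrityError(f"restoration {rid!r}: conflicting {', '.join(cols)}")
    agg = {c: "first" for c in _RESTORATION_CONTEXT}
    out = g.agg(**{c: (c, f) for c, f in agg.items()},
                min_di=("di", "min"), n_stages=("di", "size"))
    return out.reset_index()[RESTORATION_COLUMNS]


def restorations_to_table(restorations: Sequence[Restoration]) -> pd.DataFrame:
    """Arrange Restoration objects as the restoration-level table."""
    rows = []
    for r in restorations:
        rows.append({
            "restoration_id": r.restoration_id,
            "student_id": r.student_id,
            "cohort_id": r.cohort_id,
            "year_of_study": r.year_of_study,
            "staff_id": r.staff_id,
            "patient_id": r.patient_id,
            "quadrant": r.site.quadrant,
            "tooth": r.site.position,
            "surface": r.surface.value,
            "material": r.material,
            "staff_difficult_flag": r.staff_difficult_flag,
            "min_di": r.min_di,
            "n_stages": len(r.stage_dis),
        })
    return pd.DataFrame(rows, columns=RESTORATION_COLUMNS)
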