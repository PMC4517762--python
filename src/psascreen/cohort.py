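"""Cohort data model for PSA early-detection biopsy cohorts.

One record per screened man at the time of prostate biopsy: age, total PSA
(ng/mL), percent free PSA (fPSA%), the biopsy outcome (benign vs malignant),
the biopsy Gleason category for cancers, and, where the patient later
underwent radical prostatectomy, the pathology of the specimen.

The module also provides the canonical four-way age stratification
(<=49, 50-59, 60-69, >=70 years), delimited-text I/O and descriptive
summaries in the shape clinical screening reports use (per-group n and
percent, mean/SD/median/IQR for numeric columns, absolute and relative
frequencies for categorical columns).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import pct, round_half_away

__all__ = [
    "Outcome",
    "BiopsyGS",
    "RpGS",
    "PathStage",
    "Margin",
    "RPPathology",
    "PatientRecord",
    "AgeGroup",
    "AGE_GROUPS",
    "GROUP_LABELS",
    "assign_age_group",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "summarize_cohort",
    "CohortSummary",
    "CohortValidationError",
]


class CohortValidationError(ValueError):
    """Raised when a record or a cohort file violates the data contract."""


class Outcome(str, Enum):
    BENIGN = "benign"
    MALIGNANT = "malignant"


class BiopsyGS(str, Enum):
    """Biopsy Gleason category; ``None`` elsewhere denotes missing."""

    GS6 = "GS<=6"
    GS7_34 = "GS7(3+4)"
    GS7_43 = "GS7(4+3)"
    GS8 = "GS8"
    GS9 = "GS9"
    GS10 = "GS10"


class RpGS(str, Enum):
    """Radical-prostatectomy Gleason category (coarser than biopsy)."""

    GS6 = "GS<=6"
    GS7_34 = "GS7(3+4)"
    GS7_43 = "GS7(4+3)"
    GS8PLUS = "GS>=8"


class PathStage(str, Enum):
    ORGAN_CONFINED = "<=pT2c"
    EXTRAPROSTATIC = ">=pT3a"


class Margin(str, Enum):
    R0 = "R0"
    R1 = "R1"


@dataclass(frozen=True)
class RPPathology:
    """Radical-prostatectomy specimen pathology; ``None`` fields are missing."""

    rp_gs: RpGS | None = None
    stage: PathStage | None = None
    margin: Margin | None = None


@dataclass(frozen=True)
class PatientRecord:
    """One screened man at biopsy.

    Benign records carry no Gleason category; malignant records may still
    have a missing one (incomplete pathology reporting).
    """

    patient_id: str
    age: int
    psa: float
    fpsa_pct: float
    outcome: Outcome
    biopsy_gs: BiopsyGS | None = None
    prostate_volume: float | None = None
    rp: RPPathology | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.age, (int, np.integer)) or isinstance(self.age, bool):
            raise CohortValidationError(f"age must be an integer, got {self.age!r}")
        if self.age < 18:
            raise CohortValidationError(f"age must be >= 18, got {self.age}")
        if not math.isfinite(self.psa) or self.psa < 0:
            raise CohortValidationError(f"psa must be a non-negative real, got {self.psa!r}")
        if not (0.0 <= self.fpsa_pct <= 100.0):
            raise CohortValidationError(
                f"fpsa_pct must lie in [0, 100], got {self.fpsa_pct!r}"
            )
        if self.prostate_volume is not None and self.prostate_volume < 0:
            raise CohortValidationError(
                f"prostate_volume must be non-negative, got {self.prostate_volume!r}"
            )
        if not isinstance(self.outcome, Outcome):
            raise CohortValidationError(f"outcome must be an Outcome, got {self.outcome!r}")

    @property
    def malignant(self) -> bool:
        return self.outcome is Outcome.MALIGNANT


@dataclass(frozen=True)
class AgeGroup:
    """Half-open-at-the-top age stratum; ``upper`` is None for the last one."""

    label: str
    lower: int
    upper: int | None

    def contains(self, age: int) -> bool:
        return age >= self.lower and (self.upper is None or age <= self.upper)


#: The four strata used throughout: boundaries are inclusive as labelled
#: (49 belongs to the first group, 50 and 59 to the second, and so on).
AGE_GROUPS: tuple[AgeGroup, ...] = (
    AgeGroup("<=49", 18, 49),
    AgeGroup("50-59", 50, 59),
    AgeGroup("60-69", 60, 69),
    AgeGroup(">=70", 70, None),
)

GROUP_LABELS: tuple[str, ...] = tuple(g.label for g in AGE_GROUPS)


def assign_age_group(age: int) -> AgeGroup:
    """Map an age in years to its stratum.

    Total on ages >= 18; ages below 18 (or non-numeric input) are rejected.
    """
    try:
        age_i = int(age)
    except (TypeError, ValueError) as exc:
        raise CohortValidationError(f"age must be numeric, got {age!r}") from exc
    if age_i != age:
        raise CohortValidationError(f"age must be an integer number of years, got {age!r}")
    if age_i < 18:
        raise CohortValidationError(f"age must be >= 18, got {age!r}")
    for group in AGE_GROUPS:
        if group.contains(age_i):
            return group
    raise AssertionError("unreachable: AGE_GROUPS partition all ages >= 18")


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

COLUMNS = (
    "patient_id",
    "age",
    "psa_ng_ml",
    "fpsa_pct",
    "outcome",
    "biopsy_gs",
    "prostate_volume_ml",
    "rp_gs",
    "rp_stage",
    "rp_margin",
)

MANDATORY_COLUMNS = ("age", "psa_ng_ml", "fpsa_pct", "outcome")


def _parse_enum(enum_cls, token: str, row_no: int, column: str):
    try:
        return enum_cls(token)
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise CohortValidationError(
            f"row {row_no}: invalid {column} {token!r} (allowed: {allowed})"
        ) from None


def read_cohort(
    path: str | Path,
    *,
    delimiter: str = ",",
    missing_token: str = "",
) -> list[PatientRecord]:
    """Read a cohort from a delimited text file (RFC-4180 quoting).

    The header must name at least the mandatory columns
    ``age, psa_ng_ml, fpsa_pct, outcome``; malformed rows are reported with
    their line number and out-of-range values are hard errors.
    """
    records: list[PatientRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise CohortValidationError(f"{path}: empty file, no header")
        missing_cols = [c for c in MANDATORY_COLUMNS if c not in reader.fieldnames]
        if missing_cols:
            raise CohortValidationError(
                f"{path}: missing mandatory column(s): {', '.join(missing_cols)}"
            )
        for row_no, row in enumerate(reader, start=2):  # header is line 1
            records.append(_parse_row(row, row_no, missing_token))
    return records


def _parse_row(row: Mapping[str, str], row_no: int, missing_token: str) -> PatientRecord:
    def get(col: str) -> str | None:
        raw = row.get(col)
        if raw is None:
            return None
        raw = raw.strip()
        return None if raw == missing_token else raw

    def number(col: str, caster, required: bool):
        raw = get(col)
        if raw is None:
            if required:
                raise CohortValidationError(f"row {row_no}: missing value for {col!r}")
            return None
        try:
            return caster(raw)
        except ValueError:
            raise CohortValidationError(
                f"row {row_no}: cannot parse {col}={raw!r}"
            ) from None

    def _strict_int(s: str) -> int:
        v = float(s)
        if v != int(v):
            raise ValueError(s)
        return int(v)

    age = number("age", _strict_int, True)
    psa = number("psa_ng_ml", float, True)
    fpsa = number("fpsa_pct", float, True)
    volume = number("prostate_volume_ml", float, False)

    raw_outcome = get("outcome")
    if raw_outcome is None:
        raise CohortValidationError(f"row {row_no}: missing value for 'outcome'")
    outcome = _parse_enum(Outcome, raw_outcome, row_no, "outcome")

    raw_gs = get("biopsy_gs")
    biopsy_gs = None if raw_gs is None else _parse_enum(BiopsyGS, raw_gs, row_no, "biopsy_gs")

    rp_fields = [get("rp_gs"), get("rp_stage"), get("rp_margin")]
    rp = None
    if any(v is not None for v in rp_fields):
        rp = RPPathology(
            rp_gs=None if rp_fields[0] is None else _parse_enum(RpGS, rp_fields[0], row_no, "rp_gs"),
            stage=None if rp_fields[1] is None else _parse_enum(PathStage, rp_fields[1], row_no, "rp_stage"),
            margin=None if rp_fields[2] is None else _parse_enum(Margin, rp_fields[2], row_no, "rp_margin"),
        )

    try:
        return PatientRecord(
            patient_id=get("patient_id") or f"row{row_no}",
            age=age,
            psa=psa,
            fpsa_pct=fpsa,
            outcome=outcome,
            biopsy_gs=biopsy_gs,
            prostate_volume=volume,
            rp=rp,
        )
    except CohortValidationError as exc:
        raise CohortValidationError(f"row {row_no}: {exc}") from None


def write_cohort(
    records: Iterable[PatientRecord],
    path: str | Path,
    *,
    delimiter: str = ",",
    missing_token: str = "",
) -> None:
    """Write records so that :func:`read_cohort` recovers them field-for-field."""

    def fmt(value) -> str:
        if value is None:
            return missing_token
        if isinstance(value, Enum):
            return value.value
        if isinstance(value, float):
            return repr(value)
        return str(value)

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(COLUMNS)
        for rec in records:
            rp = rec.rp or RPPathology()
            writer.writerow(
                [
                    rec.patient_id,
                    rec.age,
                    fmt(rec.psa),
                    fmt(rec.fpsa_pct),
                    rec.outcome.value,
                    fmt(rec.biopsy_gs),
                    fmt(rec.prostate_volume),
                    fmt(rp.rp_gs),
                    fmt(rp.stage),
                    fmt(rp.margin),
                ]
            )


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (one row per patient) for analysis."""
    rows = []
    for rec in records:
        rp = rec.rp or RPPathology()
        rows.append(
            {
                "patient_id": rec.patient_id,
                "age": rec.age,
                "age_group": assign_age_group(rec.age).label,
                "psa": rec.psa,
                "fpsa_pct": rec.fpsa_pct,
                "outcome": rec.outcome.value,
                "malignant": rec.malignant,
                "biopsy_gs": None if rec.biopsy_gs is None else rec.biopsy_gs.value,
                "prostate_volume": rec.prostate_volume,
                "has_rp": rec.rp is not None,
                "rp_gs": None if rp.rp_gs is None else rp.rp_gs.value,
                "rp_stage": None if rp.stage is None else rp.stage.value,
                "rp_margin": None if rp.margin is None else rp.margin.value,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

NUMERIC_SUMMARY_COLUMNS = ("age", "psa", "fpsa_pct", "prostate_volume")


@dataclass
class CohortSummary:
    """Descriptive summary stratified by age group plus a pooled column.

    ``counts``     : n and percent-of-total per group.
    ``numeric``     : mean/SD/median/IQR per numeric variable and group.
    ``outcome``     : benign/malignant counts and percents per group.
    ``gleason``     : biopsy Gleason mix among malignant records (explicit
                      missing row) per group.
    Percents are rounded half away from zero to one decimal; raw counts are
    kept unrounded so conservation identities hold exactly.
    """

    counts: pd.DataFrame
    numeric: pd.DataFrame
    outcome: pd.DataFrame
    gleason: pd.DataFrame

    def to_text(self) -> str:
        parts = []
        for title, frame in [
            ("Cohort size", self.counts),
            ("Numeric variables", self.numeric),
            ("Biopsy outcome", self.outcome),
            ("Biopsy Gleason (malignant records)", self.gleason),
        ]:
            parts.append(f"== {title} ==")
            parts.append(frame.to_string())
            parts.append("")
        return "\n".join(parts)


def _describe(series: pd.Series) -> dict[str, float]:
    vals = series.dropna().astype(float)
    if vals.empty:
        return {"mean": np.nan, "sd": np.nan, "median": np.nan, "q25": np.nan, "q75": np.nan}
    if len(vals) == 1:
        warnings.warn(
            "SD of a single observation reported as 0", RuntimeWarning, stacklevel=3
        )
        sd = 0.0
    else:
        sd = float(vals.std(ddof=1))
    q25, q75 = np.percentile(vals, [25, 75])  # linear-interpolation quantiles
    return {
        "mean": float(vals.mean()),
        "sd": sd,
        "median": float(vals.median()),
        "q25": float(q25),
        "q75": float(q75),
    }


def summarize_cohort(records: Sequence[PatientRecord]) -> CohortSummary:
    """Descriptive statistics per age group and pooled.

    Raises on an empty cohort.
    """
    if not records:
        raise CohortValidationError("cannot summarize an empty cohort")
    df = records_to_frame(records)
    n_total = len(df)
    group_keys = list(GROUP_LABELS) + ["total"]

    def subset(label: str) -> pd.DataFrame:
        return df if label == "total" else df[df["age_group"] == label]

    counts = pd.DataFrame(
        {
            "n": [len(subset(g)) for g in group_keys],
            "pct_of_total": [pct(len(subset(g)) / n_total) for g in group_keys],
        },
        index=group_keys,
    )

    numeric_rows = {}
    for var in NUMERIC_SUMMARY_COLUMNS:
        for g in group_keys:
            numeric_rows[(var, g)] = _describe(subset(g)[var])
    numeric = pd.DataFrame.from_dict(numeric_rows, orient="index")
    numeric.index = pd.MultiIndex.from_tuples(numeric.index, names=["variable", "group"])

    outcome_rows = {}
    for g in group_keys:
        sub = subset(g)
        n = len(sub)
        n_mal = int(sub["malignant"].sum())
        outcome_rows[g] = {
            "n": n,
            "benign": n - n_mal,
            "benign_pct": pct((n - n_mal) / n) if n else np.nan,
            "malignant": n_mal,
            "malignant_pct": pct(n_mal / n) if n else np.nan,
        }
    outcome = pd.DataFrame.from_dict(outcome_rows, orient="index")

    gs_categories = [e.value for e in BiopsyGS] + ["missing"]
    gleason_rows = {}
    for g in group_keys:
        sub = subset(g)
        mal = sub[sub["malignant"]]
        n_mal = len(mal)
        row = {}
        for cat in gs_categories:
            if cat == "missing":
                count = int(mal["biopsy_gs"].isna().sum())
            else:
                count = int((mal["biopsy_gs"] == cat).sum())
            row[f"{cat}_n"] = count
            row[f"{cat}_pct"] = pct(count / n_mal) if n_mal else np.nan
        gleason_rows[g] = row
    gleason = pd.DataFrame.from_dict(gleason_rows, orient="index")

    return CohortSummary(counts=counts, numeric=numeric, outcome=outcome, gleason=gleason)
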