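"""Cohort schema, I/O and binarization.

The canonical interchange format is a flat CSV, one participant per row:

``participant_id, age, sex, ethnicity, income_quintile, smoker, cycle,
bmi, cal_extent`` followed by one column per catalog disease coded
``1`` (present), ``0`` (absent) or empty (missing).

In memory a cohort is a :class:`CohortTable`: a pandas DataFrame in that
schema plus the :class:`~hypermorb.catalog.DiseaseCatalog` that orders the
disease columns and a ``missing_policy`` saying how missing diagnosis flags
are resolved when the table is binarized. The default policy codes a
missing flag as absent (complete-case style); the ``present`` policy is
used by the missing-to-positive sensitivity analysis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .catalog import DiseaseCatalog
from .errors import SchemaError, ValidationError

MissingPolicy = Literal["absent", "present"]

#: Demographic / clinical columns preceding the disease block, in order.
BASE_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "age",
    "sex",
    "ethnicity",
    "income_quintile",
    "smoker",
    "cycle",
    "bmi",
    "cal_extent",
)

SEX_LEVELS = ("female", "male")
ETHNICITY_LEVELS = ("white", "other")
SMOKER_LEVELS = ("yes", "no")
CYCLE_LEVELS = ("2009-2010", "2011-2012", "2013-2014")

#: BMI at or above this value (kg/m^2) defines obesity.
OBESITY_BMI_THRESHOLD = 30.0


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's demographics, diagnosis flags and periodontal extent."""

    participant_id: str
    age: int
    sex: str
    ethnicity: str
    income_quintile: int | None
    smoker: str | None
    cycle: str
    bmi: float | None
    cal_extent: float | None
    diagnosis_flags: dict[str, str]  # disease -> "present" | "absent" | "missing"


def derive_obesity(bmi: float | None) -> str:
    """Classify obesity from body-mass index.

    Present iff ``bmi >= 30`` kg/m^2 (inclusive threshold); a missing BMI
    propagates to a missing flag.
    """
    if bmi is None or (isinstance(bmi, float) and math.isnan(bmi)):
        return "missing"
    if bmi <= 0:
        raise ValidationError(f"BMI must be positive, got {bmi!r}")
    return "present" if bmi >= OBESITY_BMI_THRESHOLD else "absent"


@dataclass
class CohortTable:
    """A validated cohort: DataFrame + disease catalog + missing-flag policy."""

    frame: pd.DataFrame
    catalog: DiseaseCatalog = field(default_factory=DiseaseCatalog)
    missing_policy: MissingPolicy = "absent"

    def __post_init__(self) -> None:
        validate_frame(self.frame, self.catalog)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def disease_columns(self) -> list[str]:
        return list(self.catalog.names)

    def binarize(self, policy: MissingPolicy | None = None) -> np.ndarray:
        """Participant x disease 0/1 matrix under ``policy`` (default: table's own)."""
        return binarize(self, policy if policy is not None else self.missing_policy)

    @property
    def records(self) -> Iterator[ParticipantRecord]:
        """Row-wise dataclass view (for inspection; analysis is vectorized)."""
        for _, row in self.frame.iterrows():
            flags = {}
            for d in self.catalog.names:
                v = row[d]
                flags[d] = "missing" if pd.isna(v) else ("present" if v == 1 else "absent")
            yield ParticipantRecord(
                participant_id=str(row["participant_id"]),
                age=int(row["age"]),
                sex=row["sex"],
                ethnicity=row["ethnicity"],
                income_quintile=None if pd.isna(row["income_quintile"]) else int(row["income_quintile"]),
                smoker=None if pd.isna(row["smoker"]) else row["smoker"],
                cycle=row["cycle"],
                bmi=None if pd.isna(row["bmi"]) else float(row["bmi"]),
                cal_extent=None if pd.isna(row["cal_extent"]) else float(row["cal_extent"]),
                diagnosis_flags=flags,
            )

    def subset(self, mask: np.ndarray | pd.Series) -> "CohortTable":
        """Row subset preserving order; returns a new table, original untouched."""
        return replace(self, frame=self.frame.loc[np.asarray(mask)].reset_index(drop=True))


def validate_frame(frame: pd.DataFrame, catalog: DiseaseCatalog) -> None:
    """Check a cohort DataFrame against the documented schema and invariants."""
    expected = list(BASE_COLUMNS) + list(catalog.names)
    extra = [c for c in frame.columns if c not in expected]
    if extra:
        raise SchemaError(f"unknown column(s) {extra}; disease columns must match the catalog")
    missing_cols = [c for c in expected if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"missing column(s) {missing_cols}")

    ids = frame["participant_id"]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValidationError(f"duplicate participant_id {dup!r}")

    ext = pd.to_numeric(frame["cal_extent"], errors="coerce")
    bad = frame.index[(ext < 0) | (ext > 1)]
    if len(bad):
        raise ValidationError(f"cal_extent outside [0, 1] at row {bad[0]}")

    bmi = pd.to_numeric(frame["bmi"], errors="coerce")
    if (bmi <= 0).any():
        raise ValidationError("BMI must be positive where present")

    for d in catalog.names:
        vals = pd.to_numeric(frame[d], errors="coerce")
        ok = vals.isna() | vals.isin([0, 1])
        if not ok.all():
            raise ValidationError(f"disease column {d!r} must be coded 1/0/empty")


def read_cohort(path: str | Path, catalog: DiseaseCatalog | None = None,
                missing_policy: MissingPolicy = "absent") -> CohortTable:
    """Read a cohort CSV, validating it against the schema.

    Raises :class:`SchemaError` for unknown/missing columns and
    :class:`ValidationError` for out-of-range values or duplicate ids.
    """
    catalog = catalog or DiseaseCatalog()
    frame = pd.read_csv(path, dtype={"participant_id": str, "sex": str, "ethnicity": str,
                                     "smoker": str, "cycle": str})
    for col in list(catalog.names) + ["income_quintile", "bmi", "cal_extent", "age"]:
        if col in frame.columns:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return CohortTable(frame=frame, catalog=catalog, missing_policy=missing_policy)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort to CSV in the canonical schema (missing cells left empty)."""
    out = table.frame.copy()
    for d in table.catalog.names:
        out[d] = out[d].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out["income_quintile"] = out["income_quintile"].map(
        lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)


def binarize(table: CohortTable, policy: MissingPolicy) -> np.ndarray:
    """0/1 participant x disease matrix in catalog column order.

    Under policy ``absent`` a missing flag codes to 0; under ``present``
    (the sensitivity-analysis coding) it codes to 1.
    """
    block = table.frame[list(table.catalog.names)].to_numpy(dtype=float)
    if policy == "present":
        out = np.where(np.isnan(block), 1.0, block)
    elif policy == "absent":
        out = np.where(np.isnan(block), 0.0, block)
    else:
        raise ValueError(f"unknown missing policy {policy!r}")
    return out.astype(np.int8)


def exclude_no_disease(table: CohortTable) -> CohortTable:
    """Drop participants with no disease present (under the table's policy).

    Mirrors the study-design exclusion of participants without any systemic
    disease diagnosis; row order of the retained participants is preserved.
    """
    matrix = table.binarize()
    return table.subset(matrix.sum(axis=1) >= 1)
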