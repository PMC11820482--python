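"""Respondent data model: codebook-driven reading, validation and exclusion.

The questionnaire export is a wide CSV, one row per respondent, columns per
codebook.  The codebook declares each column's semantic type, allowed levels
or range, and units, so dirty survey exports fail loudly instead of being
silently coerced.  Respondent tables are carried as pandas DataFrames; a
:class:`WBQRespondent` dataclass view is available for single records.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import BEVERAGE_CATEGORIES, default_composition_table

__all__ = [
    "Field",
    "Codebook",
    "ValidationIssue",
    "ResponseSet",
    "WBQRespondent",
    "default_codebook",
    "read_responses",
    "write_responses",
    "exclusion_filter",
    "EXCLUSION_FLAGS",
    "SchemaError",
]

#: Accepted encodings of a missing cell in a CSV export.
MISSING_TOKENS = ("", "NA")

#: Binary exclusion-criterion flag columns (all are "drop if yes").
EXCLUSION_FLAGS: tuple[str, ...] = (
    "excl_pregnancy",
    "excl_breastfeeding",
    "excl_urinary_infection",
    "excl_diabetes",
    "excl_kidney_disease",
    "excl_hydration_medication",
    "excl_recent_symptoms",
)

AGE_RANGE = (18, 65)


class SchemaError(ValueError):
    """Raised when a response file does not match the codebook schema."""


@dataclass(frozen=True)
class Field:
    """One codebook column: name, semantic kind and value constraints."""

    name: str
    kind: str  # id | categorical | binary | ordinal | continuous | count
    levels: tuple[str, ...] | None = None       # categorical / binary
    bounds: tuple[float, float] | None = None   # ordinal / continuous / count
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind in ("categorical", "binary") and not self.levels:
            raise ValueError(f"{self.name}: {self.kind} field needs levels")
        if self.levels is not None and len(set(self.levels)) != len(self.levels):
            raise ValueError(f"{self.name}: duplicate levels")
        if self.kind in ("ordinal", "count") and self.bounds is None:
            raise ValueError(f"{self.name}: {self.kind} field needs bounds")


@dataclass(frozen=True)
class Codebook:
    """Ordered collection of :class:`Field`, one per response column."""

    fields: tuple[Field, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.fields]
        if len(set(names)) != len(names):
            raise ValueError("duplicate field names in codebook")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.fields]

    def __getitem__(self, name: str) -> Field:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.fields)


@dataclass(frozen=True)
class ValidationIssue:
    """A single out-of-range or unknown-level cell, by row id and column."""

    row: object
    column: str
    value: object
    message: str


@dataclass
class ResponseSet:
    """Validated respondent table plus the issues found while reading it."""

    data: pd.DataFrame
    issues: list[ValidationIssue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)


def default_codebook(food_items: Sequence[str] | None = None) -> Codebook:
    """The shipped codebook.

    The instrument's food-frequency item list is configurable; by default it
    follows the shipped composition-table fixture.
    """
    if food_items is None:
        food_items = list(default_composition_table())
    yes_no = ("no", "yes")
    fields: list[Field] = [
        Field("id", "id"),
        Field("gender", "categorical", levels=("male", "female")),
        Field("age", "continuous", bounds=(18, 65), units="years"),
        Field("weight_kg", "continuous", bounds=(25, 300), units="kg"),
        Field("height_m", "continuous", bounds=(1.0, 2.3), units="m"),
        Field("education_years", "continuous", bounds=(0, 30), units="years"),
        Field("residence", "categorical",
              levels=("capital", "other_city", "small_town", "village")),
        Field("family_status", "categorical",
              levels=("unmarried", "married", "divorced")),
        Field("profession", "categorical",
              levels=("self_employed", "private", "public", "other")),
        Field("work_hours_week", "continuous", bounds=(0, 100), units="h/week"),
    ]
    for likert in ("labor_intensity", "physical_strain", "mental_strain",
                   "wc_access", "weather_exposure", "water_access"):
        fields.append(Field(likert, "ordinal", bounds=(1, 5)))
    for yn in ("bottle_at_work", "bottle_during_day", "glass_during_day",
               "water_without_thirst", "water_for_pleasure"):
        fields.append(Field(yn, "binary", levels=yes_no))
    for bev in BEVERAGE_CATEGORIES:
        fields.append(Field(f"bev_{bev}", "ordinal", bounds=(1, 6),
                            units="frequency category"))
    for item in food_items:
        fields.append(Field(f"food_{item}", "ordinal", bounds=(1, 6),
                            units="frequency category"))
    fields += [
        Field("drinking_water_ml", "continuous", bounds=(0, 20000), units="mL/day"),
        Field("urination_scale", "ordinal", bounds=(1, 5)),
        Field("defecation_scale", "ordinal", bounds=(1, 5)),
        Field("sweat_rest_scale", "ordinal", bounds=(1, 10)),
        Field("sweat_exercise_scale", "ordinal", bounds=(1, 10)),
    ]
    for cls in ("vigorous", "moderate", "walking"):
        fields.append(Field(f"ipaq_{cls}_days", "count", bounds=(0, 7), units="days/week"))
        fields.append(Field(f"ipaq_{cls}_min", "continuous", bounds=(0, 960),
                            units="min/session"))
    for flag in EXCLUSION_FLAGS:
        fields.append(Field(flag, "binary", levels=yes_no))
    return Codebook(tuple(fields))


def _validate_column(raw: pd.Series, f: Field, ids: pd.Series,
                     issues: list[ValidationIssue]) -> pd.Series:
    """Return the validated column; invalid cells become missing + an issue."""
    as_str = raw.astype("string").str.strip()
    missing = raw.isna() | as_str.isin(MISSING_TOKENS)
    if f.kind == "id":
        return raw.where(~missing)
    if f.kind in ("categorical", "binary"):
        lowered = as_str.str.lower()
        bad = ~missing & ~lowered.isin(f.levels)
        for i in np.flatnonzero(bad.to_numpy()):
            issues.append(ValidationIssue(ids.iloc[i], f.name, raw.iloc[i],
                                          f"not one of levels {f.levels}"))
        return lowered.where(~missing & ~bad)
    def _parse(s):
        # Python's float() is correctly rounded, so CSV round-trips exactly
        try:
            return float(s)
        except (TypeError, ValueError):
            return np.nan

    numeric = as_str.where(~missing).map(_parse, na_action="ignore")
    numeric = pd.to_numeric(numeric, errors="coerce")
    unparsable = ~missing & numeric.isna()
    for i in np.flatnonzero(unparsable.to_numpy()):
        issues.append(ValidationIssue(ids.iloc[i], f.name, raw.iloc[i],
                                      "not a number"))
    if f.kind in ("ordinal", "count"):
        non_integral = numeric.notna() & (numeric != numeric.round())
        for i in np.flatnonzero(non_integral.to_numpy()):
            issues.append(ValidationIssue(ids.iloc[i], f.name, raw.iloc[i],
                                          "not an integer scale level"))
        numeric = numeric.where(~non_integral)
    if f.bounds is not None:
        lo, hi = f.bounds
        out = numeric.notna() & ((numeric < lo) | (numeric > hi))
        for i in np.flatnonzero(out.to_numpy()):
            issues.append(ValidationIssue(ids.iloc[i], f.name, raw.iloc[i],
                                          f"outside range [{lo}, {hi}]"))
        numeric = numeric.where(~out)
    return numeric


def validate_responses(df: pd.DataFrame, codebook: Codebook) -> ResponseSet:
    """Validate a raw table against the codebook (see :func:`read_responses`)."""
    missing_cols = [n for n in codebook.names if n not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {missing_cols}")
    issues: list[ValidationIssue] = []
    ids = df["id"]
    out = {}
    for f in codebook.fields:
        out[f.name] = _validate_column(df[f.name], f, ids, issues)
    clean = pd.DataFrame(out, index=df.index)
    return ResponseSet(clean, issues)


def read_responses(path: str | Path, codebook: Codebook | None = None) -> ResponseSet:
    """Read a response CSV and validate it against the codebook.

    Out-of-range ordinals and unknown categorical levels are recorded as
    :class:`ValidationIssue` entries (and the offending cell is set missing);
    empty cells and ``NA`` become explicit missing values.
    """
    codebook = codebook or default_codebook()
    path = Path(path)
    if not path.exists():
        raise OSError(f"response file not found: {path}")
    df = pd.read_csv(path, dtype="object", keep_default_na=False,
                     na_values=list(MISSING_TOKENS))
    return validate_responses(df, codebook)


def write_responses(df: pd.DataFrame, path: str | Path,
                    codebook: Codebook | None = None) -> None:
    """Write a respondent table as a codebook-ordered CSV (inverse of read)."""
    codebook = codebook or default_codebook()
    cols = [n for n in codebook.names if n in df.columns]
    out = df[cols].copy()
    for f in codebook.fields:
        if f.kind in ("ordinal", "count") and f.name in out:
            num = pd.to_numeric(out[f.name], errors="coerce")
            out[f.name] = num.astype("Int64")
    out.to_csv(path, index=False)


@dataclass
class Exclusion:
    """One dropped respondent and the criterion that triggered the drop."""

    id: object
    reason: str


def exclusion_filter(
    df: pd.DataFrame,
    flags: Iterable[str] = EXCLUSION_FLAGS,
    age_range: tuple[float, float] = AGE_RANGE,
) -> tuple[pd.DataFrame, list[Exclusion], list[str]]:
    """Apply the eligibility criteria: drop flagged respondents and ages
    outside the inclusive adult range.

    Returns ``(retained, exclusion_log, warnings)``.  A missing flag column is
    treated as "no" for every respondent and reported in ``warnings`` (the
    original instrument enforced these at entry).  Retained and excluded rows
    partition the input exactly.
    """
    warnings: list[str] = []
    log: list[Exclusion] = []
    drop = pd.Series(False, index=df.index)
    for flag in flags:
        if flag not in df.columns:
            warnings.append(f"exclusion flag {flag!r} absent; assuming 'no' for all")
            continue
        hit = df[flag].astype("string").str.lower() == "yes"
        for idx in df.index[hit & ~drop]:
            log.append(Exclusion(df.loc[idx, "id"], flag))
        drop |= hit
    if "age" in df.columns:
        age = pd.to_numeric(df["age"], errors="coerce")
        lo, hi = age_range
        bad_age = age.notna() & ((age < lo) | (age > hi))
        for idx in df.index[bad_age & ~drop]:
            log.append(Exclusion(df.loc[idx, "id"], "age"))
        drop |= bad_age
    return df.loc[~drop].copy(), log, warnings


@dataclass
class WBQRespondent:
    """Dataclass view of a single respondent row (missing values are NaN/None)."""

    id: object = None
    gender: str | None = None
    age: float | None = None
    weight_kg: float | None = None
    height_m: float | None = None
    education_years: float | None = None
    residence: str | None = None
    family_status: str | None = None
    profession: str | None = None
    work_hours_week: float | None = None
    labor_intensity: float | None = None
    physical_strain: float | None = None
    mental_strain: float | None = None
    wc_access: float | None = None
    weather_exposure: float | None = None
    water_access: float | None = None
    bottle_at_work: str | None = None
    bottle_during_day: str | None = None
    glass_during_day: str | None = None
    water_without_thirst: str | None = None
    water_for_pleasure: str | None = None
    beverage_freq: dict = field(default_factory=dict)
    food_freq: dict = field(default_factory=dict)
    drinking_water_ml: float | None = None
    urination_scale: float | None = None
    defecation_scale: float | None = None
    sweat_rest_scale: float | None = None
    sweat_exercise_scale: float | None = None
    ipaq: dict = field(default_factory=dict)

    @classmethod
    def from_row(cls, row: pd.Series) -> "WBQRespondent":
        simple = {f.name for f in dataclasses.fields(cls)} - {"beverage_freq",
                                                              "food_freq", "ipaq"}
        kwargs = {k: row[k] for k in simple if k in row.index}
        kwargs["beverage_freq"] = {
            c[len("bev_"):]: row[c] for c in row.index if c.startswith("bev_")
        }
        kwargs["food_freq"] = {
            c[len("food_"):]: row[c] for c in row.index if c.startswith("food_")
        }
        kwargs["ipaq"] = {
            c[len("ipaq_"):]: row[c] for c in row.index if c.startswith("ipaq_")
        }
        return cls(**kwargs)
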