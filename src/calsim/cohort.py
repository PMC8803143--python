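"""Cohort data model: schema, validation and CSV (de)serialization.

One row per child.  Columns (fixed order):

======================  =======================================================
``child_id``            opaque unique identifier
``sex``                 ``male`` / ``female``
``social_class``        maternal occupational social class, ordered
                        ``high`` < ``mid`` < ``low`` (numeric codes 0/1/2; the
                        code is monotone in *disadvantage*, so a positive slope
                        on the code means more disadvantage -> higher risk)
``ethnicity``           ``white`` / ``non_white`` (baseline confounder)
``birthweight_cat``     ``low`` < ``mid`` < ``high`` (intermediate confounder)
``health_cat``          ``healthy`` / ``unwell`` (intermediate confounder)
``activity_cat``        ``low`` < ``mid`` < ``high`` (intermediate confounder)
``tv_cat``              ``low`` < ``mid`` < ``high`` (intermediate confounder)
``kcal7``               total daily energy intake at age 7, kcal/day (mediator)
``low_income``          household income below the low-income line (targeting)
``obese7``              obesity at age 7 (targeting)
``obese11``             obesity at age 11 (outcome)
``overweight_or_obese11``  combined overweight/obesity at 11 (alt. outcome)
``education``           optional ordered alternative exposure, same coding as
                        ``social_class``
======================  =======================================================

Booleans are serialized as 0/1, category labels as lowercase strings.
Missing cells are rejected: the analysis path is complete-case by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CATEGORIES",
    "ORDERED",
    "COLUMNS",
    "BOOL_COLUMNS",
    "EARTable",
    "CohortSchemaError",
    "CohortValidationError",
    "class_codes",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
]

#: Category levels per categorical column (order = numeric code order).
CATEGORIES: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "social_class": ("high", "mid", "low"),
    "ethnicity": ("white", "non_white"),
    "birthweight_cat": ("low", "mid", "high"),
    "health_cat": ("healthy", "unwell"),
    "activity_cat": ("low", "mid", "high"),
    "tv_cat": ("low", "mid", "high"),
    "education": ("high", "mid", "low"),
}

#: Columns whose categories are ordered (ordinal).
ORDERED = frozenset(
    {"social_class", "birthweight_cat", "activity_cat", "tv_cat", "education"}
)

BOOL_COLUMNS = ("low_income", "obese7", "obese11", "overweight_or_obese11")

#: Required columns, in canonical serialization order.
COLUMNS: tuple[str, ...] = (
    "child_id",
    "sex",
    "social_class",
    "ethnicity",
    "birthweight_cat",
    "health_cat",
    "activity_cat",
    "tv_cat",
    "kcal7",
    "low_income",
    "obese7",
    "obese11",
    "overweight_or_obese11",
)

#: Optional columns appended after the required block when present.
OPTIONAL_COLUMNS: tuple[str, ...] = ("education",)


class CohortSchemaError(ValueError):
    """A required column is missing or has the wrong type/labels."""


class CohortValidationError(ValueError):
    """One or more rows violate a cohort invariant.

    Attributes
    ----------
    child_ids : list
        Identifiers of the offending rows.
    """

    def __init__(self, message: str, child_ids: Sequence | None = None):
        super().__init__(message)
        self.child_ids = list(child_ids) if child_ids is not None else []


@dataclass(frozen=True)
class EARTable:
    """Estimated average requirement (kcal/day) by sex for 7-year-olds."""

    ear_by_sex: Mapping[str, float] = field(
        default_factory=lambda: {"male": 1649.0, "female": 1530.0}
    )

    def __post_init__(self):
        for sex, v in self.ear_by_sex.items():
            if sex not in CATEGORIES["sex"]:
                raise ValueError(f"unknown sex label {sex!r}")
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"EAR for {sex} must be positive, got {v}")

    def __getitem__(self, sex: str) -> float:
        return float(self.ear_by_sex[sex])

    def per_child(self, cohort: pd.DataFrame) -> np.ndarray:
        """Sex-specific EAR aligned to the cohort's rows."""
        return cohort["sex"].map(self.ear_by_sex).to_numpy(dtype=float)


def class_codes(cohort: pd.DataFrame, col: str = "social_class") -> np.ndarray:
    """Integer disadvantage codes (0=high ... 2=low) for an ordinal column."""
    s = cohort[col]
    if isinstance(s.dtype, pd.CategoricalDtype):
        codes = s.cat.codes.to_numpy()
        if (codes < 0).any():
            raise CohortValidationError(f"missing values in {col}")
        return codes.astype(np.int64)
    return s.to_numpy(dtype=np.int64)


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce raw columns to canonical dtypes without validating content."""
    out = df.copy()
    for col, cats in CATEGORIES.items():
        if col not in out.columns:
            continue
        vals = out[col]
        if not isinstance(vals.dtype, pd.CategoricalDtype):
            vals = vals.astype(str).str.strip().str.lower()
        out[col] = pd.Categorical(vals, categories=cats, ordered=col in ORDERED)
    for col in BOOL_COLUMNS:
        if col in out.columns:
            v = out[col]
            if v.dtype != bool:
                v = pd.to_numeric(v, errors="coerce")
                bad = ~v.isin([0, 1]) | v.isna()
                if bad.any():
                    raise CohortValidationError(
                        f"column {col!r} must be boolean 0/1",
                        child_ids=out.loc[bad, "child_id"].tolist(),
                    )
                v = v.astype(bool)
            out[col] = v
    if "kcal7" in out.columns:
        out["kcal7"] = pd.to_numeric(out["kcal7"], errors="coerce")
    return out


def validate_cohort(df: pd.DataFrame, coerce: bool = True) -> pd.DataFrame:
    """Validate a cohort table against the schema and row invariants.

    Returns the (possibly dtype-coerced) table; raises
    :class:`CohortSchemaError` / :class:`CohortValidationError` otherwise.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")
    if coerce:
        df = _coerce(df)

    if df["child_id"].duplicated().any():
        dup = df.loc[df["child_id"].duplicated(), "child_id"].tolist()
        raise CohortValidationError("duplicate child_id values", child_ids=dup)

    for col in CATEGORIES:
        if col in df.columns:
            na = df[col].isna()
            if na.any():
                raise CohortValidationError(
                    f"invalid or missing labels in {col!r}",
                    child_ids=df.loc[na, "child_id"].tolist(),
                )

    kcal = df["kcal7"]
    bad = ~np.isfinite(kcal.to_numpy(dtype=float)) | (kcal <= 0)
    if bad.any():
        ids = df.loc[bad, "child_id"].tolist()
        raise CohortValidationError(
            f"kcal7 must be positive and finite; offending child_id(s): {ids}",
            child_ids=ids,
        )

    incons = df["obese11"] & ~df["overweight_or_obese11"]
    if incons.any():
        ids = df.loc[incons, "child_id"].tolist()
        raise CohortValidationError(
            "obese11 implies overweight_or_obese11; "
            f"offending child_id(s): {ids}",
            child_ids=ids,
        )
    return df


def read_cohort(
    path: str | Path,
    schema_options: Mapping[str, str] | str | Path | None = None,
) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path
        CSV file with the canonical header (see module docstring).
    schema_options
        Optional ``{file_column: canonical_column}`` rename map, or a path to
        a YAML/JSON file containing one.
    """
    df = pd.read_csv(path)
    if schema_options is not None:
        if isinstance(schema_options, (str, Path)):
            with open(schema_options) as fh:
                schema_options = yaml.safe_load(fh)
        df = df.rename(columns=dict(schema_options))
    return validate_cohort(df)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a validated cohort to CSV in canonical column order.

    Enums go out as lowercase strings, booleans as 0/1, kcal with full
    precision; ``read_cohort(write_cohort(T)) == T`` field-for-field.
    """
    cohort = validate_cohort(cohort)
    cols = list(COLUMNS) + [c for c in OPTIONAL_COLUMNS if c in cohort.columns]
    out = cohort[cols].copy()
    for col in BOOL_COLUMNS:
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False)
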