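"""Cohort data dictionary, inclusion filters, variable coding and delimited-text I/O.

The unit of analysis is one singleton live birth. Raw records carry routine
maternity fields (gestational age in completed weeks, birthweight, maternal
age, parity, marital status, area-deprivation quintile, calendar year), four
binary pregnancy mediators (smoking, maternal mental ill health,
hospitalisation for physical health, obstetric conditions) and the flags
needed for inclusion screening. Coded analysis records add the derived
exposure/confounder categories, the binary preterm outcome and a six-level
gestational-age category.

Cohorts are held as :class:`pandas.DataFrame` objects with the column
dictionaries below; missing values use pandas ``NA``.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable

import numpy as np
import pandas as pd

#: Raw cohort columns (one row per birth). Mediator flags, singleton,
#: live_birth and year must never be missing; parity, marital_status,
#: smoking and wimd_quintile may be.
COHORT_COLUMNS: tuple[str, ...] = (
    "gestational_age_weeks",
    "birthweight_g",
    "maternal_age_years",
    "parity",
    "marital_status",
    "wimd_quintile",
    "smoking",
    "mental_health",
    "physical_health",
    "obstetric_conditions",
    "singleton",
    "live_birth",
    "year",
)

#: Coded analysis columns produced by :func:`code_analysis_records`.
ANALYSIS_COLUMNS: tuple[str, ...] = (
    "exposure",
    "age_cat",
    "parity_cat",
    "marital_status",
    "smoking",
    "mental_health",
    "physical_health",
    "obstetric_conditions",
    "preterm",
    "ga_category",
    "year",
)

MARITAL_LEVELS: tuple[str, ...] = (
    "married_cp",
    "not_married_sole",
    "not_married_joint_same_addr",
    "not_married_joint_diff_addr",
)
AGE_LEVELS: tuple[str, ...] = ("<18", "18-24", "25-34", "35+")
PARITY_LEVELS: tuple[str, ...] = ("0", "1", "2+")
GA_LEVELS: tuple[str, ...] = (
    "extremely_preterm",
    "very_preterm",
    "moderate_preterm",
    "early_term",
    "term",
    "post_term",
)
#: Binary mediator columns in DAG order (obstetric conditions downstream).
MEDIATORS: tuple[str, ...] = (
    "smoking",
    "mental_health",
    "physical_health",
    "obstetric_conditions",
)

_INT_COLUMNS = (
    "gestational_age_weeks",
    "birthweight_g",
    "maternal_age_years",
    "parity",
    "wimd_quintile",
    "smoking",
    "mental_health",
    "physical_health",
    "obstetric_conditions",
    "singleton",
    "live_birth",
    "year",
)


class SchemaError(ValueError):
    """A cohort file does not match the documented data dictionary."""


def _coerce_cohort_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in _INT_COLUMNS:
        df[col] = pd.array(pd.to_numeric(df[col], errors="raise"), dtype="Int64")
    ms = df["marital_status"].astype("object")
    ms = ms.where(~pd.isna(ms), other=pd.NA)
    bad = set(ms.dropna().unique()) - set(MARITAL_LEVELS)
    if bad:
        raise SchemaError(f"unknown marital_status levels: {sorted(bad)}")
    df["marital_status"] = pd.Categorical(ms, categories=MARITAL_LEVELS)
    return df


def read_cohort(path, missing_token: str = "") -> pd.DataFrame:
    """Read a raw cohort from delimited text (RFC-4180 CSV, UTF-8, header row).

    ``missing_token`` is the sole string treated as a missing value.
    Raises :class:`SchemaError` naming any absent mandatory column.
    """
    df = pd.read_csv(
        path,
        dtype="object",
        keep_default_na=False,
        na_values=[missing_token],
        encoding="utf-8",
    )
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {missing_cols}")
    try:
        df = _coerce_cohort_dtypes(df[list(COHORT_COLUMNS)])
    except SchemaError:
        raise
    except Exception as exc:  # surface the offending row for record-level errors
        raise SchemaError(f"unparseable cohort file {path}: {exc}") from exc
    return df


def write_cohort(df: pd.DataFrame, path, missing_token: str = "") -> None:
    """Write a raw cohort as CSV; the inverse of :func:`read_cohort`."""
    df.to_csv(path, index=False, na_rep=missing_token, encoding="utf-8")


def apply_inclusion_filters(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the cohort inclusion criteria and tally exclusions per reason.

    Included births are singleton live births with a recorded deprivation
    quintile, gestation 22-43 completed weeks, birthweight 500-6500 g,
    maternal age 13-50 years and parity below 10 (records with missing parity
    are retained, since the criterion cannot be assessed and parity is imputed
    downstream). Exclusion reasons are not mutually exclusive: a record can
    increment several counters, so the sum of counts can exceed the number of
    excluded rows.
    """
    r = records
    fails = {
        "not_singleton": (r["singleton"] != 1).fillna(True),
        "not_live_birth": (r["live_birth"] != 1).fillna(True),
        "missing_wimd": r["wimd_quintile"].isna(),
        "gestation": ~r["gestational_age_weeks"].between(22, 43).fillna(False),
        "birthweight": ~r["birthweight_g"].between(500, 6500).fillna(False),
        "maternal_age": ~r["maternal_age_years"].between(13, 50).fillna(False),
        "parity": (r["parity"] >= 10).fillna(False),
    }
    counts = Counter({reason: int(mask.sum()) for reason, mask in fails.items()})
    any_fail = np.column_stack([m.to_numpy(dtype=bool) for m in fails.values()]).any(axis=1)
    included = r.loc[~any_fail].reset_index(drop=True)
    return included, dict(counts)


def ga_category(weeks: int) -> str:
    """Six-level gestational-age category from completed weeks.

    <28 extremely preterm, 28-31 very preterm, 32-36 moderate preterm,
    37-38 early term, 39-41 term (reference), 42+ post term.
    """
    if weeks < 28:
        return "extremely_preterm"
    if weeks <= 31:
        return "very_preterm"
    if weeks <= 36:
        return "moderate_preterm"
    if weeks <= 38:
        return "early_term"
    if weeks <= 41:
        return "term"
    return "post_term"


def _age_cat(age: int) -> str:
    if age < 18:
        return "<18"
    if age <= 24:
        return "18-24"
    if age <= 34:
        return "25-34"
    return "35+"


def code_analysis_records(records: pd.DataFrame, preterm_cutoff_weeks: int = 37) -> pd.DataFrame:
    """Code filtered raw records into analysis records.

    The exposure is the deprivation quintile (1 = most deprived; quintile 5 is
    the analysis reference level). ``preterm`` is gestation below
    ``preterm_cutoff_weeks`` (37 by default; 34 for the sensitivity variant).
    ``ga_category`` always uses the fixed six-category boundaries regardless
    of the cutoff. Missing parity, marital status and smoking propagate as
    missing. Coding is deterministic and row-independent.
    """
    ga = records["gestational_age_weeks"]
    if ga.isna().any() or not ga.between(22, 43).all():
        raise ValueError("gestational age outside 22-43 weeks: records must pass inclusion filters")
    if records["wimd_quintile"].isna().any():
        raise ValueError("missing wimd_quintile: records must pass inclusion filters")

    ga_np = ga.to_numpy(dtype=int)
    parity = records["parity"]
    out = pd.DataFrame(
        {
            "exposure": records["wimd_quintile"].astype(int).to_numpy(),
            "age_cat": pd.Categorical(
                [_age_cat(a) for a in records["maternal_age_years"].to_numpy(dtype=int)],
                categories=AGE_LEVELS,
            ),
            "parity_cat": pd.Categorical(
                np.select(
                    [
                        parity.isna().to_numpy(),
                        (parity == 0).fillna(False).to_numpy(dtype=bool),
                        (parity == 1).fillna(False).to_numpy(dtype=bool),
                    ],
                    [None, "0", "1"],
                    default="2+",
                ),
                categories=PARITY_LEVELS,
            ),
            "marital_status": pd.Categorical(records["marital_status"], categories=MARITAL_LEVELS),
            "smoking": records["smoking"].astype("Int64").to_numpy(dtype=object),
            "mental_health": records["mental_health"].astype(int).to_numpy(),
            "physical_health": records["physical_health"].astype(int).to_numpy(),
            "obstetric_conditions": records["obstetric_conditions"].astype(int).to_numpy(),
            "preterm": (ga_np < preterm_cutoff_weeks).astype(int),
            "ga_category": pd.Categorical([ga_category(w) for w in ga_np], categories=GA_LEVELS),
            "year": records["year"].astype(int).to_numpy(),
        }
    )
    out["smoking"] = pd.array(out["smoking"], dtype="Int64")
    return out


def write_analysis(df: pd.DataFrame, path, missing_token: str = "") -> None:
    df.to_csv(path, index=False, na_rep=missing_token, encoding="utf-8")


def read_analysis(path, missing_token: str = "") -> pd.DataFrame:
    """Read a coded analysis table written by :func:`write_analysis`."""
    df = pd.read_csv(path, dtype="object", keep_default_na=False, na_values=[missing_token])
    missing_cols = [c for c in ANALYSIS_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {missing_cols}")
    df = df[list(ANALYSIS_COLUMNS)].copy()
    for col in ("exposure", "mental_health", "physical_health", "obstetric_conditions", "preterm", "year"):
        df[col] = df[col].astype(int)
    df["smoking"] = pd.array(pd.to_numeric(df["smoking"]), dtype="Int64")
    df["age_cat"] = pd.Categorical(df["age_cat"], categories=AGE_LEVELS)
    df["parity_cat"] = pd.Categorical(df["parity_cat"], categories=PARITY_LEVELS)
    df["marital_status"] = pd.Categorical(df["marital_status"], categories=MARITAL_LEVELS)
    df["ga_category"] = pd.Categorical(df["ga_category"], categories=GA_LEVELS)
    return df


def listwise_complete(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Complete-case subset over the three incompletely observed variables."""
    masks = {v: df[v].isna() for v in ("smoking", "parity_cat", "marital_status")}
    counts = {v: int(m.sum()) for v, m in masks.items()}
    keep = ~np.column_stack([m.to_numpy(dtype=bool) for m in masks.values()]).any(axis=1)
    counts["dropped_rows"] = int((~keep).sum())
    return df.loc[keep].reset_index(drop=True), counts
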