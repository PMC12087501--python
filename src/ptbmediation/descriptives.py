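"""Stratified descriptive table: variable level by deprivation quintile.

Counts are exact; percentages use the full column total (including rows with
the variable missing) as the denominator and are rounded half-up to one
decimal, matching routine epidemiological reporting of cohort descriptives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .cohort import AGE_LEVELS, MARITAL_LEVELS, MEDIATORS, PARITY_LEVELS

#: Tabulated variables and their displayed level order (None = missing row).
TABLE_VARIABLES: dict[str, tuple] = {
    "preterm": ("0", "1"),
    "smoking": ("0", "1", None),
    "mental_health": ("0", "1"),
    "physical_health": ("0", "1"),
    "obstetric_conditions": ("0", "1"),
    "age_cat": AGE_LEVELS,
    "parity_cat": PARITY_LEVELS + (None,),
    "marital_status": MARITAL_LEVELS + (None,),
}

QUINTILE_COLUMNS = (1, 2, 3, 4, 5, "Total")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (printed-table convention, not banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class StratifiedTable:
    """Counts and column percentages per (variable, level) x quintile cell."""

    counts: pd.DataFrame  # MultiIndex rows (variable, level), cols QUINTILE_COLUMNS
    percents: pd.DataFrame  # same shape; percent of column total, 1 decimal
    column_totals: dict = field(default_factory=dict)

    def cell(self, variable: str, level, column) -> tuple[int, float]:
        key = (variable, "Missing" if level is None else str(level))
        return int(self.counts.loc[key, column]), float(self.percents.loc[key, column])

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: variable, level, column, count, percent."""
        rows = []
        for (var, level), crow in self.counts.iterrows():
            for col in QUINTILE_COLUMNS:
                rows.append(
                    {
                        "variable": var,
                        "level": level,
                        "column": col,
                        "count": int(crow[col]),
                        "percent": float(self.percents.loc[(var, level), col]),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "column_totals": {str(k): v for k, v in self.column_totals.items()},
            "cells": self.to_frame().to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def tabulate(records: pd.DataFrame, variables: dict | None = None) -> StratifiedTable:
    """Tabulate coded analysis records into a quintile-stratified table.

    Every variable's levels (plus a Missing row where applicable) sum to the
    column total, and the Total column is the row-wise sum over quintiles.
    """
    if len(records) == 0:
        raise ValueError("empty cohort: nothing to tabulate")
    variables = variables if variables is not None else TABLE_VARIABLES
    col_totals = {q: int((records["exposure"] == q).sum()) for q in range(1, 6)}
    col_totals["Total"] = len(records)

    index = []
    count_rows = []
    for var, levels in variables.items():
        series = records[var]
        str_series = series.astype("object").map(lambda v: None if pd.isna(v) else str(v))
        for level in levels:
            label = "Missing" if level is None else str(level)
            if level is None:
                mask = str_series.isna()
            else:
                mask = str_series == str(level)
            per_q = [int((mask & (records["exposure"] == q)).sum()) for q in range(1, 6)]
            index.append((var, label))
            count_rows.append(per_q + [int(mask.sum())])

    midx = pd.MultiIndex.from_tuples(index, names=["variable", "level"])
    counts = pd.DataFrame(count_rows, index=midx, columns=list(QUINTILE_COLUMNS))
    percents = counts.copy().astype(float)
    for col in QUINTILE_COLUMNS:
        denom = col_totals[col]
        percents[col] = [
            round_half_up(100.0 * c / denom, 1) if denom else float("nan") for c in counts[col]
        ]
    return StratifiedTable(counts=counts, percents=percents, column_totals=col_totals)
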