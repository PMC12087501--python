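"""Published aggregate reference data for the Welsh national birth cohort.

``TABLE1_COUNTS`` holds the published descriptive cell counts (variable level
by deprivation quintile) for the cleaned Welsh singleton live-birth cohort
2000-2019 (609 610 births), prior to imputation. These are aggregate counts
only; no individual-level data are included. They serve two purposes: as the
calibration targets of the synthetic-cohort generator, and as an input for
checking the descriptive tabulation against the published percentages.

``table1_cohort`` expands the counts into a row-per-birth analysis table.
Because the published table reports each variable's margin separately, the
expansion assigns each variable independently within a quintile column: all
within-quintile margins are exact, while the joint distribution across
variables is synthetic (and irrelevant to marginal tabulation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import AGE_LEVELS, GA_LEVELS, MARITAL_LEVELS, PARITY_LEVELS

#: Cell counts by quintile 1..5 (1 = most deprived). ``None`` level = missing.
TABLE1_COUNTS: dict[str, dict[str | None, list[int]]] = {
    "preterm": {
        "0": [147243, 122309, 112569, 97692, 92764],
        "1": [10938, 8254, 7011, 5751, 5079],
    },
    "smoking": {
        "0": [66219, 67159, 66300, 60284, 55143],
        "1": [35811, 23889, 16458, 11059, 6627],
        None: [56151, 39515, 36822, 32100, 36073],
    },
    "mental_health": {
        "0": [150810, 125337, 115672, 100522, 95301],
        "1": [7371, 5226, 3908, 2921, 2542],
    },
    "physical_health": {
        "0": [137855, 115190, 106899, 92969, 88208],
        "1": [20326, 15373, 12681, 10474, 9635],
    },
    "obstetric_conditions": {
        "0": [117287, 98968, 92236, 81393, 76623],
        "1": [40894, 31595, 27344, 22050, 21220],
    },
    "age_cat": {
        "<18": [5308, 3233, 2134, 1320, 803],
        "18-24": [59601, 40092, 29888, 20641, 13428],
        "25-34": [77039, 70317, 67654, 60671, 59252],
        "35+": [16233, 16921, 19904, 20811, 24360],
    },
    "parity_cat": {
        "0": [54902, 51552, 50473, 42267, 38584],
        "1": [40230, 35072, 33698, 28525, 28927],
        "2+": [35991, 23654, 19711, 15284, 12534],
        None: [27058, 20285, 15698, 17367, 17798],
    },
    "marital_status": {
        "married_cp": [47041, 48264, 54354, 54007, 61209],
        "not_married_sole": [17906, 10278, 6734, 4312, 2891],
        "not_married_joint_same_addr": [59994, 51260, 44181, 35321, 26838],
        "not_married_joint_diff_addr": [30954, 18885, 12196, 7724, 5260],
        None: [2286, 1876, 2115, 2079, 1645],
    },
}

#: Births per quintile column (sum of the preterm rows; identical for every variable).
QUINTILE_TOTALS: list[int] = [158181, 130563, 119580, 103443, 97843]

_CATEGORIES = {
    "age_cat": AGE_LEVELS,
    "parity_cat": PARITY_LEVELS,
    "marital_status": MARITAL_LEVELS,
    "ga_category": GA_LEVELS,
}


def _expand_column(var: str, q_idx: int, n_q: int):
    levels = TABLE1_COUNTS[var]
    values: list = []
    total = 0
    for level, counts in levels.items():
        c = counts[q_idx]
        values.append(np.repeat(np.array([level], dtype=object), c))
        total += c
    if total != n_q:
        raise AssertionError(f"{var}: quintile {q_idx + 1} counts sum to {total}, expected {n_q}")
    return np.concatenate(values)


def table1_cohort() -> pd.DataFrame:
    """Row-per-birth analysis table whose margins reproduce the published counts.

    Binary columns come back as nullable integers, categoricals with the
    package's level sets; ``ga_category`` is "moderate_preterm" for preterm
    rows and "term" otherwise (the published table does not subdivide), and
    ``year`` is a constant placeholder.
    """
    frames = []
    for q_idx, n_q in enumerate(QUINTILE_TOTALS):
        cols: dict[str, np.ndarray] = {"exposure": np.full(n_q, q_idx + 1, dtype=int)}
        for var in TABLE1_COUNTS:
            cols[var] = _expand_column(var, q_idx, n_q)
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)
    for col in ("preterm", "mental_health", "physical_health", "obstetric_conditions"):
        df[col] = df[col].astype(int)
    df["smoking"] = pd.array(pd.to_numeric(df["smoking"]), dtype="Int64")
    for col, cats in _CATEGORIES.items():
        if col in df.columns:
            df[col] = pd.Categorical(df[col], categories=cats)
    df["ga_category"] = pd.Categorical(
        np.where(df["preterm"] == 1, "moderate_preterm", "term"), categories=GA_LEVELS
    )
    df["year"] = 2010
    return df
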