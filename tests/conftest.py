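import numpy as np
import pandas as pd
import pytest

import ptbmediation as pm


@pytest.fixture(scope="session")
def mixed_params():
    return pm.default_params(n=20_000, seed=101)


@pytest.fixture(scope="session")
def mixed_raw(mixed_params):
    return pm.generate_cohort(mixed_params)


@pytest.fixture(scope="session")
def mixed_coded(mixed_raw):
    included, _ = pm.apply_inclusion_filters(mixed_raw)
    return pm.code_analysis_records(included)


@pytest.fixture(scope="session")
def idm_fit(mixed_coded):
    """Fitted IDM model set on the small mixed cohort (complete data)."""
    return pm.fit_idm_models(mixed_coded)


@pytest.fixture()
def tiny_raw():
    """Hand-written raw cohort covering inclusion edge cases."""
    base = dict(
        gestational_age_weeks=39, birthweight_g=3200, maternal_age_years=28,
        parity=1, marital_status="married_cp", wimd_quintile=3, smoking=0,
        mental_health=0, physical_health=0, obstetric_conditions=0,
        singleton=1, live_birth=1, year=2010,
    )
    rows = [
        dict(base),  # valid
        dict(base, gestational_age_weeks=21),  # too early
        dict(base, gestational_age_weeks=21, birthweight_g=400),  # two reasons
        dict(base, maternal_age_years=52),
        dict(base, parity=12),
        dict(base, parity=None),  # missing parity retained
        dict(base, singleton=0),
        dict(base, wimd_quintile=None),
    ]
    df = pd.DataFrame(rows)
    for col in df.columns:
        if col != "marital_status":
            df[col] = pd.array(df[col], dtype="Int64")
    df["marital_status"] = pd.Categorical(df["marital_status"], categories=pm.cohort.MARITAL_LEVELS)
    return df
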