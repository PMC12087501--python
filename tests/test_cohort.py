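"""Inclusion filtering, variable coding and cohort CSV round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ptbmediation as pm
from ptbmediation.cohort import GA_LEVELS, SchemaError, ga_category


class TestInclusionFilters:
    def test_edge_cases_and_reason_counts(self, tiny_raw):
        included, counts = pm.apply_inclusion_filters(tiny_raw)
        # valid row and the missing-parity row survive
        assert len(included) == 2
        assert included["parity"].isna().sum() == 1
        assert counts["gestation"] == 2
        assert counts["birthweight"] == 1
        assert counts["maternal_age"] == 1
        assert counts["parity"] == 1
        assert counts["not_singleton"] == 1
        assert counts["missing_wimd"] == 1
        # reasons are not mutually exclusive: totals can exceed excluded rows
        n_excluded = len(tiny_raw) - len(included)
        assert sum(counts.values()) >= n_excluded

    def test_idempotence(self, mixed_raw):
        included, _ = pm.apply_inclusion_filters(mixed_raw)
        again, counts = pm.apply_inclusion_filters(included)
        assert len(again) == len(included)
        assert all(v == 0 for v in counts.values())


class TestCoding:
    @pytest.mark.parametrize(
        "weeks,preterm,category",
        [
            (22, 1, "extremely_preterm"),
            (27, 1, "extremely_preterm"),
            (28, 1, "very_preterm"),
            (31, 1, "very_preterm"),
            (32, 1, "moderate_preterm"),
            (36, 1, "moderate_preterm"),
            (37, 0, "early_term"),
            (38, 0, "early_term"),
            (39, 0, "term"),
            (41, 0, "term"),
            (42, 0, "post_term"),
            (43, 0, "post_term"),
        ],
    )
    def test_ga_coding(self, tiny_raw, weeks, preterm, category):
        row = tiny_raw.iloc[[0]].copy()
        row["gestational_age_weeks"] = weeks
        coded = pm.code_analysis_records(row)
        assert coded["preterm"].iloc[0] == preterm
        assert coded["ga_category"].iloc[0] == category

    def test_cutoff_34(self, tiny_raw):
        row = tiny_raw.iloc[[0]].copy()
        row["gestational_age_weeks"] = 36
        coded = pm.code_analysis_records(row, preterm_cutoff_weeks=34)
        assert coded["preterm"].iloc[0] == 0
        assert coded["ga_category"].iloc[0] == "moderate_preterm"

    @given(st.integers(min_value=22, max_value=43))
    @settings(max_examples=22, deadline=None, derandomize=True)
    def test_ga_partition(self, weeks):
        """Every included gestational age maps to exactly one category, and
        the preterm dichotomy matches the preterm categories."""
        cat = ga_category(weeks)
        assert cat in GA_LEVELS
        preterm_cats = {"extremely_preterm", "very_preterm", "moderate_preterm"}
        assert (weeks < 37) == (cat in preterm_cats)

    def test_contract_violation_outside_range(self, tiny_raw):
        row = tiny_raw.iloc[[0]].copy()
        row["gestational_age_weeks"] = 21
        with pytest.raises(ValueError, match="22-43"):
            pm.code_analysis_records(row)

    def test_order_independence(self, mixed_raw):
        included, _ = pm.apply_inclusion_filters(mixed_raw)
        shuffled = included.sample(frac=1, random_state=7).reset_index(drop=True)
        a = pm.code_analysis_records(included).sort_values(list(pm.cohort.ANALYSIS_COLUMNS)).reset_index(drop=True)
        b = pm.code_analysis_records(shuffled).sort_values(list(pm.cohort.ANALYSIS_COLUMNS)).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_missingness_propagates(self, mixed_params, mixed_raw):
        masked = pm.inject_missingness(mixed_raw, mixed_params)
        included, _ = pm.apply_inclusion_filters(masked)
        coded = pm.code_analysis_records(included)
        assert coded["smoking"].isna().sum() == included["smoking"].isna().sum()
        assert coded["parity_cat"].isna().sum() == included["parity"].isna().sum()


class TestRoundTrip:
    def test_write_read_identity(self, mixed_params, mixed_raw, tmp_path):
        masked = pm.inject_missingness(mixed_raw.head(1000), mixed_params)
        path = tmp_path / "cohort.csv"
        pm.write_cohort(masked, path)
        back = pm.read_cohort(path)
        pd.testing.assert_frame_equal(back, masked.reset_index(drop=True), check_categorical=False)

    def test_missing_token_configurable(self, mixed_raw, tmp_path):
        path = tmp_path / "cohort.csv"
        pm.write_cohort(mixed_raw.head(5), path, missing_token="NA")
        back = pm.read_cohort(path, missing_token="NA")
        assert len(back) == 5

    def test_empty_cell_is_missing(self, tmp_path):
        path = tmp_path / "cohort.csv"
        header = ",".join(pm.cohort.COHORT_COLUMNS)
        row = "39,3200,28,1,married_cp,3,,0,0,0,1,1,2010"
        path.write_text(header + "\n" + row + "\n")
        back = pm.read_cohort(path)
        assert back["smoking"].isna().iloc[0]

    def test_missing_column_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("gestational_age_weeks\n39\n")
        with pytest.raises(SchemaError, match="birthweight_g"):
            pm.read_cohort(path)
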