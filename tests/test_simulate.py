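"""Generator calibration, determinism, MAR injection and exact estimands."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import ptbmediation as pm
from ptbmediation.cohort import AGE_LEVELS, MARITAL_LEVELS, PARITY_LEVELS
from ptbmediation.simulate import (
    QUINTILES,
    _conf_cells,
    _targets_from_counts,
    scenario_params,
)


class TestGeneration:
    def test_determinism(self):
        p = pm.default_params(n=2_000, seed=42)
        a, b = pm.generate_cohort(p), pm.generate_cohort(p)
        pd.testing.assert_frame_equal(a, b)

    def test_smoking_gradient_matches_published_margins(self):
        p = pm.default_params(n=50_000, seed=7)
        df = pm.generate_cohort(p)
        targets = _targets_from_counts("smoking")
        for q in QUINTILES:
            sub = df[df["wimd_quintile"] == q]
            prev = float(sub["smoking"].mean())
            se = np.sqrt(targets[q - 1] * (1 - targets[q - 1]) / len(sub))
            assert abs(prev - targets[q - 1]) < 4 * se

    def test_null_scenario_flat_across_quintiles(self):
        """With every exposure and confounder coefficient zero, mediator
        prevalence is equal across quintiles up to sampling error."""
        from scipy.special import logit

        from ptbmediation.simulate import GenLogit

        p = scenario_params("null", n=60_000, seed=8)
        p.model_smoking = GenLogit(intercept=float(logit(0.154)))
        df = pm.generate_cohort(p)
        overall = float(df["smoking"].mean())
        for q in QUINTILES:
            sub = df[df["wimd_quintile"] == q]
            se = np.sqrt(overall * (1 - overall) / len(sub))
            assert abs(float(sub["smoking"].mean()) - overall) < 4 * se

    def test_all_records_pass_inclusion(self, mixed_raw):
        included, counts = pm.apply_inclusion_filters(mixed_raw)
        assert len(included) == len(mixed_raw)
        assert all(v == 0 for v in counts.values())


class TestMissingness:
    def test_marginal_fractions(self):
        p = pm.default_params(n=100_000, seed=3)
        masked = pm.inject_missingness(pm.generate_cohort(p), p)
        assert abs(masked["smoking"].isna().mean() - 0.329) < 0.006
        assert abs(masked["parity"].isna().mean() - 0.161) < 0.005
        assert abs(masked["marital_status"].isna().mean() - 0.016) < 0.002

    def test_per_quintile_rates_follow_logit(self):
        p = pm.default_params(n=100_000, seed=4)
        masked = pm.inject_missingness(pm.generate_cohort(p), p)
        model = p.missingness["smoking"]
        for q in QUINTILES:
            sub = masked[masked["wimd_quintile"] == q]
            implied = float(np.mean(model.prob(np.full(len(sub), q), sub["year"].to_numpy(dtype=int))))
            rate = float(sub["smoking"].isna().mean())
            se = np.sqrt(implied * (1 - implied) / len(sub))
            assert abs(rate - implied) < 4 * se

    def test_no_missingness_when_disabled(self, mixed_raw, mixed_params):
        import dataclasses

        p = dataclasses.replace(mixed_params, missingness={})
        masked = pm.inject_missingness(mixed_raw, p)
        assert not masked.isna().any().any()


class TestTrueEstimands:
    def test_null_scenario_all_zero(self):
        t = pm.true_estimands(scenario_params("null", n=10, seed=0))
        for key in ("taa", "idm_direct", "idm_indirect_S", "idm_indirect_MH",
                    "idm_indirect_PH", "idm_indirect_O", "mediated_dependence"):
            assert abs(getattr(t, key)) < 1e-10
        assert t.or_total == pytest.approx(1.0)
        assert t.cde == pytest.approx(1.0)

    def test_full_mediation_through_smoking(self):
        t = pm.true_estimands(scenario_params("smoking_only", n=10, seed=0))
        assert abs(t.idm_direct) < 1e-10
        assert t.idm_indirect_S == pytest.approx(t.taa, abs=1e-10)
        assert abs(t.idm_indirect_MH) < 1e-10
        assert abs(t.mediated_dependence) < 1e-10
        assert t.cde == pytest.approx(1.0)

    def test_additivity_machine_precision(self):
        for name in pm.simulate.SCENARIOS:
            t = pm.true_estimands(scenario_params(name, n=10, seed=0))
            assert t.taa == pytest.approx(
                t.idm_direct + t.indirect_total + t.mediated_dependence, abs=1e-10
            )

    def test_monotone_in_outcome_exposure_coefficient(self):
        import copy

        p = pm.default_params(n=10, seed=0)
        base = pm.true_estimands(p)
        stronger = copy.deepcopy(p)
        stronger.model_preterm.exposure[1] += 0.2
        boosted = pm.true_estimands(stronger)
        assert boosted.taa > base.taa
        assert boosted.idm_direct > base.idm_direct

    def test_taa_agrees_with_independent_forward_simulation(self):
        """Exact enumeration vs a from-scratch forward simulator of the
        generating mechanism (samples confounders from the population mix,
        fixes exposure, draws mediators sequentially, averages outcome
        probability)."""
        p = pm.default_params(n=10, seed=0)
        rng = np.random.default_rng(12345)
        n = 200_000

        # population confounder mix: quintile draws give each quintile's tables
        qs = rng.choice(np.asarray(QUINTILES), size=n, p=p.exposure_probs)
        age = np.empty(n, dtype=object)
        par = np.empty(n, dtype=object)
        mar = np.empty(n, dtype=object)
        for q in QUINTILES:
            idx = np.flatnonzero(qs == q)
            age[idx] = rng.choice(np.asarray(AGE_LEVELS, dtype=object), size=len(idx), p=p.age_probs[q])
            par[idx] = rng.choice(np.asarray(PARITY_LEVELS, dtype=object), size=len(idx), p=p.parity_probs[q])
            mar[idx] = rng.choice(np.asarray(MARITAL_LEVELS, dtype=object), size=len(idx), p=p.marital_probs[q])

        def mean_risk(x):
            lp = lambda model, med: np.array(
                [model.lp(x, age[i], par[i], mar[i], med if med is None else {k: v[i] for k, v in med.items()})
                 for i in range(n)]
            )
            draws = {}
            for name, model in (("smoking", p.model_smoking), ("mental_health", p.model_mental),
                                ("physical_health", p.model_physical)):
                prob = expit(np.array([model.lp(x, age[i], par[i], mar[i]) for i in range(n)]))
                draws[name] = (rng.random(n) < prob).astype(int)
            po = expit(lp(p.model_obstetric, draws))
            draws["obstetric_conditions"] = (rng.random(n) < po).astype(int)
            py = expit(lp(p.model_preterm, draws))
            return float(py.mean()), float(py.std() / np.sqrt(n))

        r1, se1 = mean_risk(1)
        r5, se5 = mean_risk(5)
        sim_taa = 100 * (r1 - r5)
        se = 100 * np.sqrt(se1**2 + se5**2)
        exact = pm.true_estimands(p).taa
        assert abs(sim_taa - exact) < 3 * se

    def test_scenario_name_validation(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario_params("bogus")
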