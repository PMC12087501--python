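"""Interventional disparity machinery: DAG ordering, oracle equivalence,
decomposition identities and invariances."""

import itertools

import numpy as np
import pandas as pd
import pytest

import ptbmediation as pm
from ptbmediation._glm import fit_logit
from ptbmediation.cohort import MEDIATORS
from ptbmediation.idm import IdmModelSet


class TestModelSet:
    def test_dag_ordering_of_predictors(self, idm_fit):
        assert "smoking" in idm_fit.model_O.formula
        assert "physical_health" in idm_fit.model_O.formula
        assert "obstetric_conditions" not in idm_fit.model_S.formula
        assert all(m in idm_fit.model_Y.formula for m in MEDIATORS)

    def test_refit_identical(self, mixed_coded, idm_fit):
        again = pm.fit_idm_models(mixed_coded)
        pd.testing.assert_series_equal(again.model_Y.params, idm_fit.model_Y.params)

    def test_requires_complete_mediators(self, mixed_coded):
        broken = mixed_coded.copy()
        broken.loc[0, "smoking"] = pd.NA
        with pytest.raises(ValueError, match="complete mediator"):
            pm.fit_idm_models(broken)


class TestStandardize:
    def test_no_shift_identity(self, idm_fit, mixed_coded):
        a = pm.enumerate_standardize(idm_fit, mixed_coded, 1, (), 1)
        b = pm.enumerate_standardize(idm_fit, mixed_coded, 1, MEDIATORS, 1)
        assert a == pytest.approx(b, abs=1e-12)

    def test_manual_sixteen_state_sum_single_cell(self, idm_fit, mixed_coded):
        """Independent hand computation: restrict to one covariate pattern and
        sum model probabilities over the 16 mediator states explicitly."""
        cell = mixed_coded.groupby(["age_cat", "parity_cat", "marital_status"], observed=True)
        key = list(cell.groups)[0]
        sub = cell.get_group(key).copy()
        target, donor = 1, 5

        row = sub.iloc[[0]].copy()
        p_up = {}
        for name, model in (("smoking", idm_fit.model_S), ("mental_health", idm_fit.model_MH),
                            ("physical_health", idm_fit.model_PH)):
            x = donor if name == "smoking" else target
            p_up[name] = float(model.predict(row.assign(exposure=x))[0])
        total = 0.0
        for s, mh, ph, o in itertools.product((0, 1), repeat=4):
            r = row.assign(smoking=s, mental_health=mh, physical_health=ph, obstetric_conditions=o)
            pO = float(idm_fit.model_O.predict(r.assign(exposure=target))[0])
            pY = float(idm_fit.model_Y.predict(r.assign(exposure=target))[0])
            pr = (
                (p_up["smoking"] if s else 1 - p_up["smoking"])
                * (p_up["mental_health"] if mh else 1 - p_up["mental_health"])
                * (p_up["physical_health"] if ph else 1 - p_up["physical_health"])
                * (pO if o else 1 - pO)
            )
            total += pr * pY
        package = pm.enumerate_standardize(idm_fit, sub, target, ("smoking",), donor)
        assert package == pytest.approx(total, abs=1e-12)

    def test_mc_agrees_with_enumeration(self, idm_fit, mixed_coded):
        for shift in ((), ("smoking",), MEDIATORS):
            exact = pm.enumerate_standardize(idm_fit, mixed_coded, 1, shift, 5)
            mc, se = pm.mc_standardize(
                idm_fit, mixed_coded, 1, shift, 5, k_expansions=500, seed=4, return_se=True
            )
            assert abs(mc - exact) < 3 * se

    def test_shift_irrelevant_when_outcome_ignores_mediators(self, mixed_coded):
        """If the outcome model contains no mediators, shifting mediator
        distributions cannot change the standardised risk."""
        conf = "C(exposure, Treatment(5)) + C(age_cat, Treatment('25-34'))"
        mediator_free = IdmModelSet(
            model_S=fit_logit(f"smoking ~ {conf}", mixed_coded),
            model_MH=fit_logit(f"mental_health ~ {conf}", mixed_coded),
            model_PH=fit_logit(f"physical_health ~ {conf}", mixed_coded),
            model_O=fit_logit(f"obstetric_conditions ~ {conf} + smoking", mixed_coded),
            model_Y=fit_logit(f"preterm ~ {conf}", mixed_coded),
        )
        base = pm.enumerate_standardize(mediator_free, mixed_coded, 1, (), 5)
        for shift in (("smoking",), MEDIATORS):
            assert pm.enumerate_standardize(mediator_free, mixed_coded, 1, shift, 5) == pytest.approx(base, abs=1e-12)

    def test_k_expansions_validation(self, idm_fit, mixed_coded):
        with pytest.raises(ValueError, match="k_expansions"):
            pm.mc_standardize(idm_fit, mixed_coded, 1, (), 5, k_expansions=0)
        with pytest.raises(ValueError, match="unknown mediators"):
            pm.enumerate_standardize(idm_fit, mixed_coded, 1, ("nope",), 5)

    def test_record_order_invariance(self, idm_fit, mixed_coded):
        shuffled = mixed_coded.sample(frac=1, random_state=3)
        a = pm.enumerate_standardize(idm_fit, mixed_coded, 1, ("smoking",), 5)
        b = pm.enumerate_standardize(idm_fit, shuffled, 1, ("smoking",), 5)
        assert a == pytest.approx(b, abs=1e-12)


class TestDecompose:
    def test_additivity_machine_precision(self, idm_fit, mixed_coded):
        dec = pm.decompose(idm_fit, mixed_coded, k_expansions=50, seed=1)
        total = dec.idm_direct + dec.idm_indirect_S + dec.idm_indirect_MH + dec.idm_indirect_PH + dec.idm_indirect_O + dec.mediated_dependence
        assert dec.taa == pytest.approx(total, abs=1e-12)

    def test_enumerate_and_mc_paths_agree(self, idm_fit, mixed_coded):
        exact = pm.decompose(idm_fit, mixed_coded, method="enumerate")
        mc = pm.decompose(idm_fit, mixed_coded, k_expansions=500, seed=2, method="mc")
        assert mc.taa == pytest.approx(exact.taa, abs=0.05)
        assert mc.idm_indirect_S == pytest.approx(exact.idm_indirect_S, abs=0.05)

    def test_seed_invariance_in_expectation(self, idm_fit, mixed_coded):
        _, se = pm.mc_standardize(idm_fit, mixed_coded, 1, ("smoking",), 5,
                                  k_expansions=500, seed=11, return_se=True)
        a = pm.decompose(idm_fit, mixed_coded, k_expansions=500, seed=11).taa
        b = pm.decompose(idm_fit, mixed_coded, k_expansions=500, seed=12).taa
        assert abs(a - b) < 3 * (100 * se * np.sqrt(2) * np.sqrt(2))  # two risks, two seeds

    def test_pool_decompositions_mean(self, idm_fit, mixed_coded):
        d1 = pm.decompose(idm_fit, mixed_coded, method="enumerate")
        pooled = pm.pool_decompositions([d1, d1])
        assert pooled.taa == pytest.approx(d1.taa)
        with pytest.raises(ValueError):
            pm.pool_decompositions([])

    def test_to_frame_percent_of_total(self, idm_fit, mixed_coded):
        dec = pm.decompose(idm_fit, mixed_coded, method="enumerate")
        frame = dec.to_frame()
        taa_row = frame[frame["component"] == "total_adjusted_association"]
        assert taa_row["percent_of_total"].iloc[0] == pytest.approx(100.0)
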