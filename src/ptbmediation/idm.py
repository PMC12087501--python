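"""Interventional disparity measures by g-computation standardisation.

The estimand asks how the deprivation-outcome association would change if the
distribution of a mediator among the most deprived quintile were shifted, by
intervention, to the distribution seen in the least deprived quintile. Five
richly specified logistic models (all two-way interactions among each model's
predictors) encode the working DAG: smoking, mental health and physical
health depend on exposure and confounders; obstetric conditions additionally
depend on the three upstream mediators; the outcome depends on exposure,
confounders and all four mediators.

Standardised risks are computed two ways with the same estimand:

* :func:`mc_standardize` - Monte-Carlo g-computation: each record in the
  standardisation population is expanded ``k`` times, mediators are drawn
  sequentially from their fitted models (shifted mediators see the donor
  quintile; shifted smoking propagates into the obstetric-conditions draw),
  and the outcome model's predicted probability is averaged.
* :func:`enumerate_standardize` - exact summation over the 2^4 mediator
  states per confounder cell; zero Monte-Carlo error. The two agree in
  expectation; enumeration is the fast path used in testing.

The decomposition reports, on the absolute (percentage-point) scale: the
total adjusted association (TAA), the direct path, one indirect path per
mediator, and the mediated dependence remainder; proportions mediated are
indirect paths divided by the TAA. Additivity
``TAA = direct + sum(indirect) + mediated dependence`` holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._glm import CONFOUNDER_TERMS, EXPOSURE_TERM, FittedLogit, fit_logit
from .cohort import MEDIATORS

UPSTREAM = MEDIATORS[:3]

_SHORT = {"smoking": "S", "mental_health": "MH", "physical_health": "PH", "obstetric_conditions": "O"}


@dataclass
class IdmModelSet:
    """The five fitted models, ordered per the working DAG."""

    model_S: FittedLogit
    model_MH: FittedLogit
    model_PH: FittedLogit
    model_O: FittedLogit
    model_Y: FittedLogit

    def upstream_model(self, name: str) -> FittedLogit:
        return {"smoking": self.model_S, "mental_health": self.model_MH, "physical_health": self.model_PH}[name]


@dataclass
class IdmDecomposition:
    """TAA, direct, per-mediator indirect paths, mediated dependence (all in
    percentage points) and proportions mediated (fractions of the TAA)."""

    taa: float
    idm_direct: float
    idm_indirect_S: float
    idm_indirect_MH: float
    idm_indirect_PH: float
    idm_indirect_O: float
    mediated_dependence: float
    pm_S: float
    pm_MH: float
    pm_PH: float
    pm_O: float

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}

    def to_frame(self) -> pd.DataFrame:
        """Absolute change plus percent-of-total, one row per component."""
        comps = [
            ("total_adjusted_association", self.taa),
            ("direct", self.idm_direct),
            ("indirect_smoking", self.idm_indirect_S),
            ("indirect_mental_health", self.idm_indirect_MH),
            ("indirect_physical_health", self.idm_indirect_PH),
            ("indirect_obstetric_conditions", self.idm_indirect_O),
            ("mediated_dependence", self.mediated_dependence),
        ]
        df = pd.DataFrame(comps, columns=["component", "percentage_points"])
        df["percent_of_total"] = 100.0 * df["percentage_points"] / self.taa if self.taa else np.nan
        return df


def _prepare(records: pd.DataFrame) -> pd.DataFrame:
    if records[list(MEDIATORS)].isna().any().any():
        raise ValueError("IDM estimation requires complete mediator data (impute first)")
    out = records.copy()
    for m in MEDIATORS:
        out[m] = out[m].astype(int)
    return out


def fit_idm_models(
    records: pd.DataFrame, include_marital: bool = True, include_year: bool = False
) -> IdmModelSet:
    """Fit the five richly specified models on one completed dataset."""
    records = _prepare(records)
    conf = [EXPOSURE_TERM] + [t for t in CONFOUNDER_TERMS if include_marital or "marital" not in t]
    if include_year:
        conf = conf + ["year"]

    def rich(terms: list[str]) -> str:
        return "(" + " + ".join(terms) + ")**2"

    return IdmModelSet(
        model_S=fit_logit("smoking ~ " + rich(conf), records),
        model_MH=fit_logit("mental_health ~ " + rich(conf), records),
        model_PH=fit_logit("physical_health ~ " + rich(conf), records),
        model_O=fit_logit("obstetric_conditions ~ " + rich(conf + list(UPSTREAM)), records),
        model_Y=fit_logit("preterm ~ " + rich(conf + list(MEDIATORS)), records),
    )


def _cell_frame(models: IdmModelSet, records: pd.DataFrame, population: str) -> pd.DataFrame:
    """Standardisation population collapsed to unique covariate cells."""
    if population == "exposed":
        records = records[records["exposure"] == 1]
    elif population != "full":
        raise ValueError("population must be 'full' or 'exposed'")
    keys = ["age_cat", "parity_cat", "marital_status"]
    if "year" in models.model_Y.formula:
        keys.append("year")
    cells = records.groupby(keys, observed=True, dropna=False).size().reset_index(name="weight")
    cells = cells[cells["weight"] > 0].reset_index(drop=True)
    if "year" not in cells.columns:
        cells["year"] = records["year"].iloc[0] if len(records) else 0
    return cells


_COMBOS8 = [(s, mh, ph) for s in (0, 1) for mh in (0, 1) for ph in (0, 1)]


def _mediator_probability_tables(
    models: IdmModelSet, cells: pd.DataFrame, target_quintile: int, shift_set, donor_quintile: int
):
    """Per-cell mediator probabilities under the requested shift.

    Returns (p_up, pO, pY0, pY1): p_up of shape (m, 8) joint upstream-state
    probabilities; pO of shape (m, 8); pY0/pY1 of shape (m, 8) outcome
    probabilities with obstetric conditions 0/1.
    """
    shift = set(shift_set)
    unknown = shift - set(MEDIATORS)
    if unknown:
        raise ValueError(f"unknown mediators in shift set: {sorted(unknown)}")
    m = len(cells)

    p_single = {}
    for name in UPSTREAM:
        x = donor_quintile if name in shift else target_quintile
        p_single[name] = models.upstream_model(name).predict(cells.assign(exposure=x))

    p_up = np.empty((m, 8))
    for j, (s, mh, ph) in enumerate(_COMBOS8):
        p_up[:, j] = (
            (p_single["smoking"] if s else 1 - p_single["smoking"])
            * (p_single["mental_health"] if mh else 1 - p_single["mental_health"])
            * (p_single["physical_health"] if ph else 1 - p_single["physical_health"])
        )

    xo = donor_quintile if "obstetric_conditions" in shift else target_quintile
    rep = cells.loc[cells.index.repeat(8)].reset_index(drop=True)
    combo = np.tile(np.asarray(_COMBOS8), (m, 1))
    rep["smoking"], rep["mental_health"], rep["physical_health"] = combo[:, 0], combo[:, 1], combo[:, 2]
    pO = models.model_O.predict(rep.assign(exposure=xo)).reshape(m, 8)
    rep_y = rep.assign(exposure=target_quintile)
    pY0 = models.model_Y.predict(rep_y.assign(obstetric_conditions=0)).reshape(m, 8)
    pY1 = models.model_Y.predict(rep_y.assign(obstetric_conditions=1)).reshape(m, 8)
    return p_up, pO, pY0, pY1


def enumerate_standardize(
    models: IdmModelSet,
    records: pd.DataFrame,
    target_quintile: int,
    shift_set=(),
    donor_quintile: int = 5,
    population: str = "full",
) -> float:
    """Exact standardised risk: sums over all mediator states per cell."""
    cells = _cell_frame(models, records, population)
    p_up, pO, pY0, pY1 = _mediator_probability_tables(models, cells, target_quintile, shift_set, donor_quintile)
    per_cell = np.sum(p_up * (pO * pY1 + (1 - pO) * pY0), axis=1)
    w = cells["weight"].to_numpy(float)
    return float(np.sum(w * per_cell) / w.sum())


def mc_standardize(
    models: IdmModelSet,
    records: pd.DataFrame,
    target_quintile: int,
    shift_set=(),
    donor_quintile: int = 5,
    k_expansions: int = 200,
    seed: int | None = None,
    population: str = "full",
    return_se: bool = False,
):
    """Monte-Carlo standardised risk with ``k_expansions`` replicates per record.

    Each record is expanded ``k_expansions`` times; upstream mediators are
    drawn from their fitted models (with the donor quintile substituted for
    shifted mediators), obstetric conditions are drawn conditional on the
    drawn upstream values, and the outcome model's predicted probability is
    averaged over all draws. Draws are pooled per covariate cell, which is
    distributionally identical to drawing record by record.
    """
    if k_expansions < 1:
        raise ValueError("k_expansions must be >= 1")
    rng = np.random.default_rng(seed)
    cells = _cell_frame(models, records, population)
    p_up, pO, pY0, pY1 = _mediator_probability_tables(models, cells, target_quintile, shift_set, donor_quintile)

    w = cells["weight"].to_numpy(float)
    wsum = w.sum()
    est = 0.0
    var_acc = 0.0
    for i in range(len(cells)):
        n_draws = int(round(w[i] * k_expansions))
        counts8 = rng.multinomial(n_draws, p_up[i] / p_up[i].sum())
        o1 = rng.binomial(counts8, pO[i])
        o0 = counts8 - o1
        total = float(np.sum(o1 * pY1[i] + o0 * pY0[i]))
        mean_i = total / n_draws
        est += (w[i] / wsum) * mean_i
        if return_se:
            dev2 = np.sum(o1 * (pY1[i] - mean_i) ** 2 + o0 * (pY0[i] - mean_i) ** 2) / n_draws
            var_acc += (w[i] / wsum) ** 2 * dev2 / n_draws
    if return_se:
        return float(est), float(np.sqrt(var_acc))
    return float(est)


def _risk(models, records, target, shift, donor, k_expansions, rng_seed, population, method):
    if method == "enumerate" or k_expansions == 0:
        return enumerate_standardize(models, records, target, shift, donor, population)
    return mc_standardize(models, records, target, shift, donor, k_expansions, rng_seed, population)


def decompose(
    models: IdmModelSet,
    records: pd.DataFrame,
    k_expansions: int = 200,
    seed: int | None = None,
    population: str = "full",
    method: str = "mc",
) -> IdmDecomposition:
    """Estimate the full interventional decomposition (percentage points).

    ``method="mc"`` uses Monte-Carlo standardisation with ``k_expansions``
    replicates per record (``k_expansions=0`` falls through to enumeration);
    ``method="enumerate"`` uses the exact path. Component definitions:
    TAA = risk(1) - risk(5); indirect_k = risk(1) - risk(1 with mediator k
    shifted to quintile 5); direct = risk(1 with all four shifted) - risk(5);
    mediated dependence is the additivity remainder.
    """
    seeds = np.random.SeedSequence(seed).generate_state(8).tolist()
    r15 = _risk(models, records, 1, (), 5, k_expansions, seeds[0], population, method)
    r55 = _risk(models, records, 5, (), 5, k_expansions, seeds[1], population, method)
    ind = {}
    for i, med in enumerate(MEDIATORS):
        ind[med] = r15 - _risk(models, records, 1, (med,), 5, k_expansions, seeds[2 + i], population, method)
    direct = _risk(models, records, 1, MEDIATORS, 5, k_expansions, seeds[6], population, method) - r55
    taa = r15 - r55
    md = taa - direct - sum(ind.values())
    if taa == 0:
        raise ValueError("total adjusted association is zero; proportions mediated undefined")
    return IdmDecomposition(
        taa=100 * taa,
        idm_direct=100 * direct,
        idm_indirect_S=100 * ind["smoking"],
        idm_indirect_MH=100 * ind["mental_health"],
        idm_indirect_PH=100 * ind["physical_health"],
        idm_indirect_O=100 * ind["obstetric_conditions"],
        mediated_dependence=100 * md,
        pm_S=ind["smoking"] / taa,
        pm_MH=ind["mental_health"] / taa,
        pm_PH=ind["physical_health"] / taa,
        pm_O=ind["obstetric_conditions"] / taa,
    )


def pool_decompositions(decomps: list[IdmDecomposition]) -> IdmDecomposition:
    """Average component estimates across completed (imputed) datasets."""
    if not decomps:
        raise ValueError("no decompositions to pool")
    fields = list(IdmDecomposition.__dataclass_fields__)
    means = {f: float(np.mean([getattr(d, f) for d in decomps])) for f in fields}
    return IdmDecomposition(**means)
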