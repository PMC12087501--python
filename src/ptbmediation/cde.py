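"""Controlled direct effects and proportion eliminated.

Two logistic models estimate the inequality in preterm birth between
deprivation quintiles. Model 1 (total effect) regresses the outcome on the
exposure and baseline confounders; its exposure odds ratio is the total
effect. Model 2 adds the four mediators, exposure-by-mediator interactions
and mediator-by-mediator interactions; because every mediator is coded 0/1
with 0 = absent, the exposure main-effect odds ratio in Model 2 is the
controlled direct effect (CDE) with all mediators fixed at absent.

The proportion eliminated compares the two odds ratios:

    PE = (OR_total - OR_CDE) / (OR_total - 1)

Serial logistic contrasts repeat both models for each non-reference
gestational-age category against term births only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import pandas as pd

from ._glm import CONFOUNDER_TERMS, EXPOSURE_TERM, FittedLogit, fit_logit
from .cohort import GA_LEVELS, MEDIATORS


class ProportionEliminatedUndefined(ValueError):
    """PE is undefined when the total-effect odds ratio equals 1."""


@dataclass
class CdeResult:
    """Total-effect and CDE odds ratios (per quintile vs 5) with PE for Q1."""

    or_total: dict
    cde: dict
    proportion_eliminated: float


def _confounder_terms(include_marital: bool = True, include_year: bool = False) -> list[str]:
    terms = [t for t in CONFOUNDER_TERMS if include_marital or "marital" not in t]
    if include_year:
        terms.append("year")
    return terms


def _mediator_terms(smoking_levels: int) -> list[str]:
    if smoking_levels == 3:
        return ["C(smoking3, Treatment('never'))"] + list(MEDIATORS[1:])
    return list(MEDIATORS)


def fit_total_effect(
    records: pd.DataFrame,
    outcome: str = "preterm",
    include_marital: bool = True,
    include_year: bool = False,
) -> FittedLogit:
    """Model 1: outcome on exposure and baseline confounders."""
    terms = [EXPOSURE_TERM] + _confounder_terms(include_marital, include_year)
    return fit_logit(f"{outcome} ~ " + " + ".join(terms), records)


def fit_cde_model(
    records: pd.DataFrame,
    outcome: str = "preterm",
    include_marital: bool = True,
    include_year: bool = False,
    mediator_interactions: str = "all_pairs",
    smoking_levels: int = 2,
) -> FittedLogit:
    """Model 2: adds mediators, exposure-mediator and mediator-mediator terms.

    ``mediator_interactions`` is either ``"all_pairs"`` (all six pairwise
    mediator products) or ``"smoking_obstetric"`` (the single
    smoking-by-obstetric term).
    """
    meds = _mediator_terms(smoking_levels)
    terms = [EXPOSURE_TERM] + meds + _confounder_terms(include_marital, include_year)
    terms += [f"{EXPOSURE_TERM}:{m}" for m in meds]
    if mediator_interactions == "all_pairs":
        terms += [f"{a}:{b}" for a, b in itertools.combinations(meds, 2)]
    elif mediator_interactions == "smoking_obstetric":
        terms.append(f"{meds[0]}:obstetric_conditions")
    else:
        raise ValueError(f"unknown mediator_interactions {mediator_interactions!r}")
    return fit_logit(f"{outcome} ~ " + " + ".join(terms), records)


def proportion_eliminated(or_total: float, or_cde: float) -> float:
    """PE = (OR_total - OR_CDE) / (OR_total - 1); undefined at OR_total = 1."""
    if or_total == 1:
        raise ProportionEliminatedUndefined("total-effect OR equals 1; PE undefined")
    return (or_total - or_cde) / (or_total - 1)


def estimate_cde(records: pd.DataFrame, **model_kwargs) -> CdeResult:
    """Fit both models and report per-quintile ORs with PE for quintile 1."""
    m1 = fit_total_effect(
        records,
        outcome=model_kwargs.pop("outcome", "preterm"),
        include_marital=model_kwargs.get("include_marital", True),
        include_year=model_kwargs.get("include_year", False),
    )
    m2 = fit_cde_model(records, **model_kwargs)
    or_total = {q: m1.odds_ratio(q) for q in (1, 2, 3, 4)}
    cde = {q: m2.odds_ratio(q) for q in (1, 2, 3, 4)}
    return CdeResult(
        or_total=or_total,
        cde=cde,
        proportion_eliminated=proportion_eliminated(or_total[1], cde[1]),
    )


def fit_ga_category_contrasts(
    records: pd.DataFrame,
    reference: str = "term",
    min_events_per_quintile: int = 2,
    **model_kwargs,
) -> dict[str, tuple[FittedLogit | None, FittedLogit | None]]:
    """Serial logits: each gestational-age category vs term births only.

    For every non-reference category the data are reduced to that category
    plus term, the outcome is membership of the category, and Model 1 /
    Model 2 analogues are fitted. Categories with fewer than
    ``min_events_per_quintile`` events in any quintile are skipped with a
    warning and map to ``(None, None)``.
    """
    out: dict[str, tuple] = {}
    for cat in GA_LEVELS:
        if cat == reference:
            continue
        sub = records[records["ga_category"].isin([cat, reference])].copy()
        sub["ga_event"] = (sub["ga_category"] == cat).astype(int)
        events = sub.groupby("exposure", observed=True)["ga_event"].sum()
        if len(events) < 5 or (events < min_events_per_quintile).any():
            warnings.warn(f"gestational-age category {cat!r}: too few events per quintile; skipped")
            out[cat] = (None, None)
            continue
        m1 = fit_total_effect(sub, outcome="ga_event", **{k: model_kwargs[k] for k in ("include_marital", "include_year") if k in model_kwargs})
        m2 = fit_cde_model(sub, outcome="ga_event", **model_kwargs)
        out[cat] = (m1, m2)
    return out
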