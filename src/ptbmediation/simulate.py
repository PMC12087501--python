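"""Synthetic cohort generator with a known causal structure and exact truth.

The generator emulates a national routine-maternity cohort: a five-level
area-deprivation exposure (quintile 1 = most deprived, quintile 5 = reference),
three confounders (maternal age band, parity category, marital status) whose
distributions vary by quintile, three upstream binary mediators drawn
independently given exposure and confounders (smoking in pregnancy, maternal
mental ill health, hospitalisation for physical health), a fourth mediator
downstream of the other three (obstetric conditions), and a binary preterm
outcome depending on exposure, confounders and all four mediators. Missing
values in smoking, parity and marital status are injected by a
missing-at-random mechanism depending on exposure and year only.

All generating models are logistic. Default parameters are calibrated by
moment matching on the intercept/exposure offsets so that per-quintile
prevalences of the mediators and outcome reproduce the published descriptive
margins of the Welsh 2000-2019 birth cohort; non-exposure coefficients are
fixed at plausible values (documented in ``docs/methods.md``).

Because the covariate/mediator space is finite and discrete (5 x 48 cells x
2^4 mediator states), every interventional estimand has an exact value
computable by enumeration: :func:`true_estimands` returns the decomposition
with zero Monte-Carlo error, for parameter-recovery testing.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import AGE_LEVELS, MARITAL_LEVELS, MEDIATORS, PARITY_LEVELS
from .datasets import QUINTILE_TOTALS, TABLE1_COUNTS

logger = logging.getLogger(__name__)

QUINTILES = (1, 2, 3, 4, 5)
SCENARIOS = ("null", "direct_only", "smoking_only", "obstetric_dependent", "mixed")

UPSTREAM = ("smoking", "mental_health", "physical_health")


@dataclass
class GenLogit:
    """A generating logistic model on the log-odds scale.

    ``exposure`` maps quintile -> coefficient (reference quintile 5 implicit
    zero); ``age``/``parity``/``marital`` map category -> coefficient
    (unlisted categories zero); ``mediators`` maps upstream mediator name ->
    coefficient; ``interactions`` maps (quintile, mediator) -> coefficient
    (exposure-by-mediator, outcome model only).
    """

    intercept: float = 0.0
    exposure: dict = field(default_factory=dict)
    age: dict = field(default_factory=dict)
    parity: dict = field(default_factory=dict)
    marital: dict = field(default_factory=dict)
    mediators: dict = field(default_factory=dict)
    interactions: dict = field(default_factory=dict)

    def lp(self, q: int, age: str, parity: str, marital: str, med: dict | None = None) -> float:
        x = (
            self.intercept
            + self.exposure.get(q, 0.0)
            + self.age.get(age, 0.0)
            + self.parity.get(parity, 0.0)
            + self.marital.get(marital, 0.0)
        )
        if med:
            for name, value in med.items():
                if value:
                    x += self.mediators.get(name, 0.0) + self.interactions.get((q, name), 0.0)
        return x

    def base_lp(self, age: str, parity: str, marital: str, med: dict | None = None, q: int | None = None) -> float:
        """Linear predictor without intercept and exposure main effect."""
        x = self.age.get(age, 0.0) + self.parity.get(parity, 0.0) + self.marital.get(marital, 0.0)
        if med:
            for name, value in med.items():
                if value:
                    x += self.mediators.get(name, 0.0)
                    if q is not None:
                        x += self.interactions.get((q, name), 0.0)
        return x


@dataclass
class MissingnessLogit:
    """MAR missingness model: logit depends on exposure quintile and year."""

    intercept: float = -30.0  # effectively no missingness unless configured
    exposure: dict = field(default_factory=dict)
    year_per_decade: float = 0.0

    def prob(self, q, year) -> np.ndarray:
        lp = (
            self.intercept
            + np.vectorize(lambda v: self.exposure.get(int(v), 0.0))(q)
            + self.year_per_decade * (np.asarray(year) - 2010) / 10.0
        )
        return expit(lp)


@dataclass
class GeneratorParams:
    """Full generating mechanism for a synthetic cohort."""

    n: int
    seed: int
    exposure_probs: np.ndarray  # length 5, quintiles 1..5
    age_probs: dict  # quintile -> probs over AGE_LEVELS
    parity_probs: dict  # quintile -> probs over PARITY_LEVELS
    marital_probs: dict  # quintile -> probs over MARITAL_LEVELS
    model_smoking: GenLogit
    model_mental: GenLogit
    model_physical: GenLogit
    model_obstetric: GenLogit
    model_preterm: GenLogit
    missingness: dict = field(default_factory=dict)  # var -> MissingnessLogit
    ga_preterm_weights: dict = field(default_factory=dict)  # weeks 22..36 -> weight
    ga_term_weights: dict = field(default_factory=dict)  # weeks 37..43 -> weight
    year_range: tuple = (2000, 2019)

    def __post_init__(self):
        self.exposure_probs = np.asarray(self.exposure_probs, dtype=float)
        if abs(self.exposure_probs.sum() - 1.0) > 1e-9 or (self.exposure_probs < 0).any():
            raise ValueError("exposure_probs must be a probability vector over 5 quintiles")
        for table, levels in (
            (self.age_probs, AGE_LEVELS),
            (self.parity_probs, PARITY_LEVELS),
            (self.marital_probs, MARITAL_LEVELS),
        ):
            for q in QUINTILES:
                p = np.asarray(table[q], dtype=float)
                if len(p) != len(levels) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                    raise ValueError(f"invalid conditional probabilities for quintile {q}")
                table[q] = p
        if not self.ga_preterm_weights:
            self.ga_preterm_weights = {w: 1.0 for w in range(22, 37)}
        if not self.ga_term_weights:
            self.ga_term_weights = {37: 0.10, 38: 0.15, 39: 0.25, 40: 0.30, 41: 0.15, 42: 0.04, 43: 0.01}

    @property
    def models(self) -> dict:
        return {
            "smoking": self.model_smoking,
            "mental_health": self.model_mental,
            "physical_health": self.model_physical,
            "obstetric_conditions": self.model_obstetric,
            "preterm": self.model_preterm,
        }


@dataclass
class TrueEstimands:
    """Exact interventional estimands implied by a generating mechanism.

    Risk-difference components are in percentage points; ``or_total`` is the
    confounder-standardised odds ratio quintile 1 vs 5 and ``cde`` the
    conditional odds ratio at all mediators absent.
    """

    taa: float
    idm_direct: float
    idm_indirect_S: float
    idm_indirect_MH: float
    idm_indirect_PH: float
    idm_indirect_O: float
    mediated_dependence: float
    or_total: float
    cde: float

    @property
    def indirect_total(self) -> float:
        return self.idm_indirect_S + self.idm_indirect_MH + self.idm_indirect_PH + self.idm_indirect_O

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# Published per-quintile calibration targets (percent of full column total)

def _targets_from_counts(var: str) -> np.ndarray:
    yes = np.asarray(TABLE1_COUNTS[var]["1"], dtype=float)
    return yes / np.asarray(QUINTILE_TOTALS, dtype=float)


def _overall_target(var: str) -> float:
    yes = float(np.sum(TABLE1_COUNTS[var]["1"]))
    return yes / float(np.sum(QUINTILE_TOTALS))


def _observed_probs(var: str) -> dict:
    """Per-quintile category probabilities among observed values."""
    table = TABLE1_COUNTS[var]
    levels = [lv for lv in table if lv is not None]
    out = {}
    for q_idx, q in enumerate(QUINTILES):
        counts = np.asarray([table[lv][q_idx] for lv in levels], dtype=float)
        out[q] = counts / counts.sum()
    return out


# Plausible non-exposure coefficients (log odds ratios) for the default cohort.
_DEFAULT_CONF = {
    "smoking": dict(age={"<18": 0.9, "18-24": 0.6, "35+": -0.3}, parity={"2+": 0.3},
                    marital={"not_married_sole": 0.5, "not_married_joint_diff_addr": 0.3}),
    "mental_health": dict(age={"<18": 0.3, "18-24": 0.2}, parity={"2+": 0.2},
                          marital={"not_married_sole": 0.4}),
    "physical_health": dict(age={"<18": 0.2, "35+": 0.3}, parity={}, marital={}),
    "obstetric_conditions": dict(age={"35+": 0.4}, parity={"0": 0.3}, marital={}),
    "preterm": dict(age={"<18": 0.3, "35+": 0.25}, parity={"2+": 0.1},
                    marital={"not_married_sole": 0.15}),
}
_DEFAULT_O_MEDIATORS = {"smoking": 0.3, "mental_health": 0.2, "physical_health": 0.5}
_DEFAULT_Y_MEDIATORS = {
    "smoking": math.log(1.5),
    "mental_health": math.log(1.3),
    "physical_health": math.log(1.4),
    "obstetric_conditions": math.log(2.0),
}

# Published per-quintile missingness fractions (smoking / parity / marital).
_MISSING_TARGETS = {
    "smoking": np.asarray(TABLE1_COUNTS["smoking"][None], dtype=float) / QUINTILE_TOTALS,
    "parity": np.asarray(TABLE1_COUNTS["parity_cat"][None], dtype=float) / QUINTILE_TOTALS,
    "marital_status": np.asarray(TABLE1_COUNTS["marital_status"][None], dtype=float) / QUINTILE_TOTALS,
}


def _conf_cells(params: GeneratorParams, q: int):
    """Yield (weight, age, parity, marital) cells of p(C | quintile q)."""
    for ia, age in enumerate(AGE_LEVELS):
        wa = params.age_probs[q][ia]
        for ip, par in enumerate(PARITY_LEVELS):
            wp = params.parity_probs[q][ip]
            for im, mar in enumerate(MARITAL_LEVELS):
                wm = params.marital_probs[q][im]
                w = wa * wp * wm
                if w > 0:
                    yield w, age, par, mar


def _upstream_state_probs(params: GeneratorParams, q: int, age, par, mar, exposures=None):
    """Probabilities of the 8 (S, MH, PH) states given exposure and confounders.

    ``exposures`` optionally overrides the exposure used per mediator model
    (dict mediator -> quintile), for interventional shifts.
    """
    ex = exposures or {}
    p = {
        name: expit(model.lp(ex.get(name, q), age, par, mar))
        for name, model in (
            ("smoking", params.model_smoking),
            ("mental_health", params.model_mental),
            ("physical_health", params.model_physical),
        )
    }
    for s, mh, ph in itertools.product((0, 1), repeat=3):
        pr = (
            (p["smoking"] if s else 1 - p["smoking"])
            * (p["mental_health"] if mh else 1 - p["mental_health"])
            * (p["physical_health"] if ph else 1 - p["physical_health"])
        )
        yield pr, {"smoking": s, "mental_health": mh, "physical_health": ph}


def _solve_offset(weights: np.ndarray, base: np.ndarray, target: float) -> float:
    w = np.asarray(weights, float)
    w = w / w.sum()
    b = np.asarray(base, float)

    def f(o):
        return float(np.sum(w * expit(o + b)) - target)

    return brentq(f, -25.0, 25.0, xtol=1e-12)


def _calibrate_model(
    params: GeneratorParams,
    which: str,
    targets,  # length-5 per-quintile targets, or scalar overall target
    conf: dict,
    mediators: dict | None = None,
    interactions: dict | None = None,
) -> GenLogit:
    """Solve intercept/exposure offsets so marginal prevalences hit targets.

    With per-quintile targets the exposure coefficients are offsets relative
    to quintile 5; with a scalar target the exposure coefficients are all
    zero and only the intercept is solved (a no-gradient model).
    """
    model = GenLogit(
        age=dict(conf.get("age", {})),
        parity=dict(conf.get("parity", {})),
        marital=dict(conf.get("marital", {})),
        mediators=dict(mediators or {}),
        interactions=dict(interactions or {}),
    )

    def cells_for(q):
        ws, bs = [], []
        for w, age, par, mar in _conf_cells(params, q):
            if which in ("smoking", "mental_health", "physical_health"):
                ws.append(w)
                bs.append(model.base_lp(age, par, mar))
            elif which == "obstetric_conditions":
                for pr, med in _upstream_state_probs(params, q, age, par, mar):
                    ws.append(w * pr)
                    bs.append(model.base_lp(age, par, mar, med))
            else:  # preterm
                for pr, med in _upstream_state_probs(params, q, age, par, mar):
                    pO = expit(params.model_obstetric.lp(q, age, par, mar, med))
                    for o in (0, 1):
                        full = dict(med, obstetric_conditions=o)
                        ws.append(w * pr * (pO if o else 1 - pO))
                        bs.append(model.base_lp(age, par, mar, full, q=q))
        return np.asarray(ws), np.asarray(bs)

    if np.isscalar(targets):
        ws_all, bs_all = [], []
        for q in QUINTILES:
            ws, bs = cells_for(q)
            ws_all.append(ws * params.exposure_probs[q - 1])
            bs_all.append(bs)
        model.intercept = _solve_offset(np.concatenate(ws_all), np.concatenate(bs_all), float(targets))
        model.exposure = {}
    else:
        offsets = {}
        for q in QUINTILES:
            ws, bs = cells_for(q)
            offsets[q] = _solve_offset(ws, bs, float(targets[q - 1]))
        model.intercept = offsets[5]
        model.exposure = {q: offsets[q] - offsets[5] for q in (1, 2, 3, 4)}
    return model


def _missingness_model(var: str) -> MissingnessLogit:
    t = _MISSING_TARGETS[var]
    lo = logit(t)
    return MissingnessLogit(intercept=float(lo[4]), exposure={q: float(lo[q - 1] - lo[4]) for q in (1, 2, 3, 4)})


def _base_params(n: int, seed: int) -> GeneratorParams:
    placeholder = GenLogit()
    return GeneratorParams(
        n=n,
        seed=seed,
        exposure_probs=np.asarray(QUINTILE_TOTALS, float) / float(np.sum(QUINTILE_TOTALS)),
        age_probs=_observed_probs("age_cat"),
        parity_probs=_observed_probs("parity_cat"),
        marital_probs=_observed_probs("marital_status"),
        model_smoking=placeholder,
        model_mental=placeholder,
        model_physical=placeholder,
        model_obstetric=placeholder,
        model_preterm=placeholder,
        missingness={v: _missingness_model(v) for v in ("smoking", "parity", "marital_status")},
    )


def default_params(n: int = 200_000, seed: int = 0) -> GeneratorParams:
    """Default generating mechanism: all causal paths active, calibrated to
    the published per-quintile mediator/outcome margins."""
    p = _base_params(n, seed)
    p.model_smoking = _calibrate_model(p, "smoking", _targets_from_counts("smoking"), _DEFAULT_CONF["smoking"])
    p.model_mental = _calibrate_model(p, "mental_health", _targets_from_counts("mental_health"), _DEFAULT_CONF["mental_health"])
    p.model_physical = _calibrate_model(p, "physical_health", _targets_from_counts("physical_health"), _DEFAULT_CONF["physical_health"])
    p.model_obstetric = _calibrate_model(
        p, "obstetric_conditions", _targets_from_counts("obstetric_conditions"),
        _DEFAULT_CONF["obstetric_conditions"], mediators=_DEFAULT_O_MEDIATORS,
    )
    p.model_preterm = _calibrate_model(
        p, "preterm", _targets_from_counts("preterm"), _DEFAULT_CONF["preterm"],
        mediators=_DEFAULT_Y_MEDIATORS,
    )
    return p


def scenario_params(name: str, n: int = 200_000, seed: int = 0) -> GeneratorParams:
    """Named generating scenarios with qualitatively known truth.

    - ``null``: no exposure effect anywhere; every estimand component is 0.
    - ``direct_only``: exposure affects the outcome only, mediator
      coefficients in the outcome model are zero (total effect = CDE).
    - ``smoking_only``: exposure affects smoking only and the outcome depends
      on smoking only: full mediation through smoking (CDE = 1, PM_S = 1).
    - ``obstetric_dependent``: exposure drives the three upstream mediators,
      obstetric conditions depend strongly on them, and the outcome depends
      on obstetric conditions only.
    - ``mixed``: the default fully active mechanism.
    """
    if name == "mixed":
        return default_params(n, seed)
    p = _base_params(n, seed)
    s_t, mh_t, ph_t, o_t, y_t = (
        _targets_from_counts("smoking"),
        _targets_from_counts("mental_health"),
        _targets_from_counts("physical_health"),
        _targets_from_counts("obstetric_conditions"),
        _targets_from_counts("preterm"),
    )
    if name == "null":
        p.model_smoking = _calibrate_model(p, "smoking", _overall_target("smoking"), _DEFAULT_CONF["smoking"])
        p.model_mental = _calibrate_model(p, "mental_health", _overall_target("mental_health"), _DEFAULT_CONF["mental_health"])
        p.model_physical = _calibrate_model(p, "physical_health", _overall_target("physical_health"), _DEFAULT_CONF["physical_health"])
        p.model_obstetric = _calibrate_model(
            p, "obstetric_conditions", _overall_target("obstetric_conditions"),
            _DEFAULT_CONF["obstetric_conditions"], mediators=_DEFAULT_O_MEDIATORS,
        )
        p.model_preterm = _calibrate_model(
            p, "preterm", _overall_target("preterm"), _DEFAULT_CONF["preterm"], mediators=_DEFAULT_Y_MEDIATORS,
        )
    elif name == "direct_only":
        p.model_smoking = _calibrate_model(p, "smoking", _overall_target("smoking"), _DEFAULT_CONF["smoking"])
        p.model_mental = _calibrate_model(p, "mental_health", _overall_target("mental_health"), _DEFAULT_CONF["mental_health"])
        p.model_physical = _calibrate_model(p, "physical_health", _overall_target("physical_health"), _DEFAULT_CONF["physical_health"])
        p.model_obstetric = _calibrate_model(
            p, "obstetric_conditions", _overall_target("obstetric_conditions"),
            _DEFAULT_CONF["obstetric_conditions"], mediators=_DEFAULT_O_MEDIATORS,
        )
        p.model_preterm = _calibrate_model(p, "preterm", y_t, _DEFAULT_CONF["preterm"], mediators={})
    elif name == "smoking_only":
        p.model_smoking = _calibrate_model(p, "smoking", s_t, _DEFAULT_CONF["smoking"])
        p.model_mental = _calibrate_model(p, "mental_health", _overall_target("mental_health"), _DEFAULT_CONF["mental_health"])
        p.model_physical = _calibrate_model(p, "physical_health", _overall_target("physical_health"), _DEFAULT_CONF["physical_health"])
        p.model_obstetric = _calibrate_model(
            p, "obstetric_conditions", _overall_target("obstetric_conditions"),
            _DEFAULT_CONF["obstetric_conditions"], mediators={},
        )
        p.model_preterm = _calibrate_model(
            p, "preterm", _overall_target("preterm"), _DEFAULT_CONF["preterm"],
            mediators={"smoking": math.log(2.2)},
        )
    elif name == "obstetric_dependent":
        p.model_smoking = _calibrate_model(p, "smoking", s_t, _DEFAULT_CONF["smoking"])
        p.model_mental = _calibrate_model(p, "mental_health", mh_t, _DEFAULT_CONF["mental_health"])
        p.model_physical = _calibrate_model(p, "physical_health", ph_t, _DEFAULT_CONF["physical_health"])
        p.model_obstetric = _calibrate_model(
            p, "obstetric_conditions", _overall_target("obstetric_conditions"),
            _DEFAULT_CONF["obstetric_conditions"],
            mediators={"smoking": 0.6, "mental_health": 0.4, "physical_health": 0.8},
        )
        p.model_preterm = _calibrate_model(
            p, "preterm", _overall_target("preterm"), _DEFAULT_CONF["preterm"],
            mediators={"obstetric_conditions": math.log(2.0)},
        )
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    return p


# ---------------------------------------------------------------------------
# Sampling

def _coef_array(mapping: dict, values: np.ndarray) -> np.ndarray:
    if not mapping:
        return np.zeros(len(values))
    lut = {k: v for k, v in mapping.items()}
    return np.asarray([lut.get(v, 0.0) for v in values])


def _lp_vec(model: GenLogit, q, age, par, mar, med: dict | None = None) -> np.ndarray:
    x = (
        model.intercept
        + _coef_array(model.exposure, q)
        + _coef_array(model.age, age)
        + _coef_array(model.parity, par)
        + _coef_array(model.marital, mar)
    )
    if med:
        for name, arr in med.items():
            x = x + model.mediators.get(name, 0.0) * arr
            if model.interactions:
                inter = np.asarray([model.interactions.get((int(qq), name), 0.0) for qq in q])
                x = x + inter * arr
    return x


_AGE_BOUNDS = {"<18": (13, 17), "18-24": (18, 24), "25-34": (25, 34), "35+": (35, 50)}


def generate_cohort(params: GeneratorParams) -> pd.DataFrame:
    """Draw a complete raw cohort (no missingness) from the generating models.

    Sampling order: exposure -> confounders -> upstream mediators
    (independently given exposure and confounders) -> obstetric conditions ->
    preterm -> gestational-age week within the preterm/term stratum ->
    auxiliary raw fields (maternal age within band, parity count within
    category, birthweight by gestation) chosen so every record passes the
    inclusion filters. The same seed reproduces the cohort exactly.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    q = rng.choice(np.asarray(QUINTILES), size=n, p=params.exposure_probs)

    age_cat = np.empty(n, dtype=object)
    par_cat = np.empty(n, dtype=object)
    mar_cat = np.empty(n, dtype=object)
    for quintile in QUINTILES:
        idx = np.flatnonzero(q == quintile)
        age_cat[idx] = rng.choice(np.asarray(AGE_LEVELS, dtype=object), size=len(idx), p=params.age_probs[quintile])
        par_cat[idx] = rng.choice(np.asarray(PARITY_LEVELS, dtype=object), size=len(idx), p=params.parity_probs[quintile])
        mar_cat[idx] = rng.choice(np.asarray(MARITAL_LEVELS, dtype=object), size=len(idx), p=params.marital_probs[quintile])

    probs = {}
    for name, model in (("smoking", params.model_smoking), ("mental_health", params.model_mental),
                        ("physical_health", params.model_physical)):
        probs[name] = expit(_lp_vec(model, q, age_cat, par_cat, mar_cat))
        if ((probs[name] <= 0) | (probs[name] >= 1)).any():
            logger.warning("degenerate probabilities in %s model", name)
    med = {name: (rng.random(n) < probs[name]).astype(int) for name in UPSTREAM}
    p_obs = expit(_lp_vec(params.model_obstetric, q, age_cat, par_cat, mar_cat, med))
    med["obstetric_conditions"] = (rng.random(n) < p_obs).astype(int)
    p_y = expit(_lp_vec(params.model_preterm, q, age_cat, par_cat, mar_cat, med))
    preterm = (rng.random(n) < p_y).astype(int)

    pw = np.asarray(sorted(params.ga_preterm_weights))
    pw_p = np.asarray([params.ga_preterm_weights[w] for w in pw], float)
    pw_p /= pw_p.sum()
    tw = np.asarray(sorted(params.ga_term_weights))
    tw_p = np.asarray([params.ga_term_weights[w] for w in tw], float)
    tw_p /= tw_p.sum()
    ga = np.where(preterm == 1, 0, 0)
    ga = np.empty(n, dtype=int)
    idx_p = np.flatnonzero(preterm == 1)
    idx_t = np.flatnonzero(preterm == 0)
    ga[idx_p] = rng.choice(pw, size=len(idx_p), p=pw_p)
    ga[idx_t] = rng.choice(tw, size=len(idx_t), p=tw_p)

    lo = np.asarray([_AGE_BOUNDS[a][0] for a in age_cat])
    hi = np.asarray([_AGE_BOUNDS[a][1] for a in age_cat])
    mat_age = lo + (rng.random(n) * (hi - lo + 1)).astype(int)

    parity = np.where(par_cat == "0", 0, np.where(par_cat == "1", 1, 2 + np.minimum(rng.poisson(0.8, size=n), 7)))

    bw_mean = np.where(ga < 40, 3400 - 170.0 * (40 - ga), 3400 + 50.0 * (ga - 40))
    bw = np.clip(np.round(bw_mean + 420.0 * rng.standard_normal(n)), 500, 6500).astype(int)

    year = rng.integers(params.year_range[0], params.year_range[1] + 1, size=n)

    df = pd.DataFrame(
        {
            "gestational_age_weeks": ga,
            "birthweight_g": bw,
            "maternal_age_years": mat_age,
            "parity": parity,
            "marital_status": pd.Categorical(mar_cat, categories=MARITAL_LEVELS),
            "wimd_quintile": q.astype(int),
            "smoking": med["smoking"],
            "mental_health": med["mental_health"],
            "physical_health": med["physical_health"],
            "obstetric_conditions": med["obstetric_conditions"],
            "singleton": np.ones(n, dtype=int),
            "live_birth": np.ones(n, dtype=int),
            "year": year,
        }
    )
    for col in ("gestational_age_weeks", "birthweight_g", "maternal_age_years", "parity",
                "wimd_quintile", "smoking", "mental_health", "physical_health",
                "obstetric_conditions", "singleton", "live_birth", "year"):
        df[col] = df[col].astype("Int64")
    return df


def inject_missingness(records: pd.DataFrame, params: GeneratorParams, seed: int | None = None) -> pd.DataFrame:
    """Set smoking/parity/marital values missing under the MAR mechanism.

    Missingness probabilities depend on exposure quintile and year only
    (fully observed variables), so the mechanism is missing-at-random by
    construction. Returns a copy; the caller retains the complete cohort as
    the pre-masking truth.
    """
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    out = records.copy()
    q = records["wimd_quintile"].to_numpy(dtype=int)
    year = records["year"].to_numpy(dtype=int)
    for var, col in (("smoking", "smoking"), ("parity", "parity"), ("marital_status", "marital_status")):
        model = params.missingness.get(var)
        if model is None:
            continue
        p = model.prob(q, year)
        mask = rng.random(len(out)) < p
        if col == "marital_status":
            arr = out[col].astype("object")
            arr[mask] = pd.NA
            out[col] = pd.Categorical(arr, categories=MARITAL_LEVELS)
        else:
            arr = out[col].astype("Int64")
            arr[mask] = pd.NA
            out[col] = arr
    return out


# ---------------------------------------------------------------------------
# Exact estimands

def _population_cells(params: GeneratorParams):
    """Confounder cells of the full-cohort standardisation population."""
    acc: dict[tuple, float] = {}
    for q in QUINTILES:
        pi = params.exposure_probs[q - 1]
        for w, age, par, mar in _conf_cells(params, q):
            key = (age, par, mar)
            acc[key] = acc.get(key, 0.0) + pi * w
    return acc


def true_risk(params: GeneratorParams, target_quintile: int, shift_set=(), donor_quintile: int = 5) -> float:
    """Exact standardised outcome risk under a mediator-distribution shift.

    Mediators in ``shift_set`` are drawn as if exposure were
    ``donor_quintile``; all other mediators, and the outcome model, see
    ``target_quintile``. Confounders follow the full-population distribution.
    """
    shift = set(shift_set)
    exposures = {m: (donor_quintile if m in shift else target_quintile) for m in UPSTREAM}
    xo = donor_quintile if "obstetric_conditions" in shift else target_quintile
    total = 0.0
    wsum = 0.0
    for (age, par, mar), w in _population_cells(params).items():
        for pr, med in _upstream_state_probs(params, target_quintile, age, par, mar, exposures):
            pO = expit(params.model_obstetric.lp(xo, age, par, mar, med))
            for o in (0, 1):
                full = dict(med, obstetric_conditions=o)
                pY = expit(params.model_preterm.lp(target_quintile, age, par, mar, full))
                total += w * pr * (pO if o else 1 - pO) * pY
        wsum += w
    return total / wsum


def true_estimands(params: GeneratorParams) -> TrueEstimands:
    """Exact decomposition (zero Monte-Carlo error) by full enumeration."""
    r15 = true_risk(params, 1, ())
    r55 = true_risk(params, 5, ())
    ind = {m: r15 - true_risk(params, 1, (m,), 5) for m in MEDIATORS}
    direct = true_risk(params, 1, MEDIATORS, 5) - r55
    taa = r15 - r55
    md = taa - direct - sum(ind.values())
    odds = lambda p: p / (1 - p)
    return TrueEstimands(
        taa=100 * taa,
        idm_direct=100 * direct,
        idm_indirect_S=100 * ind["smoking"],
        idm_indirect_MH=100 * ind["mental_health"],
        idm_indirect_PH=100 * ind["physical_health"],
        idm_indirect_O=100 * ind["obstetric_conditions"],
        mediated_dependence=100 * md,
        or_total=odds(r15) / odds(r55),
        cde=math.exp(params.model_preterm.exposure.get(1, 0.0)),
    )
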