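"""End-to-end run: cohort -> filters -> coding -> imputation -> estimates.

``run_pipeline`` executes every stage in order, logs row counts and wall time
at stage boundaries, writes all result tables to the output directory and
returns them in memory. The manifest records the configuration, seeds,
per-stage row counts and any warnings, and suffices to re-run the pipeline
byte-identically.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import cde as cde_mod
from . import cohort as cohort_mod
from . import descriptives as desc_mod
from . import idm as idm_mod
from .impute import ImputationSpec, impute as _impute, write_imputations as _write_imputations
from . import simulate as sim_mod
from . import uncertainty as unc_mod
from .config import RunConfig

logger = logging.getLogger(__name__)


def _pool_rubin_log_or(log_ors: list[float], ses: list[float], m: int) -> tuple[float, float, float]:
    """Rubin's rules on the log-OR scale -> (pooled OR, low, high)."""
    q = float(np.mean(log_ors))
    vw = float(np.mean(np.square(ses)))
    b = float(np.var(log_ors, ddof=1)) if m > 1 else 0.0
    t = vw + (1 + 1 / m) * b
    z = norm.ppf(0.975)
    return float(np.exp(q)), float(np.exp(q - z * np.sqrt(t))), float(np.exp(q + z * np.sqrt(t)))


def _smoking3(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Three-level smoking recode (never / ex / current).

    Routine two-level data cannot distinguish never from ex-smokers; the
    non-current group is split at a fixed ex-smoker fraction so the
    three-level sensitivity model is exercisable on synthetic cohorts.
    """
    out = df.copy()
    cur = out["smoking"].astype(int).to_numpy()
    ex = (rng.random(len(out)) < 0.25) & (cur == 0)
    out["smoking3"] = pd.Categorical(
        np.where(cur == 1, "current", np.where(ex, "ex", "never")),
        categories=["never", "ex", "current"],
    )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write artifacts to ``config.out_dir``."""
    t_start = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": [], "warnings": []}

    def stage(name: str, n_rows: int):
        entry = {"stage": name, "rows": int(n_rows), "elapsed_s": round(time.time() - t_start, 2)}
        manifest["stages"].append(entry)
        logger.info("stage %-12s rows=%d t=%.1fs", name, n_rows, entry["elapsed_s"])

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- cohort ---------------------------------------------------
        if config.generator is not None:
            scenario = config.generator.get("scenario", "mixed")
            n = int(config.generator.get("n", 100_000))
            params = sim_mod.scenario_params(scenario, n=n, seed=config.seed)
            raw = sim_mod.generate_cohort(params)
            raw = sim_mod.inject_missingness(raw, params)
        else:
            raw = cohort_mod.read_cohort(config.input_path, config.missing_token)
        stage("input", len(raw))

        included, exclusion_counts = cohort_mod.apply_inclusion_filters(raw)
        with open(out_dir / "exclusions.json", "w") as fh:
            json.dump(exclusion_counts, fh, indent=1)
        stage("filter", len(included))

        coded = cohort_mod.code_analysis_records(included, preterm_cutoff_weeks=config.preterm_cutoff)
        stage("code", len(coded))

        # --- descriptives (pre-imputation, with Missing rows) ---------
        table1 = desc_mod.tabulate(coded)
        table1.to_csv(out_dir / "descriptive_table.csv")
        stage("describe", len(coded))

        # --- missing data ---------------------------------------------
        if config.complete_case:
            complete, deletion_counts = cohort_mod.listwise_complete(coded)
            manifest["listwise_deletion"] = deletion_counts
            datasets = [complete]
        else:
            spec = ImputationSpec(
                m=int(config.imputation.get("m", 10)),
                iterations=int(config.imputation.get("iterations", 10)),
                seed=config.seed + 1,
            )
            datasets = _impute(coded, spec)
        if config.smoking_levels == 3:
            rng3 = np.random.default_rng(config.seed + 7)
            datasets = [_smoking3(d, rng3) for d in datasets]
        stage("impute" if not config.complete_case else "complete_case", len(datasets[0]))

        # --- CDE / proportion eliminated ------------------------------
        m = len(datasets)
        fits = []
        for d in datasets:
            m1 = cde_mod.fit_total_effect(d, include_marital=config.include_marital, include_year=config.include_year)
            m2 = cde_mod.fit_cde_model(
                d,
                include_marital=config.include_marital,
                include_year=config.include_year,
                smoking_levels=config.smoking_levels,
            )
            fits.append((m1, m2))
        rows = []
        pooled = {}
        for label, idx in (("or_total", 0), ("cde", 1)):
            for q in (1, 2, 3, 4):
                logs = [f[idx].exposure_coef(q) for f in fits]
                ses = [f[idx].exposure_se(q) if not f[idx].penalized else np.nan for f in fits]
                orv, lo, hi = _pool_rubin_log_or(logs, ses, m)
                pooled[(label, q)] = (orv, lo, hi)
                rows.append({"estimate": label, "quintile": q, "odds_ratio": orv, "ci_low": lo, "ci_high": hi})
        cde_table = pd.DataFrame(rows)
        cde_table.to_csv(out_dir / "cde_odds_ratios.csv", index=False)
        pe = cde_mod.proportion_eliminated(pooled[("or_total", 1)][0], pooled[("cde", 1)][0])
        fits[0][0].tidy().to_csv(out_dir / "model1_coefficients.csv", index=False)
        fits[0][1].tidy().to_csv(out_dir / "model2_coefficients.csv", index=False)
        stage("cde", len(datasets[0]))

        # --- serial GA-category contrasts (first completed dataset) ---
        ga_rows = []
        contrasts = cde_mod.fit_ga_category_contrasts(
            datasets[0], include_marital=config.include_marital, include_year=config.include_year
        )
        for cat, (g1, g2) in contrasts.items():
            if g1 is None:
                continue
            ga_rows.append(
                {"ga_category": cat, "or_total_q1": g1.odds_ratio(1), "cde_q1": g2.odds_ratio(1)}
            )
        pd.DataFrame(ga_rows).to_csv(out_dir / "ga_category_contrasts.csv", index=False)
        stage("ga_contrasts", len(ga_rows))

        # --- IDM decomposition ----------------------------------------
        decomps = []
        for i, d in enumerate(datasets):
            models = idm_mod.fit_idm_models(d, include_marital=config.include_marital, include_year=config.include_year)
            decomps.append(
                idm_mod.decompose(
                    models,
                    d,
                    k_expansions=config.k_expansions,
                    seed=config.seed + 100 + i,
                    method="mc" if config.k_expansions else "enumerate",
                )
            )
        idm_pooled = idm_mod.pool_decompositions(decomps)
        idm_pooled.to_frame().to_csv(out_dir / "idm_decomposition.csv", index=False)
        stage("idm", len(datasets[0]))

        # --- proportions table ----------------------------------------
        proportions = pd.DataFrame(
            [
                {"measure": "proportion_eliminated", "percent": 100 * pe},
                {"measure": "proportion_mediated_smoking", "percent": 100 * idm_pooled.pm_S},
                {"measure": "proportion_mediated_mental_health", "percent": 100 * idm_pooled.pm_MH},
                {"measure": "proportion_mediated_physical_health", "percent": 100 * idm_pooled.pm_PH},
                {"measure": "proportion_mediated_obstetric_conditions", "percent": 100 * idm_pooled.pm_O},
            ]
        )
        proportions.to_csv(out_dir / "proportions.csv", index=False)

        # --- resampling intervals (optional; sized by config) ---------
        intervals = {}
        b = int(config.bootstrap.get("b_per_imputation", 0))
        if b > 0:
            def pe_stat(d):
                m1 = cde_mod.fit_total_effect(d, include_marital=config.include_marital, include_year=config.include_year)
                m2 = cde_mod.fit_cde_model(d, include_marital=config.include_marital, include_year=config.include_year,
                                           smoking_levels=config.smoking_levels)
                return cde_mod.proportion_eliminated(m1.odds_ratio(1), m2.odds_ratio(1))

            est = unc_mod.bootstrap_mi_ci(pe_stat, datasets, b_per_imputation=b, seed=config.seed + 200)
            intervals["proportion_eliminated"] = est.__dict__
        n_sub = int(config.subsampling.get("n_subsamples", 0))
        if n_sub > 0:
            def pm_s_stat(d):
                models = idm_mod.fit_idm_models(d, include_marital=config.include_marital, include_year=config.include_year)
                return idm_mod.decompose(models, d, k_expansions=0, method="enumerate").pm_S

            est = unc_mod.subsampling_ci(
                pm_s_stat, datasets, n_subsamples=n_sub,
                exponent=float(config.subsampling.get("exponent", 0.7)), seed=config.seed + 300,
            )
            intervals["proportion_mediated_smoking"] = est.__dict__
        with open(out_dir / "intervals.json", "w") as fh:
            json.dump(intervals, fh, indent=1, default=float)
        stage("intervals", len(intervals))

        # --- E-values --------------------------------------------------
        ev_total = unc_mod.evalue(pooled[("or_total", 1)][0], pooled[("or_total", 1)][1])
        ev_cde = unc_mod.evalue(pooled[("cde", 1)][0], pooled[("cde", 1)][1])
        evalues = {"total_effect": ev_total.__dict__, "cde": ev_cde.__dict__}
        with open(out_dir / "evalues.json", "w") as fh:
            json.dump(evalues, fh, indent=1, default=float)
        stage("evalues", 2)

        manifest["warnings"] = sorted({str(w.message) for w in caught})

    results = {
        "exclusion_counts": exclusion_counts,
        "descriptive_table": table1,
        "cde_table": cde_table,
        "proportion_eliminated": pe,
        "pooled_or": {f"{k[0]}_q{k[1]}": v for k, v in pooled.items()},
        "idm": idm_pooled,
        "intervals": intervals,
        "evalues": evalues,
        "manifest": manifest,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return results
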