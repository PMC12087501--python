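"""Multiple imputation by chained equations for the three incomplete variables.

Smoking (binary), parity category (three levels) and marital status (four
levels) are imputed by fully conditional specification: binary variables with
a logistic model, multi-category variables with a multinomial logistic model.
Predictors are the exposure quintile, the fully observed mediators and
confounders, the binary outcome, the calendar year, and the current values of
the other imputed variables. Draws are proper: for each conditional model the
coefficient vector is drawn from its asymptotic normal distribution before
category probabilities are computed and categories sampled, so
between-imputation variance reflects parameter uncertainty.

Visit order is by descending missingness (smoking, parity, marital status by
default); initial values are random draws from each variable's observed
marginal distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import MARITAL_LEVELS, PARITY_LEVELS

DEFAULT_VARIABLES = ("smoking", "parity_cat", "marital_status")
DEFAULT_PREDICTORS = (
    "exposure",
    "age_cat",
    "mental_health",
    "physical_health",
    "obstetric_conditions",
    "preterm",
    "year",
)

_LEVELS = {"parity_cat": PARITY_LEVELS, "marital_status": MARITAL_LEVELS}


@dataclass
class ImputationSpec:
    """Configuration of the chained-equations run."""

    m: int = 10
    iterations: int = 10
    variables: tuple = DEFAULT_VARIABLES
    predictors: tuple = DEFAULT_PREDICTORS
    seed: int = 0

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if not self.predictors:
            raise ValueError("every imputed variable needs at least one predictor")
        for v in self.variables:
            if v in self.predictors:
                raise ValueError(f"{v!r} cannot predict itself")


def _design(df: pd.DataFrame, columns: list[str]) -> np.ndarray:
    """Dummy-coded design matrix with intercept; year centred at 2010."""
    parts = [np.ones((len(df), 1))]
    for col in columns:
        s = df[col]
        if col == "year":
            parts.append(((s.astype(float) - 2010.0) / 10.0).to_numpy()[:, None])
        elif isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object or col == "exposure":
            d = pd.get_dummies(s.astype("category"), drop_first=True, dtype=float)
            parts.append(d.to_numpy())
        else:
            parts.append(s.astype(float).to_numpy()[:, None])
    return np.column_stack(parts)


def _draw_params(point: np.ndarray, cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cov = np.asarray(cov, float)
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        chol = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    return point + chol @ rng.standard_normal(len(point))


def _impute_binary(X_obs, y_obs, X_mis, rng) -> np.ndarray:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y_obs, X_obs).fit(disp=0, maxiter=100)
        if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 50):
            raise np.linalg.LinAlgError("unstable standard errors")
        beta = _draw_params(np.asarray(res.params), res.cov_params(), rng)
    except Exception:
        warnings.warn("perfect separation in binary imputation model; penalised fit without parameter draw")
        res = sm.GLM(y_obs, X_obs, family=sm.families.Binomial()).fit_regularized(alpha=1e-4, L1_wt=0.0)
        beta = np.asarray(res.params)
    p = 1.0 / (1.0 + np.exp(-(X_mis @ beta)))
    return (rng.random(len(X_mis)) < p).astype(int)


def _impute_multinomial(X_obs, y_codes, X_mis, n_levels, rng) -> np.ndarray:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(y_codes, X_obs).fit(method="lbfgs", maxiter=200, disp=0)
        params = np.asarray(res.params)  # (p, n_levels-1)
        cov = np.asarray(res.cov_params())
        flat = _draw_params(params.ravel(order="F"), cov, rng)
        params = flat.reshape(params.shape, order="F")
    except Exception:
        warnings.warn("unstable multinomial imputation model; point-estimate fit without parameter draw")
        res = sm.MNLogit(y_codes, X_obs).fit_regularized(method="l1", alpha=1e-4, disp=0)
        params = np.asarray(res.params)
    eta = np.column_stack([np.zeros(len(X_mis))] + [X_mis @ params[:, j] for j in range(params.shape[1])])
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(len(X_mis))[:, None]
    return (p.cumsum(axis=1) < u).sum(axis=1)


def impute(records: pd.DataFrame, spec: ImputationSpec) -> list[pd.DataFrame]:
    """Run chained equations; return ``spec.m`` completed copies of ``records``.

    Observed values are never changed. With no missingness the result is
    ``m`` identical copies. A variable that is entirely missing raises, since
    no conditional model can be fitted for it.
    """
    masks = {v: records[v].isna().to_numpy() for v in spec.variables}
    for v, mask in masks.items():
        if mask.all():
            raise ValueError(f"variable {v!r} is 100% missing; cannot impute")
    if not any(m.any() for m in masks.values()):
        return [records.copy() for _ in range(spec.m)]

    # Visit order: descending missingness.
    order = sorted(spec.variables, key=lambda v: -masks[v].sum())
    root = np.random.SeedSequence(spec.seed)
    completed = []
    for child in root.spawn(spec.m):
        rng = np.random.default_rng(child)
        df = records.copy()
        # Initialise missing cells from observed marginals.
        for v in order:
            mask = masks[v]
            if not mask.any():
                continue
            observed = records.loc[~mask, v]
            draws = observed.sample(n=int(mask.sum()), replace=True, random_state=int(rng.integers(2**31)))
            if v in _LEVELS:
                vals = df[v].astype("object")
                vals[mask] = draws.to_numpy()
                df[v] = pd.Categorical(vals, categories=_LEVELS[v])
            else:
                vals = df[v].copy()
                vals[mask] = draws.to_numpy()
                df[v] = vals

        for _ in range(spec.iterations):
            for v in order:
                mask = masks[v]
                if not mask.any():
                    continue
                predictors = [p for p in spec.predictors if p != v] + [o for o in order if o != v]
                X = _design(df, predictors)
                X_obs, X_mis = X[~mask], X[mask]
                if v in _LEVELS:
                    levels = list(_LEVELS[v])
                    y_codes = df.loc[~mask, v].cat.codes.to_numpy()
                    new_codes = _impute_multinomial(X_obs, y_codes, X_mis, len(levels), rng)
                    vals = df[v].astype("object")
                    vals[mask] = [levels[c] for c in new_codes]
                    df[v] = pd.Categorical(vals, categories=levels)
                else:
                    y_obs = df.loc[~mask, v].astype(int).to_numpy()
                    new_vals = _impute_binary(X_obs, y_obs, X_mis, rng)
                    vals = df[v].copy()
                    vals[mask] = new_vals
                    df[v] = vals
        df["smoking"] = df["smoking"].astype(int) if "smoking" in spec.variables else df["smoking"]
        completed.append(df)
    return completed


def write_imputations(datasets: list[pd.DataFrame], out_dir, spec: ImputationSpec, missing_token: str = "") -> dict:
    """Write completed datasets as ``cohort_imp01.csv`` ... plus a manifest."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for i, df in enumerate(datasets, start=1):
        name = f"cohort_imp{i:02d}.csv"
        df.to_csv(out / name, index=False, na_rep=missing_token)
        files.append(name)
    manifest = {
        "m": spec.m,
        "iterations": spec.iterations,
        "variables": list(spec.variables),
        "predictors": list(spec.predictors),
        "seed": spec.seed,
        "files": files,
    }
    with open(out / "imputation_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def pool_log_odds_ratios(ors: list[float]) -> float:
    """Rubin point pooling for odds ratios: arithmetic mean on the log scale."""
    return float(np.exp(np.mean(np.log(np.asarray(ors, float)))))
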