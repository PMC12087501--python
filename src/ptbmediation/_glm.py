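"""Shared logistic-regression fitting with a penalised fallback.

All outcome/mediator models in the pipeline are binomial GLMs specified via
patsy formulas. Fits that fail to converge or show (quasi-)separation
(non-finite or absurd standard errors) are refitted with a small ridge
penalty; a warning is emitted and the ``penalized`` flag set, in which case
standard errors are unavailable but predictions and point estimates remain
usable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

EXPOSURE_TERM = "C(exposure, Treatment(5))"
CONFOUNDER_TERMS = (
    "C(age_cat, Treatment('25-34'))",
    "C(parity_cat, Treatment('0'))",
    "C(marital_status, Treatment('married_cp'))",
)

#: Log-likelihood convergence tolerance and iteration cap for IRLS.
FIT_TOL = 1e-8
FIT_MAXITER = 100


@dataclass
class FittedLogit:
    """A fitted logistic model: formula, coefficients, covariance and size."""

    formula: str
    result: object  # statsmodels results (GLM or regularized)
    n: int
    penalized: bool = False

    @property
    def params(self) -> pd.Series:
        return self.result.params

    def cov_params(self):
        if self.penalized:
            raise ValueError("covariance unavailable for penalised fit")
        return self.result.cov_params()

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.result.predict(data))

    def exposure_coef(self, quintile: int) -> float:
        if quintile == 5:
            return 0.0
        return float(self.params[f"{EXPOSURE_TERM}[T.{quintile}]"])

    def exposure_se(self, quintile: int) -> float:
        if quintile == 5:
            return 0.0
        return float(self.result.bse[f"{EXPOSURE_TERM}[T.{quintile}]"])

    def odds_ratio(self, quintile: int) -> float:
        """Exposure OR for ``quintile`` vs quintile 5 (reference)."""
        return float(np.exp(self.exposure_coef(quintile)))

    def odds_ratio_ci(self, quintile: int, alpha: float = 0.05) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        b, se = self.exposure_coef(quintile), self.exposure_se(quintile)
        return float(np.exp(b - z * se)), float(np.exp(b + z * se))

    def tidy(self) -> pd.DataFrame:
        """Coefficient table on the OR scale (Wald CIs where available)."""
        params = self.params
        out = pd.DataFrame({"term": params.index, "coef": params.to_numpy()})
        out["odds_ratio"] = np.exp(out["coef"])
        if not self.penalized:
            bse = self.result.bse
            out["se"] = bse.reindex(params.index).to_numpy()
            out["or_low"] = np.exp(out["coef"] - 1.959963984540054 * out["se"])
            out["or_high"] = np.exp(out["coef"] + 1.959963984540054 * out["se"])
        return out


def _aggregate_for_fit(formula: str, data: pd.DataFrame):
    """Collapse to unique covariate/outcome patterns with frequency weights.

    Every variable in the pipeline is categorical or a small integer, so the
    design has at most a few thousand distinct rows; fitting on the collapsed
    data with frequency weights maximises the identical likelihood at a
    fraction of the cost. Returns (frame, weights) or None when a referenced
    column is not discrete enough to collapse profitably.
    """
    used = [c for c in data.columns if c in formula]
    if not used:
        return None
    grouped = data.groupby(used, observed=True, dropna=False).size().reset_index(name="_freq")
    if len(grouped) > max(5000, len(data) // 4):
        return None
    return grouped, grouped.pop("_freq").to_numpy(float)


def fit_logit(formula: str, data: pd.DataFrame, ridge_alpha: float = 1e-5) -> FittedLogit:
    """Fit a binomial GLM by IRLS, falling back to ridge on separation.

    Raises ``ValueError`` with diagnostics if even the penalised fit fails.
    """
    n_records = len(data)
    agg = _aggregate_for_fit(formula, data)
    if agg is not None:
        data, freq = agg
        model = smf.glm(formula, data=data, family=sm.families.Binomial(), freq_weights=freq)
    else:
        model = smf.glm(formula, data=data, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=FIT_MAXITER, tol=FIT_TOL)
        bad = (not np.all(np.isfinite(res.params))) or (not np.all(np.isfinite(res.bse))) or np.any(res.bse > 50)
        if not bad:
            return FittedLogit(formula=formula, result=res, n=n_records)
        reason = "quasi-separation (unstable standard errors)"
    except Exception as exc:  # non-convergence, singular design
        reason = f"fit failure: {exc}"
    warnings.warn(f"logistic fit for {formula.split('~')[0].strip()!r} fell back to penalised fit: {reason}")
    try:
        res = model.fit_regularized(alpha=ridge_alpha, L1_wt=0.0, maxiter=FIT_MAXITER)
    except Exception as exc:
        raise ValueError(f"logistic regression failed even with ridge penalty: {exc}") from exc
    return FittedLogit(formula=formula, result=res, n=n_records, penalized=True)
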