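"""Standard (non-spatial) probit by maximum likelihood.

Fits P(y=1|x) = Φ(x'β) with Wald inference from the inverse observed
information, marginal effects evaluated at covariate means, and the
percent-correctly-predicted fit diagnostic.  Estimation is delegated to
statsmodels' Newton optimizer on the exact analytic score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .dataset import SurveyTable
from .reference import MODEL_COVARIATES


class SeparationError(RuntimeError):
    """Raised when the likelihood has no finite maximizer."""


@dataclass
class ProbitFit:
    """Maximum-likelihood probit estimates and diagnostics."""

    params: pd.Series
    vcov: pd.DataFrame
    loglik: float
    p_values: pd.Series
    fitted_prob: np.ndarray
    pct_correct: float
    model_label: str
    n: int

    @property
    def beta(self) -> np.ndarray:
        return self.params.to_numpy()

    def summary(self) -> pd.DataFrame:
        se = pd.Series(np.sqrt(np.diag(self.vcov)), index=self.params.index)
        return pd.DataFrame(
            {"coefficient": self.params, "std_err": se, "p_value": self.p_values}
        )


def fit_probit_xy(
    X: np.ndarray, y: np.ndarray, names: list[str], label: str = "probit"
) -> ProbitFit:
    """Fit a probit on an explicit design matrix (first column intercept)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    try:
        res = sm.Probit(y, X).fit(disp=0, method="newton", maxiter=200, tol=1e-10)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"probit fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError("probit did not converge")
    if np.abs(res.params).max() > 1e3:
        raise SeparationError("divergent coefficients suggest perfect separation")
    params = pd.Series(res.params, index=names)
    vcov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    probs = norm.cdf(X @ res.params)
    return ProbitFit(
        params=params,
        vcov=vcov,
        loglik=float(res.llf),
        p_values=pd.Series(res.pvalues, index=names),
        fitted_prob=probs,
        pct_correct=percent_correct(probs, y),
        model_label=label,
        n=len(y),
    )


def fit_probit(
    table: SurveyTable,
    covariates: tuple[str, ...] | list[str] | None = None,
    label: str = "probit",
) -> ProbitFit:
    """Fit a probit of willingness-to-harvest on a covariate specification."""
    X, names = table.design_matrix(covariates)
    return fit_probit_xy(X, table.wth, names, label=label)


def marginal_effects_at_means(
    fit: ProbitFit,
    table: SurveyTable,
    covariates: tuple[str, ...] | list[str] | None = None,
    discrete: bool = False,
) -> pd.Series:
    """Marginal effects on P(y=1) evaluated at covariate means.

    Default is the pdf-scaled derivative φ(x̄'β̂)·β̂_r for every
    covariate.  With ``discrete=True``, 0/1 covariates instead use the
    discrete change Φ(·|x_r=1) − Φ(·|x_r=0) at the means of the others.
    """
    covariates = list(covariates if covariates is not None else MODEL_COVARIATES)
    xbar = np.concatenate([[1.0], table.df[covariates].mean().to_numpy()])
    beta = fit.params.reindex(["intercept"] + covariates).to_numpy()
    eta = float(xbar @ beta)
    effects = norm.pdf(eta) * beta[1:]
    out = pd.Series(effects, index=covariates)
    if discrete:
        from .dataset import DUMMY_COVARIATES

        for r, name in enumerate(covariates, start=1):
            if name in DUMMY_COVARIATES:
                x1, x0 = xbar.copy(), xbar.copy()
                x1[r], x0[r] = 1.0, 0.0
                out[name] = norm.cdf(x1 @ beta) - norm.cdf(x0 @ beta)
    return out


def percent_correct(probs: np.ndarray, y: np.ndarray, threshold: float = 0.5) -> float:
    """Percent of outcomes matched by thresholded predicted probabilities.

    Classified willing iff prob strictly exceeds the threshold (ties
    classify as unwilling).
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    if probs.shape != y.shape:
        raise ValueError("probs and y must have equal length")
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities outside [0, 1]")
    yhat = (probs > threshold).astype(np.int64)
    return 100.0 * float(np.mean(yhat == y))
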