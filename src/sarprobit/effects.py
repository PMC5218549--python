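"""Average direct, indirect, and total marginal effects.

For the spatial probit the matrix of partial effects of covariate r is

    S_r = D · (I − ρW)⁻¹ · β_r,   D = diag(φ(η)),  η = (I − ρW)⁻¹ X β,

the probit analogue of the standard spatial-econometric impact
decomposition.  The average direct effect is n⁻¹·tr(S_r) (own-
observation impacts), the average total effect is the grand mean of S_r
rows, and the indirect (spillover) effect is their difference — so
additivity direct + indirect = total holds by construction.  At ρ = 0
the matrix is diagonal and the decomposition collapses to the ordinary
pdf-scaled probit marginal effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataset import SurveyTable
from .probit import ProbitFit, marginal_effects_at_means
from .reference import MODEL_COVARIATES
from .sar import SarPosterior, thin_posterior
from .spatial_weights import WeightMatrix


@dataclass
class EffectsTable:
    """Per-covariate average direct/indirect/total impacts."""

    table: pd.DataFrame  # columns: direct, indirect, total
    rho: float
    mode: str
    model_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        resid = (
            self.table["direct"] + self.table["indirect"] - self.table["total"]
        ).abs()
        if len(resid) and resid.max() > 1e-12:
            raise ValueError("direct + indirect must equal total")


def effects_matrix(
    beta_r: float,
    beta: np.ndarray,
    rho: float,
    w: WeightMatrix,
    X: np.ndarray,
) -> np.ndarray:
    """The n×n impact matrix S_r of covariate r (dense).

    Entry (i, j) is the effect of a unit change of x_r at observation j
    on P(y_i = 1), evaluated at the reduced-form mean.
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    n = w.n
    A = np.eye(n) - rho * np.asarray(w.w.todense())
    Ainv = np.linalg.inv(A)
    eta = Ainv @ (np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float))
    return norm.pdf(eta)[:, None] * Ainv * beta_r


def _spatial_averages(
    beta: np.ndarray,
    rho: float,
    w: WeightMatrix,
    X: np.ndarray,
    normalize_variance: bool = False,
) -> tuple[float, float]:
    """Per-unit-coefficient (direct, total) averages shared by all covariates.

    direct_r = β_r · n⁻¹ Σ_i φ(η_i)·A⁻¹_ii and
    total_r = β_r · n⁻¹ Σ_i φ(η_i)·(A⁻¹·1)_i, computed without forming
    each S_r.  With ``normalize_variance`` the probit index is scaled by
    the reduced-form standard deviations σ_i = √[(A⁻¹A⁻ᵀ)_ii], i.e.
    φ(η_i/σ_i)/σ_i replaces φ(η_i).
    """
    n = w.n
    A = np.eye(n) - rho * np.asarray(w.w.todense())
    Ainv = np.linalg.inv(A)
    eta = Ainv @ (X @ beta)
    if normalize_variance:
        sigma = np.sqrt(np.einsum("ij,ij->i", Ainv, Ainv))
        d = norm.pdf(eta / sigma) / sigma
    else:
        d = norm.pdf(eta)
    direct_unit = float(np.mean(d * np.diag(Ainv)))
    total_unit = float(np.mean(d * (Ainv @ np.ones(n))))
    return direct_unit, total_unit


def average_effects(
    fit: SarPosterior | ProbitFit,
    w: WeightMatrix | None = None,
    table: SurveyTable | None = None,
    covariates: tuple[str, ...] | list[str] | None = None,
    mode: str = "posterior_mean",
    max_draws: int = 100,
    normalize_variance: bool = False,
) -> EffectsTable:
    """Average direct/indirect/total impacts for a fitted model.

    For a :class:`ProbitFit` the ordinary marginal effect at covariate
    means is reported with zero indirect component.  For a
    :class:`SarPosterior` the spatial decomposition is evaluated either
    at the posterior means (``mode="posterior_mean"``, default) or
    averaged over evenly thinned retained draws (``mode="draws"``).
    """
    covariates = list(covariates if covariates is not None else MODEL_COVARIATES)

    if isinstance(fit, ProbitFit):
        if table is None:
            raise ValueError("a SurveyTable is required for probit effects")
        me = marginal_effects_at_means(fit, table, covariates)
        df = pd.DataFrame(
            {"direct": me, "indirect": 0.0, "total": me}, index=covariates
        )
        return EffectsTable(df, rho=0.0, mode="at_means", model_label=fit.model_label)

    if w is None:
        raise ValueError("a WeightMatrix is required for spatial effects")
    if table is not None:
        X, names = table.design_matrix(covariates)
    else:
        X, names = fit.meta.get("X"), fit.meta.get("names")
        if X is None:
            raise ValueError("a SurveyTable (or cached design) is required")
    cov_idx = [names.index(c) for c in covariates]

    if mode == "posterior_mean":
        beta = fit.beta_mean.to_numpy()
        rho = fit.rho_mean
        direct_unit, total_unit = _spatial_averages(
            beta, rho, w, X, normalize_variance
        )
        direct = beta[cov_idx] * direct_unit
        total = beta[cov_idx] * total_unit
    elif mode == "draws":
        thinned = thin_posterior(fit, max_draws)
        direct = np.zeros(len(cov_idx))
        total = np.zeros(len(cov_idx))
        m = len(thinned.rho_draws)
        for b_draw, r_draw in zip(thinned.beta_draws, thinned.rho_draws):
            du, tu = _spatial_averages(b_draw, float(r_draw), w, X,
                                       normalize_variance)
            direct += b_draw[cov_idx] * du / m
            total += b_draw[cov_idx] * tu / m
        rho = fit.rho_mean
    else:
        raise ValueError(f"unknown mode {mode!r}")

    df = pd.DataFrame(
        {"direct": direct, "indirect": total - direct, "total": total},
        index=covariates,
    )
    return EffectsTable(df, rho=float(rho), mode=mode, model_label=fit.model_label)


def indirect_share(
    effects: EffectsTable | pd.DataFrame,
    covariates: tuple[str, ...] | list[str] | None = None,
) -> float:
    """Mean |indirect|/|total| over selected covariates, in percent."""
    df = effects.table if isinstance(effects, EffectsTable) else effects
    if covariates is not None:
        missing = [c for c in covariates if c not in df.index]
        if missing:
            raise KeyError(f"covariates not in effects table: {missing}")
        df = df.loc[list(covariates)]
    if (df["total"] == 0).any():
        raise ValueError("zero total effect in selected covariates")
    return float(100.0 * (df["indirect"].abs() / df["total"].abs()).mean())
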