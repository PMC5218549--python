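"""Bayesian spatial autoregressive (SAR) probit estimation by MCMC.

Model: y*_i = ρ·(W y*)_i + x_i'β + ε_i with ε ~ N(0, I_n) and observed
outcome y_i = 1(y*_i > 0).  The error variance is fixed at one — the
usual probit identification, since the binary outcome carries no scale
information.  Priors: β ~ N(m, T) (default N(0, I)) and ρ uniform on a
sub-interval of (0, 1).

Sampling cycles three blocks:

* y* — single-site Gibbs sweeps from univariate truncated-normal
  conditionals of the joint N((I−ρW)⁻¹Xβ, [(I−ρW)'(I−ρW)]⁻¹);
* β — the conjugate normal conditional of the regression
  (I−ρW)y* = Xβ + ε;
* ρ — griddy Gibbs: the conditional log-kernel
  log|I−ρW| − ½‖(I−ρW)y* − Xβ‖² is evaluated on a fixed grid (exact
  log-determinants from the eigenvalues of W, computed once) and ρ is
  drawn by inverse-CDF with linear interpolation within grid cells.

The sampler is deterministic given its seed; all randomness flows from
one numpy Generator (per-sweep kernel seeds are derived from it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm

from ._gibbs import latent_sweep
from .dataset import SurveyTable
from .probit import fit_probit_xy
from .reference import MODEL_COVARIATES
from .spatial_weights import WeightMatrix


@dataclass
class SarPrior:
    """Prior for the SAR probit: β ~ N(mean, var·I), ρ ~ U(support)."""

    beta_mean: float | np.ndarray = 0.0
    beta_var: float | np.ndarray = 1.0
    rho_support: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.rho_support
        # Endpoints are open: the rho grid strictly excludes them, so a
        # support of (0, 1) is valid even though |I - W| is singular.
        if not (-1.0 < lo <= hi <= 1.0):
            raise ValueError("rho support must lie within (-1, 1]")
        if np.any(np.asarray(self.beta_var) <= 0):
            raise ValueError("beta_var must be positive")


@dataclass
class McmcConfig:
    """MCMC settings: 20,000 draws with a 5,000-draw burn-in by default."""

    n_draws: int = 20000
    burn_in: int = 5000
    rho_grid_step: float = 0.001
    seed: int = 0
    n_chains: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_draws:
            raise ValueError("burn_in must be smaller than n_draws")
        if not 0 < self.rho_grid_step <= 0.01:
            raise ValueError("rho_grid_step must lie in (0, 0.01]")


@dataclass
class SarPosterior:
    """Retained MCMC draws and posterior summaries."""

    beta_draws: np.ndarray  # (retained, k)
    rho_draws: np.ndarray  # (retained,)
    param_names: list[str]
    latent_mean: np.ndarray
    config: McmcConfig
    prior: SarPrior
    model_label: str = "sar_probit"
    meta: dict = field(default_factory=dict)

    @property
    def beta_mean(self) -> pd.Series:
        return pd.Series(self.beta_draws.mean(axis=0), index=self.param_names)

    @property
    def rho_mean(self) -> float:
        return float(self.rho_draws.mean())

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD, two-sided p-value, and P(>0) per parameter."""
        draws = np.column_stack([self.beta_draws, self.rho_draws])
        names = self.param_names + ["rho"]
        means = draws.mean(axis=0)
        sds = draws.std(axis=0, ddof=1)
        pvals = [bayesian_pvalue(draws[:, j]) for j in range(draws.shape[1])]
        return pd.DataFrame(
            {
                "mean": means,
                "sd": sds,
                "p_value": pvals,
                "prob_positive": (draws > 0).mean(axis=0),
            },
            index=names,
        )


def logdet_grid(w: WeightMatrix | sp.spmatrix, grid: np.ndarray) -> np.ndarray:
    """log|I − ρW| on a ρ grid via the eigenvalues of W (computed once).

    For row-standardized W the spectral radius is one, so the values are
    finite and non-positive on [0, 1).
    """
    W = w.w if isinstance(w, WeightMatrix) else w
    lam = np.linalg.eigvals(np.asarray(W.todense()))
    grid = np.asarray(grid, dtype=float)
    vals = np.log(np.abs(1.0 - grid[:, None] * lam[None, :])).sum(axis=1)
    if not np.isfinite(vals).all():
        raise ValueError("singular I - rho*W on the grid")
    return vals


def _precision_parts(W: sp.csr_matrix):
    """Precompute CSR structure for H(ρ) = I − ρ(W+W') + ρ²W'W.

    Returns (indptr, indices, vI, v1, v2, diag_pos) where the three value
    arrays are aligned on the union sparsity pattern, so H's values for
    any ρ are a pure vector expression.
    """
    n = W.shape[0]
    I = sp.identity(n, format="csr")
    S1 = (W + W.T).tocsr()
    S2 = (W.T @ W).tocsr()
    P = (I + S1 + S2).tocsr()
    P.sort_indices()

    def align(M: sp.csr_matrix) -> np.ndarray:
        M = M.tocsr()
        M.sort_indices()
        out = np.zeros(P.nnz)
        for i in range(n):
            p0, p1 = P.indptr[i], P.indptr[i + 1]
            m0, m1 = M.indptr[i], M.indptr[i + 1]
            pos = p0 + np.searchsorted(P.indices[p0:p1], M.indices[m0:m1])
            out[pos] = M.data[m0:m1]
        return out

    diag_pos = np.empty(n, dtype=np.int64)
    for i in range(n):
        p0, p1 = P.indptr[i], P.indptr[i + 1]
        diag_pos[i] = p0 + np.searchsorted(P.indices[p0:p1], i)
    return P.indptr, P.indices, align(I), align(S1), align(S2), diag_pos


def draw_latent(
    y: np.ndarray,
    beta: np.ndarray,
    rho: float,
    w: WeightMatrix,
    ystar: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Gibbs sweep of the latent utilities; returns the updated copy."""
    W = w.w
    indptr, indices, vI, v1, v2, diag_pos = _precision_parts(W)
    data = vI - rho * v1 + rho * rho * v2
    diag = data[diag_pos]
    xb = np.zeros(len(y)) if beta is None else np.asarray(beta, dtype=float)
    b = xb - rho * (W.T @ xb)
    out = np.array(ystar, dtype=float, copy=True)
    latent_sweep(
        indptr, indices, data, diag, b,
        np.asarray(y, dtype=np.int64), out, int(rng.integers(2**31)),
    )
    return out


def draw_beta(
    ystar: np.ndarray,
    rho: float,
    w: WeightMatrix,
    X: np.ndarray,
    prior: SarPrior,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate normal draw of β given (y*, ρ) with σ_ε² = 1."""
    k = X.shape[1]
    Tinv = np.diag(np.broadcast_to(1.0 / np.asarray(prior.beta_var, dtype=float), (k,)))
    m = np.broadcast_to(np.asarray(prior.beta_mean, dtype=float), (k,))
    Bbar = np.linalg.inv(X.T @ X + Tinv)
    z = ystar - rho * (w.w @ ystar)
    bbar = Bbar @ (X.T @ z + Tinv @ m)
    L = np.linalg.cholesky(Bbar)
    return bbar + L @ rng.standard_normal(k)


def _rho_inverse_cdf(grid: np.ndarray, logker: np.ndarray, u: float) -> float:
    """Inverse-CDF sample on a grid, linear interpolation within cells."""
    p = np.exp(logker - logker.max())
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(grid))])
    total = cdf[-1]
    if total <= 0 or not np.isfinite(total):
        raise ValueError("degenerate rho conditional on the grid")
    target = u * total
    k = int(np.searchsorted(cdf, target, side="right"))
    k = min(max(k, 1), len(grid) - 1)
    seg = cdf[k] - cdf[k - 1]
    frac = 0.5 if seg <= 0 else (target - cdf[k - 1]) / seg
    return float(grid[k - 1] + frac * (grid[k] - grid[k - 1]))


def draw_rho(
    ystar: np.ndarray,
    beta: np.ndarray,
    w: WeightMatrix,
    X: np.ndarray,
    prior: SarPrior,
    logdets: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator,
) -> float:
    """Griddy-Gibbs draw of ρ from its conditional on the grid.

    ``logdets`` is the (grid, log|I−ρW|) pair from :func:`logdet_grid`.
    """
    grid, ld = logdets
    e = ystar - X @ beta
    wy = w.w @ ystar
    a0 = float(e @ e)
    b0 = float(e @ wy)
    c0 = float(wy @ wy)
    logker = ld - 0.5 * (a0 - 2.0 * grid * b0 + grid**2 * c0)
    return _rho_inverse_cdf(grid, logker, float(rng.random()))


def bayesian_pvalue(draws: np.ndarray) -> float:
    """Two-sided normal tail at |posterior mean| / posterior SD."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 100:
        raise ValueError("at least 100 retained draws required")
    sd = draws.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance draws")
    return float(2.0 * norm.sf(abs(draws.mean()) / sd))


def run_sampler(
    table: SurveyTable | None,
    w: WeightMatrix,
    covariates: tuple[str, ...] | list[str] | None = None,
    prior: SarPrior | None = None,
    cfg: McmcConfig | None = None,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    names: list[str] | None = None,
    label: str = "sar_probit",
) -> SarPosterior:
    """Run the full MCMC cycle y* → β → ρ and return retained draws.

    Either pass a :class:`SurveyTable` (with a covariate specification)
    or an explicit design matrix ``X``/outcome ``y``.
    """
    prior = prior or SarPrior()
    cfg = cfg or McmcConfig()
    if table is not None:
        X, names = table.design_matrix(
            covariates if covariates is not None else MODEL_COVARIATES
        )
        y = table.wth
    if X is None or y is None:
        raise ValueError("either table or (X, y) must be supplied")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    n, k = X.shape
    if w.n != n:
        raise ValueError(f"W is {w.n}x{w.n} but the sample has {n} rows")
    names = names or [f"x{j}" for j in range(k)]

    rng = np.random.default_rng(cfg.seed)
    lo, hi = prior.rho_support
    fixed_rho = lo == hi
    if not fixed_rho:
        grid = np.arange(lo + cfg.rho_grid_step, hi, cfg.rho_grid_step)
        logdets = (grid, logdet_grid(w, grid))

    # Initialization: probit MLE for β (zeros on failure), support
    # midpoint for ρ, outcome-signed ±0.5 for the latent vector.
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta = fit_probit_xy(X, y, names).beta
    except Exception:
        beta = np.zeros(k)
    rho = lo if fixed_rho else 0.5 * (lo + hi)
    ystar = np.where(y == 1, 0.5, -0.5).astype(float)

    W = w.w
    indptr, indices, vI, v1, v2, diag_pos = _precision_parts(W)
    Tinv = np.diag(np.broadcast_to(1.0 / np.asarray(prior.beta_var, dtype=float), (k,)))
    pm = np.broadcast_to(np.asarray(prior.beta_mean, dtype=float), (k,))
    Bbar = np.linalg.inv(X.T @ X + Tinv)
    Lb = np.linalg.cholesky(Bbar)
    Tm = Tinv @ pm

    retained = cfg.n_draws - cfg.burn_in
    beta_draws = np.empty((retained, k))
    rho_draws = np.empty(retained)
    latent_sum = np.zeros(n)

    for it in range(cfg.n_draws):
        # --- latent utilities ---
        data = vI - rho * v1 + rho * rho * v2
        diag = data[diag_pos]
        xb = X @ beta
        b = xb - rho * (W.T @ xb)
        latent_sweep(indptr, indices, data, diag, b, y, ystar,
                     int(rng.integers(2**31)))
        if not np.isfinite(ystar).all() or np.abs(ystar).max() > 1e8:
            raise RuntimeError("latent vector diverged")

        # --- beta ---
        z = ystar - rho * (W @ ystar)
        bbar = Bbar @ (X.T @ z + Tm)
        beta = bbar + Lb @ rng.standard_normal(k)

        # --- rho ---
        if not fixed_rho:
            e = ystar - X @ beta
            wy = W @ ystar
            logker = logdets[1] - 0.5 * (
                float(e @ e)
                - 2.0 * logdets[0] * float(e @ wy)
                + logdets[0] ** 2 * float(wy @ wy)
            )
            rho = _rho_inverse_cdf(logdets[0], logker, float(rng.random()))

        if it >= cfg.burn_in:
            j = it - cfg.burn_in
            beta_draws[j] = beta
            rho_draws[j] = rho
            latent_sum += ystar

    return SarPosterior(
        beta_draws=beta_draws,
        rho_draws=rho_draws,
        param_names=list(names),
        latent_mean=latent_sum / retained,
        config=cfg,
        prior=prior,
        model_label=label,
        meta={"n": n, "fixed_rho": fixed_rho, "X": X, "names": list(names)},
    )


def mc_standard_error(draws: np.ndarray) -> float:
    """Monte-Carlo SE of a posterior mean, ESS-adjusted for autocorrelation."""
    import arviz as az

    draws = np.asarray(draws, dtype=float)
    ess = float(az.ess(az.convert_to_dataset(draws[None, :]))["x"])
    ess = max(ess, 1.0)
    return float(draws.std(ddof=1) / np.sqrt(ess))


def convergence_check(
    runs: list[SarPosterior], rel_tol: float = 0.05, mcse_factor: float = 0.5
) -> pd.DataFrame:
    """Compare posterior means/variances across repeated runs.

    A parameter passes when the spread of posterior means across runs is
    within ``rel_tol`` relative to the parameter's scale (the larger of
    the mean magnitude and the posterior SD, so near-zero coefficients
    are judged on the posterior scale) or within ``mcse_factor``
    combined Monte-Carlo standard errors; posterior variances must agree
    within twice ``rel_tol`` (variance estimates are noisier).
    """
    if len(runs) < 2:
        raise ValueError("at least two runs required")
    names0 = runs[0].param_names
    if any(r.param_names != names0 for r in runs[1:]):
        raise ValueError("runs have mismatched model specifications")
    names = names0 + ["rho"]
    rows = []
    stacked = [np.column_stack([r.beta_draws, r.rho_draws]) for r in runs]
    for j, name in enumerate(names):
        means = np.array([d[:, j].mean() for d in stacked])
        variances = np.array([d[:, j].var(ddof=1) for d in stacked])
        mcses = np.array([mc_standard_error(d[:, j]) for d in stacked])
        dmean = means.max() - means.min()
        scale = max(np.abs(means).max(), float(np.sqrt(variances.max())), 1e-12)
        mcse_comb = float(np.sqrt(np.sum(mcses**2)))
        mean_ok = (dmean / scale <= rel_tol) or (dmean <= mcse_factor * mcse_comb)
        vscale = max(variances.max(), 1e-12)
        var_ok = (variances.max() - variances.min()) / vscale <= 2 * rel_tol
        rows.append(
            {
                "parameter": name,
                "mean_range": dmean,
                "mean_rel_diff": dmean / scale,
                "var_rel_diff": (variances.max() - variances.min()) / vscale,
                "mcse_combined": mcse_comb,
                "mean_ok": mean_ok,
                "var_ok": var_ok,
                "pass": bool(mean_ok and var_ok),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def thin_posterior(post: SarPosterior, max_draws: int = 200) -> SarPosterior:
    """Evenly thin retained draws (for expensive per-draw computations)."""
    m = len(post.rho_draws)
    if m <= max_draws:
        return post
    idx = np.linspace(0, m - 1, max_draws).astype(int)
    return replace(post, beta_draws=post.beta_draws[idx], rho_draws=post.rho_draws[idx])
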