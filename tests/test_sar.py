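"""Bayesian SAR probit sampler: conditionals, griddy Gibbs, diagnostics."""

import numpy as np
import pytest
import scipy.sparse as sp

from sarprobit import (
    McmcConfig,
    SarPrior,
    SimConfig,
    bayesian_pvalue,
    convergence_check,
    draw_beta,
    draw_latent,
    draw_rho,
    logdet_grid,
    run_sampler,
    simulate_dataset,
)
from sarprobit.sar import _rho_inverse_cdf
from sarprobit.spatial_weights import WeightMatrix


def _pair_w():
    """The 2-point graph: W = [[0,1],[1,0]]."""
    w = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
    return WeightMatrix(
        n=2,
        neighbors=[np.array([1]), np.array([0])],
        w=w,
        coords=np.array([[0.0, 0.0], [1.0, 0.0]]),
    )


class TestLogdetGrid:
    def test_zero_rho_gives_zero(self, small_sim):
        assert logdet_grid(small_sim.w, np.array([0.0]))[0] == pytest.approx(0.0)

    def test_two_point_closed_form(self):
        """log|I − ρW| = log(1 − ρ²) for the 2-point graph."""
        vals = logdet_grid(_pair_w(), np.array([0.5]))
        assert vals[0] == pytest.approx(np.log(0.75), abs=1e-12)
        assert vals[0] == pytest.approx(-0.2877, abs=1e-4)

    def test_monotone_decreasing_and_nonpositive(self, small_sim):
        grid = np.linspace(0.01, 0.99, 99)
        vals = logdet_grid(small_sim.w, grid)
        assert np.all(np.diff(vals) < 0)
        assert np.all(vals <= 0)
        assert np.all(np.isfinite(vals))


class TestDrawLatent:
    def test_sign_constraints_respected(self, small_sim, rng):
        n = small_sim.w.n
        y = small_sim.table.wth
        ystar = np.zeros(n)
        for _ in range(5):
            ystar = draw_latent(y, np.zeros(n), 0.3, small_sim.w, ystar, rng)
        assert np.all(ystar[y == 1] > 0)
        assert np.all(ystar[y == 0] <= 0)

    def test_truncated_mean_closed_form(self, small_sim, rng):
        """ρ=0, Xβ=0, y=1: long-run mean is E[N(0,1)|>0] = 0.7979."""
        n = small_sim.w.n
        y = np.ones(n, dtype=np.int64)
        ystar = np.full(n, 0.5)
        means = []
        for _ in range(400):
            ystar = draw_latent(y, np.zeros(n), 0.0, small_sim.w, ystar, rng)
            means.append(ystar.mean())
        assert np.mean(means) == pytest.approx(np.sqrt(2 / np.pi), abs=0.02)

    def test_rho_zero_is_independent_truncated_normal(self, small_sim, rng):
        """At ρ=0 the conditionals are N(x'β, 1) truncated by outcome."""
        from scipy.stats import truncnorm

        n = small_sim.w.n
        xb = np.full(n, 0.7)
        y = np.zeros(n, dtype=np.int64)
        ystar = np.full(n, -0.5)
        draws = []
        for _ in range(400):
            ystar = draw_latent(y, xb, 0.0, small_sim.w, ystar, rng)
            draws.append(ystar.mean())
        expected = truncnorm.mean(-np.inf, -0.7, loc=0.7, scale=1.0)
        assert np.mean(draws) == pytest.approx(expected, abs=0.03)


class TestDrawBeta:
    def test_dominant_prior_concentrates_at_prior_mean(self, small_sim, rng):
        X, _ = small_sim.table.design_matrix()
        prior = SarPrior(beta_mean=2.0, beta_var=1e-12)
        draws = np.array(
            [draw_beta(small_sim.y_star, 0.2, small_sim.w, X, prior, rng)
             for _ in range(50)]
        )
        np.testing.assert_allclose(draws.mean(axis=0), 2.0, atol=1e-2)

    def test_draw_dimension(self, small_sim, rng):
        X, names = small_sim.table.design_matrix()
        d = draw_beta(small_sim.y_star, 0.1, small_sim.w, X, SarPrior(), rng)
        assert d.shape == (len(names),)

    def test_rho_zero_diffuse_prior_matches_least_squares(self, rng):
        """Mean of conjugate draws ≈ OLS of y* on X (closed-form oracle)."""
        sim = simulate_dataset(SimConfig(n=500, rho_true=0.0, seed=21))
        X, _ = sim.table.design_matrix()
        ols = np.linalg.lstsq(X, sim.y_star, rcond=None)[0]
        prior = SarPrior(beta_var=1e6)
        m = 400
        draws = np.array(
            [draw_beta(sim.y_star, 0.0, sim.w, X, prior, rng) for _ in range(m)]
        )
        mcse = draws.std(axis=0, ddof=1) / np.sqrt(m)
        assert np.all(np.abs(draws.mean(axis=0) - ols) <= 3 * mcse + 1e-8)


class TestDrawRho:
    def test_constant_kernel_is_uniform(self, small_sim, rng):
        """With a flat kernel the griddy draw is U(lo, hi)."""
        X, _ = small_sim.table.design_matrix()
        beta = np.zeros(X.shape[1])
        ystar = np.zeros(small_sim.w.n)  # (I−ρW)y* − Xβ = 0 for all ρ
        grid = np.arange(0.001, 1.0, 0.001)
        logdets = (grid, np.zeros_like(grid))
        draws = [
            draw_rho(ystar, beta, small_sim.w, X, SarPrior(), logdets, rng)
            for _ in range(10_000)
        ]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.01)

    def test_inverse_cdf_reproducible(self):
        grid = np.linspace(0.01, 0.99, 99)
        logker = -0.5 * (grid - 0.4) ** 2 / 0.01
        assert _rho_inverse_cdf(grid, logker, 0.37) == _rho_inverse_cdf(
            grid, logker, 0.37
        )

    def test_peaked_kernel_concentrates(self):
        grid = np.linspace(0.001, 0.999, 999)
        logker = -0.5 * (grid - 0.4) ** 2 / 1e-6
        u = np.linspace(0.01, 0.99, 50)
        draws = [_rho_inverse_cdf(grid, logker, ui) for ui in u]
        assert np.allclose(draws, 0.4, atol=0.01)


class TestRunSampler:
    def test_reproducible_given_seed(self, small_sim):
        cfg = McmcConfig(n_draws=300, burn_in=100, seed=9)
        p1 = run_sampler(small_sim.table, small_sim.w, cfg=cfg)
        p2 = run_sampler(small_sim.table, small_sim.w, cfg=cfg)
        np.testing.assert_array_equal(p1.beta_draws, p2.beta_draws)
        np.testing.assert_array_equal(p1.rho_draws, p2.rho_draws)

    def test_retained_count_and_support(self, small_posterior):
        cfg = small_posterior.config
        assert len(small_posterior.rho_draws) == cfg.n_draws - cfg.burn_in
        lo, hi = small_posterior.prior.rho_support
        assert np.all(small_posterior.rho_draws > lo)
        assert np.all(small_posterior.rho_draws < hi)

    def test_dimension_mismatch_rejected(self, small_sim, study_sim):
        with pytest.raises(ValueError, match="rows"):
            run_sampler(small_sim.table, study_sim.w,
                        cfg=McmcConfig(n_draws=20, burn_in=5))

    def test_rho_recovery_synthetic(self):
        """Posterior mean of ρ within 3 posterior SDs of the truth."""
        sim = simulate_dataset(SimConfig(n=300, rho_true=0.4, seed=17))
        post = run_sampler(
            sim.table, sim.w, cfg=McmcConfig(n_draws=2000, burn_in=500, seed=2)
        )
        sd = post.rho_draws.std(ddof=1)
        assert abs(post.rho_mean - 0.4) <= 3 * sd

    def test_doubling_draws_leaves_posterior_stable(self, small_sim):
        """Posterior means from m and 2m draws agree within MC error."""
        from sarprobit.sar import mc_standard_error

        base = McmcConfig(n_draws=2000, burn_in=500, seed=6)
        double = McmcConfig(n_draws=4000, burn_in=500, seed=60)
        p1 = run_sampler(small_sim.table, small_sim.w, cfg=base)
        p2 = run_sampler(small_sim.table, small_sim.w, cfg=double)
        d1 = np.column_stack([p1.beta_draws, p1.rho_draws])
        d2 = np.column_stack([p2.beta_draws, p2.rho_draws])
        for j in range(d1.shape[1]):
            mcse = np.hypot(mc_standard_error(d1[:, j]), mc_standard_error(d2[:, j]))
            assert abs(d1[:, j].mean() - d2[:, j].mean()) <= 3 * mcse

    def test_repeated_long_runs_pass_convergence_default(self, small_sim):
        """Independent full-length runs satisfy the default tolerance.

        A well-mixing specification is used (no collinear quadratic
        term, which mixes slowly on a 60-point fixture).
        """
        covs = ["sawlog", "past_harvest", "age55", "income_ge_50k", "market_access"]
        p1 = run_sampler(small_sim.table, small_sim.w, covariates=covs,
                         cfg=McmcConfig(n_draws=20_000, burn_in=5_000, seed=6))
        p2 = run_sampler(small_sim.table, small_sim.w, covariates=covs,
                         cfg=McmcConfig(n_draws=40_000, burn_in=5_000, seed=60))
        report = convergence_check([p1, p2])
        assert report["mean_ok"].all()


class TestDiagnostics:
    def test_pvalue_symmetric_draws_near_one(self, rng):
        p = bayesian_pvalue(rng.standard_normal(5000))
        assert p > 0.5

    def test_pvalue_far_from_zero_mean(self, rng):
        p = bayesian_pvalue(5.0 + 0.1 * rng.standard_normal(5000))
        assert p < 1e-10

    def test_pvalue_requires_draws_and_variance(self):
        with pytest.raises(ValueError):
            bayesian_pvalue(np.ones(10))
        with pytest.raises(ValueError):
            bayesian_pvalue(np.ones(500))

    def test_convergence_identical_runs_pass_with_zero_diff(self, small_sim):
        cfg = McmcConfig(n_draws=300, burn_in=100, seed=9)
        p1 = run_sampler(small_sim.table, small_sim.w, cfg=cfg)
        p2 = run_sampler(small_sim.table, small_sim.w, cfg=cfg)
        report = convergence_check([p1, p2])
        assert report["pass"].all()
        assert (report["mean_range"] == 0).all()

    def test_convergence_flags_short_run(self, small_sim):
        short = run_sampler(
            small_sim.table, small_sim.w,
            cfg=McmcConfig(n_draws=200, burn_in=50, seed=1),
        )
        long = run_sampler(
            small_sim.table, small_sim.w,
            cfg=McmcConfig(n_draws=4000, burn_in=1000, seed=2),
        )
        report = convergence_check([short, long])
        assert not report["pass"].all()

    def test_convergence_mismatched_specs_rejected(self, small_sim, small_posterior):
        other = run_sampler(
            small_sim.table, small_sim.w, covariates=["sawlog", "past_harvest"],
            cfg=McmcConfig(n_draws=200, burn_in=50, seed=1),
        )
        with pytest.raises(ValueError, match="mismatch"):
            convergence_check([small_posterior, other])
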