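"""Direct/indirect/total impact decomposition for the spatial probit."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sarprobit import (
    SimConfig,
    average_effects,
    effects_matrix,
    fit_probit,
    indirect_share,
    simulate_dataset,
)
from sarprobit.effects import EffectsTable, _spatial_averages
from sarprobit.reference import (
    PUBLISHED_EFFECTS_SPATIAL_ALL,
    SIGNIFICANT_COVARIATES,
)
from sarprobit.spatial_weights import WeightMatrix, build_weights
from tests.oracles import fd_effects_matrix


def _triangle_w():
    pts = np.array([[0.0, 0.0], [10.0, 0.0], [4.0, 8.0]])
    return build_weights(pts, already_planar=True)


class TestEffectsMatrix:
    def test_rho_zero_x_zero_is_scaled_identity(self):
        w = _triangle_w()
        X = np.zeros((3, 2))
        S = effects_matrix(0.7, np.zeros(2), 0.0, w, X)
        np.testing.assert_allclose(S, norm.pdf(0.0) * 0.7 * np.eye(3), atol=1e-14)

    def test_zero_coefficient_zero_matrix(self):
        w = _triangle_w()
        X = np.ones((3, 2))
        S = effects_matrix(0.0, np.array([0.3, -0.2]), 0.5, w, X)
        np.testing.assert_allclose(S, 0.0, atol=1e-16)

    def test_matches_finite_difference_oracle(self):
        """Analytic S_r equals numeric ∂Φ(reduced form)/∂x_jr element-wise."""
        w = _triangle_w()
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(3), rng.normal(size=3), rng.normal(size=3)])
        beta = np.array([0.2, 0.8, -0.5])
        S = effects_matrix(beta[1], beta, 0.5, w, X)
        S_fd = fd_effects_matrix(1, beta, 0.5, w.w.toarray(), X)
        np.testing.assert_allclose(S, S_fd, atol=1e-5)

    def test_rho_out_of_range_rejected(self):
        w = _triangle_w()
        with pytest.raises(ValueError):
            effects_matrix(0.5, np.zeros(1), 1.0, w, np.zeros((3, 1)))


class TestAverageEffects:
    def test_additivity_machine_precision(self, small_sim, small_posterior):
        et = average_effects(small_posterior, w=small_sim.w, table=small_sim.table)
        resid = (et.table["direct"] + et.table["indirect"] - et.table["total"]).abs()
        assert resid.max() <= 1e-12

    def test_probit_effects_have_zero_indirect(self, study_sim):
        fit = fit_probit(study_sim.table)
        et = average_effects(fit, table=study_sim.table)
        assert (et.table["indirect"] == 0).all()
        pd.testing.assert_series_equal(
            et.table["direct"], et.table["total"], check_names=False
        )

    def test_average_matches_effects_matrix(self, small_sim, small_posterior):
        """Averages agree with explicit trace / grand mean of S_r."""
        et = average_effects(small_posterior, w=small_sim.w, table=small_sim.table)
        X, names = small_sim.table.design_matrix()
        beta = small_posterior.beta_mean.to_numpy()
        r = names.index("sawlog")
        S = effects_matrix(beta[r], beta, small_posterior.rho_mean, small_sim.w, X)
        n = small_sim.w.n
        assert et.table.loc["sawlog", "direct"] == pytest.approx(
            np.trace(S) / n, rel=1e-10
        )
        assert et.table.loc["sawlog", "total"] == pytest.approx(
            S.sum() / n, rel=1e-10
        )

    def test_limit_rho_to_zero_matches_average_pdf_effect(self, small_sim):
        """At ρ→0⁺ the spatial decomposition equals mean φ(x'β)·β_r."""
        X, _ = small_sim.table.design_matrix()
        rng = np.random.default_rng(0)
        beta = rng.normal(scale=0.3, size=X.shape[1])
        du, tu = _spatial_averages(beta, 1e-8, small_sim.w, X)
        expected = norm.pdf(X @ beta).mean()
        assert du == pytest.approx(expected, rel=1e-6)
        assert tu == pytest.approx(expected, rel=1e-6)

    def test_draws_mode_additive_and_close_to_point_mode(
        self, small_sim, small_posterior
    ):
        et_d = average_effects(
            small_posterior, w=small_sim.w, table=small_sim.table, mode="draws",
            max_draws=40,
        )
        et_p = average_effects(small_posterior, w=small_sim.w, table=small_sim.table)
        resid = (et_d.table["direct"] + et_d.table["indirect"] - et_d.table["total"]).abs()
        assert resid.max() <= 1e-12
        # the two evaluation modes agree to the first decimal on this fixture
        assert np.allclose(et_d.table["total"], et_p.table["total"], atol=0.1)

    def test_monotone_spillover_share_in_rho(self, small_sim):
        """|indirect|/|total| increases with ρ for fixed β on one W."""
        X, _ = small_sim.table.design_matrix()
        beta = np.zeros(X.shape[1])
        beta[0] = -0.5
        shares = []
        for rho in (0.1, 0.3, 0.5, 0.7):
            du, tu = _spatial_averages(beta, rho, small_sim.w, X)
            shares.append(1.0 - du / tu)
        assert np.all(np.diff(shares) > 0)

    def test_normalize_variance_option_changes_averages(self, small_sim):
        X, names = small_sim.table.design_matrix()
        beta = np.zeros(X.shape[1])
        beta[0] = -0.4
        beta[names.index("sawlog")] = 0.8
        beta[names.index("past_harvest")] = 0.5
        du, tu = _spatial_averages(beta, 0.4, small_sim.w, X)
        dun, tun = _spatial_averages(beta, 0.4, small_sim.w, X, normalize_variance=True)
        assert dun != pytest.approx(du, rel=1e-6)
        assert tun != pytest.approx(tu, rel=1e-6)
        # at rho=0 the reduced-form variance is 1 and the option is a no-op
        du0, tu0 = _spatial_averages(beta, 0.0, small_sim.w, X)
        dun0, tun0 = _spatial_averages(beta, 0.0, small_sim.w, X,
                                       normalize_variance=True)
        assert dun0 == pytest.approx(du0, rel=1e-12)


class TestIndirectShare:
    def _published(self):
        df = pd.DataFrame(
            PUBLISHED_EFFECTS_SPATIAL_ALL, index=["direct", "indirect", "total"]
        ).T
        return df

    def test_single_covariate_ratio(self):
        df = self._published().loc[["past_harvest"]]
        assert indirect_share(df) == pytest.approx(100 * 0.030 / 0.216, abs=1e-9)
        assert round(indirect_share(df), 1) == 13.9

    def test_significant_covariates_round_to_14(self):
        share = indirect_share(self._published(), SIGNIFICANT_COVARIATES)
        assert round(share) == 14

    def test_zero_rho_table_gives_zero_share(self, study_sim):
        fit = fit_probit(study_sim.table)
        et = average_effects(fit, table=study_sim.table)
        assert indirect_share(et, ["sawlog"]) == 0.0

    def test_zero_total_rejected(self):
        df = pd.DataFrame({"direct": [0.0], "indirect": [0.0], "total": [0.0]},
                          index=["x"])
        with pytest.raises(ValueError):
            indirect_share(df)

    def test_unknown_covariate_rejected(self):
        with pytest.raises(KeyError):
            indirect_share(self._published(), ["not_a_covariate"])


class TestEffectsTable:
    def test_additivity_enforced_at_construction(self):
        df = pd.DataFrame(
            {"direct": [0.1], "indirect": [0.05], "total": [0.2]}, index=["x"]
        )
        with pytest.raises(ValueError):
            EffectsTable(df, rho=0.1, mode="posterior_mean")
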