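"""Heritability/correlation summaries, delta-method SEs, GLS and the LRT."""

import numpy as np
import pytest

from mvgreml import (
    InputError,
    MgremlModel,
    delta_method_ses,
    gls_fixed_effects,
    heritability_and_correlations,
    likelihood_ratio_test,
)
from mvgreml.factors import (
    ParameterVector,
    VarianceStructure,
    implied_variance_matrices,
    parameter_index,
    saturated_spec,
)
from mvgreml.inference import LrtResult

from conftest import random_theta, small_dataset


class TestHeritabilityAndCorrelations:
    def test_equal_components_give_half(self):
        vs = VarianceStructure.from_loadings(np.eye(2) * 0.7, np.eye(2) * 0.7)
        h2, _, _ = heritability_and_correlations(vs)
        np.testing.assert_allclose(h2, 0.5)

    def test_diagonal_genetic_variance_gives_identity_correlation(self):
        vs = VarianceStructure.from_loadings(np.diag([0.5, 0.8]), np.eye(2))
        _, rho_g, _ = heritability_and_correlations(vs)
        np.testing.assert_allclose(rho_g, np.eye(2))

    def test_hand_computed_correlation(self):
        # V_G = [[1, .5], [.5, 4]] -> rho = 0.5 / sqrt(4) = 0.25
        c = np.linalg.cholesky(np.array([[1.0, 0.5], [0.5, 4.0]]))
        vs = VarianceStructure.from_loadings(c, np.eye(2))
        _, rho_g, _ = heritability_and_correlations(vs)
        assert rho_g[0, 1] == pytest.approx(0.25)

    def test_zero_genetic_variance_reported_as_nan_not_zero(self):
        vs = VarianceStructure.from_loadings(
            np.array([[0.7, 0.0], [0.0, 0.0]]), np.eye(2)
        )
        _, rho_g, _ = heritability_and_correlations(vs)
        assert np.isnan(rho_g[0, 1]) and np.isnan(rho_g[1, 1])
        assert rho_g[0, 0] == 1.0

    def test_zero_total_variance_rejected(self):
        vs = VarianceStructure.from_loadings(np.zeros((1, 1)), np.zeros((1, 1)))
        with pytest.raises(InputError):
            heritability_and_correlations(vs)

    def test_correlation_matrices_always_valid_psd_fuzz(self):
        # Gram parameterization guarantee: every implied rho_G is a valid
        # correlation matrix (PSD, unit diagonal) wherever it is defined
        rng = np.random.default_rng(11)
        for _ in range(1000):
            t = int(rng.integers(2, 6))
            f = int(rng.integers(1, t + 1))
            c_g = rng.standard_normal((t, f)) * rng.uniform(0.1, 2.0)
            c_g *= rng.integers(0, 2, size=(t, f))  # random sparsity pattern
            vs = VarianceStructure.from_loadings(c_g, np.eye(t))
            _, rho_g, _ = heritability_and_correlations(vs)
            defined = ~np.isnan(np.diag(rho_g))
            sub = rho_g[np.ix_(defined, defined)]
            if sub.size == 0:
                continue
            np.testing.assert_allclose(np.diag(sub), 1.0, atol=1e-10)
            assert np.abs(sub).max() <= 1.0 + 1e-10
            assert np.linalg.eigvalsh((sub + sub.T) / 2).min() >= -1e-10


class TestDeltaMethodSes:
    def test_identity_summary_matches_cov_diagonal(self):
        # SE of a raw loading must equal sqrt of its theta_cov entry; verified
        # through h2 of a single-trait model with frozen environment scale:
        # h2 = g^2/(g^2+e^2), J known in closed form
        spec = saturated_spec(["y0"])
        index = parameter_index(spec, spec)
        theta = ParameterVector(np.array([0.8, 0.6]), index)
        cov = np.diag([0.01, 0.02])
        rep = delta_method_ses(theta, cov, spec, spec)
        g, e = 0.8, 0.6
        tot = g * g + e * e
        jac = np.array([2 * g * e * e / tot**2, -2 * e * g * g / tot**2])
        expected = np.sqrt(jac @ cov @ jac)
        assert rep.h2_se[0] == pytest.approx(expected, rel=1e-10)

    def test_analytic_jacobian_cross_check_mode(self):
        rng = np.random.default_rng(12)
        spec = saturated_spec(["a", "b", "c"])
        theta = random_theta(spec, spec, rng)
        cov = np.eye(len(theta)) * 0.01
        # raises internally if analytic and finite-difference Jacobians differ
        delta_method_ses(theta, cov, spec, spec, check_finite_differences=True)

    def test_reported_se_tracks_replicate_scatter(self):
        # calibration: mean reported SE(h2) versus the SD of estimates across
        # simulated replicates of the same design
        from mvgreml import make_simulation_design, simulate_dataset

        design = make_simulation_design(1, N=500, M=500, T=2, rho=0.5, seed=3)
        h2_hat, se_hat = [], []
        for rep in range(12):
            ds = simulate_dataset(design, rep)
            res = MgremlModel(ds.grm, ds.phen, drop_leading_pcs=0).fit()
            h2_hat.append(res.h2)
            se_hat.append(res.h2_se)
        sd_emp = np.array(h2_hat).std(axis=0, ddof=1).mean()
        se_mean = np.array(se_hat).mean()
        assert 0.6 < se_mean / sd_emp < 1.6  # wide band: 12 replicates only

    def test_nonfinite_free_trait_gets_nan_se(self):
        # trait a has no genetic variance -> rho entries/SEs around it are NaN
        from mvgreml.factors import FactorModelSpec

        spec_g = FactorModelSpec(["a", "b"], ["f0", "f1"],
                                 np.array([[0, 0], [1, 1]]))
        spec_e = saturated_spec(["a", "b"])
        index = parameter_index(spec_g, spec_e)
        theta = ParameterVector(np.array([0.5, 0.3, 1.0, 0.2, 0.9]), index)
        rep = delta_method_ses(theta, np.eye(5) * 0.01, spec_g, spec_e)
        assert np.isnan(rep.rhoG[0, 1]) and np.isnan(rep.rhoG_se[0, 1])


class TestGlsFixedEffects:
    def test_identity_covariance_reduces_to_ols(self):
        # V_G=0, V_E=I: GLS on the transformed data equals per-trait OLS
        ds = small_dataset(n=60, m=120, t=2)
        model = MgremlModel(ds.grm, ds.phen, drop_leading_pcs=0)
        vs = VarianceStructure.from_loadings(np.zeros((2, 1)), np.eye(2))
        fe = gls_fixed_effects(model.transformed, vs)
        # OLS per trait in the original coordinates (rotation is orthogonal)
        y = model.phenotypes.Y
        x = np.ones((y.shape[0], 1))
        beta_ols = np.linalg.lstsq(x, y, rcond=None)[0].ravel()
        np.testing.assert_allclose(fe.beta, beta_ols, atol=1e-8)

    def test_recovers_simulated_intercept(self):
        ds = small_dataset(n=400, m=400, t=2, rho=0.3)
        phen = type(ds.phen)(
            ids=ds.phen.ids,
            trait_labels=ds.phen.trait_labels,
            Y=ds.phen.Y + np.array([5.0, 0.0]),
        )
        res = MgremlModel(ds.grm, phen, drop_leading_pcs=0).fit(se=False)
        fe = gls_fixed_effects(res.model.transformed, res.variance_structure)
        i = fe.labels.index(("trait_0", "intercept"))
        assert abs(fe.beta[i] - 5.0) < 3 * fe.beta_se[i] + 0.05

    def test_matches_dense_oracle_gls(self):
        ds = small_dataset(n=25, m=60, t=2)
        model = MgremlModel(ds.grm, ds.phen, drop_leading_pcs=0)
        rng = np.random.default_rng(13)
        theta = random_theta(model.spec_g, model.spec_e, rng)
        vs = implied_variance_matrices(theta, model.spec_g, model.spec_e)
        fe = gls_fixed_effects(model.transformed, vs)
        # dense GLS in the original coordinates
        import scipy.linalg

        n = model.grm.n
        v = np.kron(vs.V_G, model.grm.A) + np.kron(vs.V_E, np.eye(n))
        y = model.phenotypes.Y.T.reshape(-1)
        x_t = np.ones((n, 1))
        z = scipy.linalg.block_diag(x_t, x_t)
        vi_z = np.linalg.solve(v, z)
        beta_dense = np.linalg.solve(z.T @ vi_z, vi_z.T @ y)
        np.testing.assert_allclose(fe.beta, beta_dense, atol=1e-8)


class TestLikelihoodRatioTest:
    @pytest.mark.parametrize(
        "stat,df,expected_p",
        [(11.11, 10, 0.349), (72.03, 10, 1.79e-11)],
    )
    def test_chi_square_tail_worked_examples(self, stat, df, expected_p):
        res = LrtResult.from_statistic(stat, df)
        assert res.p_value == pytest.approx(expected_p, rel=5e-3)

    def test_statistic_from_loglikelihoods(self):
        res = likelihood_ratio_test(-100.0, -103.5, df=2)
        assert res.statistic == pytest.approx(7.0)
        assert 0.0 < res.p_value < 0.05

    def test_equal_loglikelihoods_give_p_one(self):
        res = likelihood_ratio_test(-50.0, -50.0, df=3)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_substantially_negative_statistic_rejected(self):
        with pytest.raises(InputError):
            likelihood_ratio_test(-60.0, -50.0, df=2)
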