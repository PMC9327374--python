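"""REML kernel: whitening, log-likelihood vs the dense oracle, gradient, AI."""

import numpy as np
import pytest
import scipy.linalg

from mvgreml import (
    MgremlModel,
    NumericalError,
    dense_reml_oracle,
    diagonalize_pair,
    reml_loglik,
)
from mvgreml.factors import (
    VarianceStructure,
    implied_variance_matrices,
    parameter_index,
)
from mvgreml.kernel import average_information, reml_loglik_and_gradient

from conftest import random_theta, small_dataset


class TestDiagonalizePair:
    def test_identity_pair(self):
        vs = VarianceStructure.from_loadings(np.eye(2), np.eye(2))
        bd = diagonalize_pair(vs)
        np.testing.assert_allclose(bd.lam, [1.0, 1.0])
        np.testing.assert_allclose(bd.W @ bd.W.T, np.eye(2), atol=1e-10)

    def test_already_diagonal(self):
        vs = VarianceStructure.from_loadings(
            np.diag([np.sqrt(2.0), np.sqrt(3.0)]), np.eye(2)
        )
        bd = diagonalize_pair(vs)
        np.testing.assert_allclose(sorted(bd.lam), [2.0, 3.0])

    @pytest.mark.parametrize("d", [0.0, 0.5, 2.0])
    def test_simultaneous_whitening_random_pair(self, d):
        rng = np.random.default_rng(4)
        c_g = rng.standard_normal((5, 5)) * 0.5
        c_e = np.tril(rng.standard_normal((5, 5)) * 0.4) + np.eye(5)
        vs = VarianceStructure.from_loadings(c_g, c_e)
        bd = diagonalize_pair(vs)
        target = d * np.diag(bd.lam) + np.eye(5)
        got = bd.W @ (d * vs.V_G + vs.V_E) @ bd.W.T
        assert np.abs(got - target).max() < 1e-8

    def test_singular_environment_raises(self):
        vs = VarianceStructure.from_loadings(np.eye(2), np.zeros((2, 2)))
        with pytest.raises(NumericalError):
            diagonalize_pair(vs)


class TestRemlLoglik:
    def test_univariate_iid_closed_form(self):
        # A = I, T = 1, no covariates: the model is y ~ N(0, (sG+sE) I) and the
        # REML log-likelihood (constant omitted) is -(n/2) log s2 - y'y/(2 s2)
        rng = np.random.default_rng(5)
        n = 40
        from mvgreml import GrmData, PhenotypeMatrix, canonical_transform, eigendecompose_grm

        ids = [("f", f"i{k}") for k in range(n)]
        grm = GrmData(ids, np.eye(n), np.full((n, n), 5.0))
        y = rng.standard_normal((n, 1))
        phen = PhenotypeMatrix(ids, ["y0"], y)
        td = canonical_transform(eigendecompose_grm(grm), phen, L=0, include_intercept=False)
        s_g, s_e = 0.3, 0.9
        vs = VarianceStructure.from_loadings([[np.sqrt(s_g)]], [[np.sqrt(s_e)]])
        got = reml_loglik(td, vs).loglik
        s2 = s_g + s_e
        expected = -0.5 * (n * np.log(s2) + float(np.sum(y**2)) / s2)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_matches_dense_oracle_with_intercepts(self):
        ds = small_dataset(n=30, m=70, t=2)
        model = MgremlModel(ds.grm, ds.phen, drop_leading_pcs=0)
        rng = np.random.default_rng(6)
        theta = random_theta(model.spec_g, model.spec_e, rng)
        vs = implied_variance_matrices(theta, model.spec_g, model.spec_e)
        fast = reml_loglik(model.transformed, vs).loglik
        dense = dense_reml_oracle(model.grm, model.phenotypes, model.covariates, vs)
        assert abs(fast - dense) < 1e-8

    def test_rescaling_shifts_loglik_like_the_oracle(self):
        ds = small_dataset(n=25, m=60, t=2)
        model = MgremlModel(ds.grm, ds.phen, drop_leading_pcs=0)
        vs = VarianceStructure.from_loadings(
            np.array([[0.7, 0.0], [0.2, 0.6]]), np.array([[0.8, 0.0], [0.1, 0.9]])
        )
        c = 3.0
        phen_scaled = type(ds.phen)(
            ids=model.phenotypes.ids,
            trait_labels=model.phenotypes.trait_labels,
            Y=model.phenotypes.Y * c,
        )
        model_scaled = MgremlModel(model.grm, phen_scaled, drop_leading_pcs=0)
        ll = reml_loglik(model.transformed, vs).loglik
        ll_scaled = reml_loglik(model_scaled.transformed, vs).loglik
        dense = dense_reml_oracle(model.grm, model.phenotypes, model.covariates, vs)
        dense_scaled = dense_reml_oracle(
            model_scaled.grm, model_scaled.phenotypes, model_scaled.covariates, vs
        )
        assert abs((ll_scaled - ll) - (dense_scaled - dense)) < 1e-8

    def test_kronecker_degenerate_no_genetics(self):
        # V_G = 0: the oracle must equal the iid-model REML log-likelihood
        ds = small_dataset(n=20, m=50, t=2)
        model = MgremlModel(ds.grm, ds.phen, drop_leading_pcs=0)
        vs = VarianceStructure.from_loadings(
            np.zeros((2, 1)), np.array([[0.9, 0.0], [0.2, 0.8]])
        )
        dense = dense_reml_oracle(model.grm, model.phenotypes, model.covariates, vs)
        iid_grm = type(model.grm)(
            model.grm.ids, np.eye(model.grm.n), model.grm.pair_counts
        )
        dense_iid = dense_reml_oracle(iid_grm, model.phenotypes, model.covariates, vs)
        assert dense == pytest.approx(dense_iid, abs=1e-9)


class TestRemlGradient:
    def test_finite_difference_agreement(self):
        rng = np.random.default_rng(7)
        ds = small_dataset(n=40, m=90, t=3)
        model = MgremlModel(ds.grm, ds.phen, drop_leading_pcs=0)
        td = model.transformed
        for _ in range(5):
            theta = random_theta(model.spec_g, model.spec_e, rng)
            vs = implied_variance_matrices(theta, model.spec_g, model.spec_e)
            grad = reml_loglik_and_gradient(td, vs, theta).grad
            step = 1e-5
            for i in range(len(theta)):
                up, dn = theta.values.copy(), theta.values.copy()
                up[i] += step
                dn[i] -= step
                lu = reml_loglik(
                    td, implied_variance_matrices(theta.replace(up), model.spec_g, model.spec_e)
                ).loglik
                ld = reml_loglik(
                    td, implied_variance_matrices(theta.replace(dn), model.spec_g, model.spec_e)
                ).loglik
                fd = (lu - ld) / (2 * step)
                assert abs(grad[i] - fd) / max(1.0, abs(fd)) < 1e-5

    def test_zero_genetic_loadings_have_zero_gradient_structure(self):
        # with c_f = 0 the derivative e_t c_f' + c_f e_t' vanishes identically
        ds = small_dataset(n=30, m=60, t=2)
        model = MgremlModel(ds.grm, ds.phen, drop_leading_pcs=0)
        from mvgreml.factors import ParameterVector

        index = parameter_index(model.spec_g, model.spec_e)
        values = np.array(
            [0.0 if tag == "G" else (1.0 if t == f else 0.2) for tag, t, f in index]
        )
        theta = ParameterVector(values=values, index=index)
        vs = implied_variance_matrices(theta, model.spec_g, model.spec_e)
        grad = reml_loglik_and_gradient(model.transformed, vs, theta).grad
        genetic = np.array([tag == "G" for tag, _, _ in index])
        np.testing.assert_allclose(grad[genetic], 0.0, atol=1e-12)

    def test_loglik_invariant_to_loading_column_sign_flip(self):
        ds = small_dataset(n=25, m=60, t=2)
        model = MgremlModel(ds.grm, ds.phen, drop_leading_pcs=0)
        c_g = np.array([[0.7, 0.0], [0.4, 0.5]])
        c_e = np.array([[0.9, 0.0], [0.1, 0.8]])
        ll = reml_loglik(model.transformed, VarianceStructure.from_loadings(c_g, c_e)).loglik
        c_g_flipped = c_g * np.array([-1.0, 1.0])
        ll_flip = reml_loglik(
            model.transformed, VarianceStructure.from_loadings(c_g_flipped, c_e)
        ).loglik
        assert ll == pytest.approx(ll_flip, abs=1e-12)


class TestAverageInformation:
    def test_symmetric_by_construction(self):
        ds = small_dataset(n=30, m=60, t=2)
        model = MgremlModel(ds.grm, ds.phen, drop_leading_pcs=0)
        theta = random_theta(model.spec_g, model.spec_e, np.random.default_rng(8))
        vs = implied_variance_matrices(theta, model.spec_g, model.spec_e)
        ai = average_information(model.transformed, vs, theta)
        np.testing.assert_array_equal(ai, ai.T)

    def test_matches_dense_brute_force(self):
        ds = small_dataset(n=25, m=60, t=2)
        model = MgremlModel(ds.grm, ds.phen, drop_leading_pcs=0)
        td = model.transformed
        theta = random_theta(model.spec_g, model.spec_e, np.random.default_rng(9))
        vs = implied_variance_matrices(theta, model.spec_g, model.spec_e)
        ai = average_information(td, vs, theta)

        # brute force with M materialized in the transformed coordinates
        n, t = td.n, td.n_traits
        from mvgreml.factors import variance_derivative

        big_d = np.diag(td.d)
        v = np.kron(big_d, vs.V_G) + np.kron(np.eye(n), vs.V_E)
        y = td.Ystar.T.reshape(-1)
        z = td.design_tensor.reshape(n * t, -1)
        vi = np.linalg.inv(v)
        m_mat = vi - vi @ z @ np.linalg.inv(z.T @ vi @ z) @ z.T @ vi
        my = m_mat @ y
        p = len(theta)
        dense = np.empty((p, p))
        dvs = []
        for i in range(p):
            tag, e, c = variance_derivative(theta, i, vs)
            dv = np.outer(e, c) + np.outer(c, e)
            dvs.append(np.kron(big_d, dv) if tag == "G" else np.kron(np.eye(n), dv))
        for i in range(p):
            for j in range(p):
                dense[i, j] = 0.5 * my @ dvs[i] @ m_mat @ dvs[j] @ my
        assert np.abs(ai - dense).max() < 1e-8

    def test_univariate_iid_matches_expected_information(self):
        # T=1, A=I, no fixed effects: V = (sG+sE) I, and both parameters act
        # through s2 = gamma^2 + eps^2; the exact information for s2 is
        # n / (2 s2^2), so AI for gamma is (2 gamma)^2 * I_s2 in expectation.
        rng = np.random.default_rng(10)
        from mvgreml import GrmData, PhenotypeMatrix, canonical_transform, eigendecompose_grm
        from mvgreml.factors import ParameterVector, saturated_spec

        n = 1500
        ids = [("f", f"i{k}") for k in range(n)]
        grm = GrmData(ids, np.eye(n), np.full((n, n), 5.0))
        gamma, eps = 0.8, 0.9
        s2 = gamma**2 + eps**2
        y = rng.standard_normal((n, 1)) * np.sqrt(s2)
        phen = PhenotypeMatrix(ids, ["y0"], y)
        td = canonical_transform(eigendecompose_grm(grm), phen, L=0, include_intercept=False)
        spec = saturated_spec(["y0"])
        theta = ParameterVector(np.array([gamma, eps]), parameter_index(spec, spec))
        vs = implied_variance_matrices(theta, spec, spec)
        ai = average_information(td, vs, theta)
        info_s2 = n / (2 * s2**2)
        expected = np.array(
            [[4 * gamma**2, 4 * gamma * eps], [4 * gamma * eps, 4 * eps**2]]
        ) * info_s2
        # AI is stochastic (quadratic in y); Monte Carlo slack ~ 1/sqrt(n)
        assert np.abs(ai / expected - 1.0).max() < 0.15
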