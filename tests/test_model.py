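"""Covariance construction and likelihood contracts of the mixed model."""

import numpy as np
import pytest
from scipy import stats

import ctmm.model as mdl
from ctmm import (
    ModelSpec,
    SimulationConfig,
    SingularCovarianceError,
    VarianceComponents,
    simulate_ctp,
    simulate_op,
)
from ctmm.fit import fit_reml, fit_ml


def _random_instance(rng, N, C, covariates=False, batch=False, mode="ctp"):
    # OP mode has one observation per individual: keep the fixed-effect
    # design (C cell types + covariates) strictly thinner than N
    if mode == "op":
        N = max(N, C + (2 if covariates else 0) + 2)
    cfg = SimulationConfig(n_individuals=N, n_cell_types=C, structure="free",
                           seed=int(rng.integers(2**16)))
    pb, _ = (simulate_ctp if mode == "ctp" else simulate_op)(cfg, 0)
    V = rng.normal(size=(C, C))
    V = 0.05 * (V + V.T) + 0.3 * np.eye(C)
    params = VarianceComponents(
        beta=rng.normal(size=C + (2 if covariates else 0)),
        sigma_alpha2=float(rng.uniform(0.05, 0.3)), V=V,
        batch_var=float(rng.uniform(0.05, 0.2)) if batch else 0.0)
    spec = ModelSpec(
        structure="full", mode=mode,
        covariates=rng.normal(size=(N, 2)) if covariates else None,
        random_blocks=rng.integers(0, 3, size=N) if batch else None)
    return spec, params, pb


class TestCovarianceConstruction:
    def test_hom_with_unit_noise_is_shifted_identity(self):
        cfg = SimulationConfig(n_individuals=3, n_cell_types=2,
                               structure="hom", seed=0)
        pb, _ = simulate_ctp(cfg, 0)
        pb.nu_ct = np.ones_like(pb.nu_ct)
        params = VarianceComponents(beta=np.zeros(2), sigma_alpha2=0.0,
                                    V=np.zeros((2, 2)))
        spec = ModelSpec(structure="hom", mode="ctp")
        Sigma, mean = mdl.ctp_covariance(spec, params, pb)
        np.testing.assert_allclose(Sigma, np.eye(6))
        np.testing.assert_allclose(mean, 0.0)

    def test_op_variance_quadratic_form(self):
        # P = (1/2, 1/2), V = diag(0.4, 0.4) -> P'VP = 0.2
        cfg = SimulationConfig(n_individuals=1, n_cell_types=2,
                               structure="free", seed=0)
        pb, _ = simulate_op(cfg, 0)
        pb.P = np.array([[0.5, 0.5]])
        pb.nu_op = np.zeros(1)
        params = VarianceComponents(beta=np.zeros(2), sigma_alpha2=0.0,
                                    V=0.4 * np.eye(2))
        var = mdl._op_variances(ModelSpec(structure="free", mode="op"),
                                params, pb)
        assert var[0] == pytest.approx(0.2)
        # hom collapse: V = 0 -> sigma_alpha2 + nu regardless of P
        params2 = VarianceComponents(beta=np.zeros(2), sigma_alpha2=0.3,
                                     V=np.zeros((2, 2)))
        pb.nu_op = np.array([0.1])
        var2 = mdl._op_variances(ModelSpec(structure="hom", mode="op"),
                                 params2, pb)
        assert var2[0] == pytest.approx(0.4)
        # pure cell type: P = (1, 0) -> sigma_alpha2 + V_11 + nu
        pb.P = np.array([[1.0, 0.0]])
        params3 = VarianceComponents(beta=np.zeros(2), sigma_alpha2=0.3,
                                     V=np.diag([0.4, 7.0]))
        var3 = mdl._op_variances(ModelSpec(structure="free", mode="op"),
                                 params3, pb)
        assert var3[0] == pytest.approx(0.8)

    def test_c1_block_is_scalar_sum(self):
        cfg = SimulationConfig(n_individuals=2, n_cell_types=1,
                               structure="free", V=np.array([[0.2]]), seed=0)
        pb, _ = simulate_ctp(cfg, 0)
        params = VarianceComponents(beta=np.zeros(1), sigma_alpha2=0.3,
                                    V=np.array([[0.2]]))
        Sigma, _ = mdl.ctp_covariance(ModelSpec(structure="free", mode="ctp"),
                                      params, pb)
        np.testing.assert_allclose(np.diag(Sigma),
                                   0.5 + pb.nu_ct[:, 0], rtol=1e-12)

    def test_nonpositive_total_covariance_names_parameters(self):
        cfg = SimulationConfig(n_individuals=3, n_cell_types=2,
                               structure="hom", seed=0)
        pb, _ = simulate_ctp(cfg, 0)
        params = VarianceComponents(beta=np.zeros(2), sigma_alpha2=-5.0,
                                    V=np.zeros((2, 2)))
        with pytest.raises(SingularCovarianceError, match="sigma_alpha2"):
            mdl.ctp_covariance(ModelSpec(structure="hom", mode="ctp"),
                               params, pb)


class TestLikelihoodOracle:
    @pytest.mark.parametrize("covariates,batch", [
        (False, False), (True, False), (False, True), (True, True)])
    @pytest.mark.parametrize("mode", ["ctp", "op"])
    def test_fast_path_matches_dense_oracle(self, covariates, batch, mode):
        """The O(N C^3) block/Woodbury likelihood equals the dense
        multivariate-normal construction on random small instances."""
        rng = np.random.default_rng(12345)
        for _ in range(25):
            N, C = int(rng.integers(4, 7)), int(rng.integers(1, 4))
            spec, params, pb = _random_instance(rng, N, C, covariates,
                                                batch, mode)
            for fn in (mdl.restricted_loglik,):
                fast = fn(spec, params, pb, method="fast")
                dense = fn(spec, params, pb, method="dense")
                assert abs(fast - dense) < 1e-8
            fast = mdl.gaussian_loglik(spec, params, pb, method="fast",
                                       profile_beta=True)
            dense = mdl.gaussian_loglik(spec, params, pb, method="dense",
                                        profile_beta=True)
            assert abs(fast - dense) < 1e-8

    def test_loglik_equals_scipy_mvn_density(self):
        """On a complete instance, the unprofiled likelihood is exactly the
        multivariate-normal log-density at the dense mean/covariance."""
        rng = np.random.default_rng(9)
        spec, params, pb = _random_instance(rng, 4, 3)
        Sigma, mean = mdl.ctp_covariance(spec, params, pb)
        y = pb.y_ct.reshape(-1)
        expected = stats.multivariate_normal(mean, Sigma).logpdf(y)
        got = mdl.gaussian_loglik(spec, params, pb, profile_beta=False)
        assert got == pytest.approx(expected, abs=1e-9)


class TestModelProperties:
    def test_full_model_lambda_shift_invariance(self):
        """Passing a constant between sigma_alpha2 and V + lambda*J leaves
        the likelihood unchanged (the Full-model identifiability gauge)."""
        rng = np.random.default_rng(3)
        spec, params, pb = _random_instance(rng, 5, 3)
        C = 3
        base = mdl.restricted_loglik(spec, params, pb)
        base_ml = mdl.gaussian_loglik(spec, params, pb, profile_beta=True)
        for lam in (-0.1, 0.05, 0.3):
            shifted = VarianceComponents(
                beta=params.beta, sigma_alpha2=params.sigma_alpha2 - lam,
                V=params.V + lam * np.ones((C, C)),
                batch_var=params.batch_var)
            assert abs(mdl.restricted_loglik(spec, shifted, pb) - base) < 1e-8
            assert abs(mdl.gaussian_loglik(spec, shifted, pb,
                                           profile_beta=True) - base_ml) < 1e-8

    def test_nested_structures_order_max_loglik(self):
        cfg = SimulationConfig(n_individuals=25, n_cell_types=3,
                               structure="free", seed=77)
        pb, _ = simulate_ctp(cfg, 0)
        lls = []
        for structure in ("hom", "iid", "free", "full"):
            res = fit_reml(pb, ModelSpec(structure=structure, mode="ctp"),
                           seed=0)
            assert res.converged
            lls.append(res.objective)
        tol = 1e-6
        assert lls[0] <= lls[1] + tol <= lls[2] + 2 * tol <= lls[3] + 3 * tol

    def test_reml_invariant_to_fixed_design_reparameterization(self):
        """REML is unchanged when a covariate column is rescaled or
        shifted (absorbed by the fixed effects)."""
        rng = np.random.default_rng(21)
        cfg = SimulationConfig(n_individuals=20, n_cell_types=2,
                               structure="free", seed=5)
        pb, truth = simulate_ctp(cfg, 0)
        W = rng.normal(size=(20, 1))
        params = VarianceComponents(beta=np.zeros(3), sigma_alpha2=0.1,
                                    V=0.1 * np.eye(2))
        base = mdl.restricted_loglik(
            ModelSpec(structure="free", mode="ctp", covariates=W), params, pb)
        for W2 in (3.0 * W, W + 7.0):
            ll = mdl.restricted_loglik(
                ModelSpec(structure="free", mode="ctp", covariates=W2),
                params, pb)
            assert abs(ll - base) < 1e-8

    def test_parameter_counts(self):
        C = 4
        assert mdl.n_model_params(ModelSpec(structure="hom"), C) == C + 1
        assert mdl.n_model_params(ModelSpec(structure="iid"), C) == C + 2
        assert mdl.n_model_params(ModelSpec(structure="free"), C) == 2 * C + 1
        assert mdl.n_model_params(ModelSpec(structure="full"), C) == \
            C + C * (C + 1) // 2

    def test_pack_unpack_round_trip(self):
        rng = np.random.default_rng(2)
        for structure in ("hom", "iid", "free", "full"):
            for batch in (False, True):
                spec = ModelSpec(structure=structure,
                                 random_blocks=np.zeros(3) if batch else None)
                n = mdl.n_variance_params(spec, 3)
                theta = rng.normal(size=n)
                back = mdl.pack(spec, mdl.unpack(spec, theta, 3))
                np.testing.assert_allclose(back, theta)
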