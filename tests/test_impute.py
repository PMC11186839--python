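"""Matrix completion of pseudobulk and copy-mask benchmarking."""

import numpy as np
import pandas as pd
import pytest

import ctmm.impute as imp


def _lowrank_matrix(rng, N=40, C=4, rank=1):
    U = rng.normal(size=(N, rank))
    W = rng.normal(size=(rank, C))
    return U @ W


class TestLowRank:
    def test_rank1_recovery(self):
        rng = np.random.default_rng(0)
        Y = _lowrank_matrix(rng, rank=1)
        Ym = Y.copy()
        hide = rng.random(Y.shape) < 0.10
        Ym[hide] = np.nan
        Z = imp.soft_impute(Ym, lam=0.0, rank=1, tol=1e-12, max_iter=5000)
        scale = np.abs(Y[hide]).mean()
        assert np.abs(Z[hide] - Y[hide]).max() / scale < 1e-3

    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(10, 3))
        np.testing.assert_array_equal(imp.soft_impute(Y, lam=0.5), Y)

    def test_observed_entries_never_altered(self):
        rng = np.random.default_rng(2)
        Y = _lowrank_matrix(rng, rank=2) + 0.1 * rng.normal(size=(40, 4))
        Ym = Y.copy()
        Ym[rng.random(Y.shape) < 0.15] = np.nan
        for imputer in (lambda X: imp.soft_impute(X, lam=0.1),
                        lambda X: imp.impute_pergene_mvn(X)[0],
                        imp.column_mean_impute,
                        imp.impute_pergene_lowrank):
            Z = imputer(Ym)
            obs = ~np.isnan(Ym)
            np.testing.assert_array_equal(Z[obs], Ym[obs])

    def test_identical_columns_fill_from_row(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=20)
        Y = np.tile(col[:, None], (1, 3))
        Ym = Y.copy()
        Ym[5, 1] = np.nan
        Z = imp.soft_impute(Ym, lam=1e-6, rank=1, tol=1e-12, max_iter=5000)
        assert Z[5, 1] == pytest.approx(col[5], abs=1e-3)

    def test_fully_missing_column_rejected(self):
        Y = np.ones((5, 2))
        Y[:, 1] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            imp.soft_impute(Y, lam=0.1)

    def test_transcriptomewide_with_one_gene_is_pergene(self):
        rng = np.random.default_rng(4)
        Y = _lowrank_matrix(rng, rank=2)
        Y[rng.random(Y.shape) < 0.1] = np.nan
        np.testing.assert_array_equal(
            imp.impute_transcriptomewide_lowrank(Y, seed=3),
            imp.impute_pergene_lowrank(Y, seed=3))

    def test_joint_imputation_beats_pergene_on_shared_factors(self):
        """Genes driven by a common individual factor: stacking them lets
        the low-rank imputer borrow strength, lowering the error."""
        rng = np.random.default_rng(5)
        N, C, G = 30, 4, 12
        factor = rng.normal(size=(N, 1))
        genes = [factor @ rng.normal(size=(1, C))
                 + 0.05 * rng.normal(size=(N, C)) for _ in range(G)]
        hide = [rng.random((N, C)) < 0.1 for _ in range(G)]
        masked = [np.where(h, np.nan, g) for g, h in zip(genes, hide)]
        per_err, joint_in = [], np.hstack(masked)
        joint_out = imp.impute_transcriptomewide_lowrank(joint_in, seed=0)
        joint_err = []
        for g in range(G):
            Z = imp.impute_pergene_lowrank(masked[g], seed=g)
            per_err.append(np.nanmean((Z[hide[g]] - genes[g][hide[g]]) ** 2))
            Zj = joint_out[:, g * C:(g + 1) * C]
            joint_err.append(np.nanmean((Zj[hide[g]] - genes[g][hide[g]]) ** 2))
        assert np.mean(joint_err) <= np.mean(per_err)


class TestMVN:
    def test_perfect_correlation_gives_linear_prediction(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        Y = np.column_stack([x, 2.0 * x + 1.0])
        Ym = Y.copy()
        Ym[3, 1] = np.nan
        Z, conv = imp.impute_pergene_mvn(Ym)
        assert conv
        assert Z[3, 1] == pytest.approx(2.0 * x[3] + 1.0, abs=1e-4)

    def test_independent_columns_fill_with_column_mean(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(400, 2))
        Ym = Y.copy()
        Ym[10, 0] = np.nan
        Z, _ = imp.impute_pergene_mvn(Ym)
        # nearly independent columns: conditional mean ~ marginal mean
        assert Z[10, 0] == pytest.approx(np.nanmean(Ym[:, 0]), abs=0.05)

    def test_mse_matches_analytic_conditional_variance(self):
        """Masked-entry MSE under a known MVN equals the analytic
        conditional variance given the observed coordinates."""
        rng = np.random.default_rng(8)
        C = 4
        A = rng.normal(size=(C, C))
        Sigma = A @ A.T + 0.5 * np.eye(C)
        N = 2500
        Y = rng.multivariate_normal(np.zeros(C), Sigma, size=N)
        Ym = Y.copy()
        hide_col = 2
        hide_rows = rng.random(N) < 0.10
        Ym[hide_rows, hide_col] = np.nan
        Z, conv = imp.impute_pergene_mvn(Ym)
        assert conv
        o = [c for c in range(C) if c != hide_col]
        cond_var = Sigma[hide_col, hide_col] - Sigma[hide_col, o] @ \
            np.linalg.solve(Sigma[np.ix_(o, o)], Sigma[o, hide_col])
        mse = np.mean((Z[hide_rows, hide_col] - Y[hide_rows, hide_col]) ** 2)
        se = np.std((Z[hide_rows, hide_col] - Y[hide_rows, hide_col]) ** 2,
                    ddof=1) / np.sqrt(hide_rows.sum())
        assert abs(mse - cond_var) < 4 * se


class TestRepairNegativeNu:
    def test_op_clamps_to_zero(self):
        out = imp.repair_negative_nu(np.array([[-0.1, 0.2]]), "op")
        np.testing.assert_allclose(out, [[0.0, 0.2]])

    def test_ctp_uses_max_observed_raw(self):
        raw = np.array([[0.1, np.nan], [0.4, 0.2]])
        nu = np.array([[-0.3, 0.05], [0.2, 0.1]])
        out = imp.repair_negative_nu(nu, "ctp", raw_nu=raw)
        assert out[0, 0] == pytest.approx(0.4)
        np.testing.assert_allclose(out[1], [0.2, 0.1])

    def test_nonnegative_input_unchanged(self):
        nu = np.array([[0.0, 0.2], [0.3, 0.1]])
        np.testing.assert_array_equal(
            imp.repair_negative_nu(nu, "ctp", raw_nu=nu), nu)

    def test_output_is_everywhere_nonnegative(self):
        rng = np.random.default_rng(9)
        nu = rng.normal(0, 0.2, size=(20, 3))
        raw = np.abs(rng.normal(0, 0.2, size=(20, 3)))
        assert (imp.repair_negative_nu(nu, "op") >= 0).all()
        assert (imp.repair_negative_nu(nu, "ctp", raw_nu=raw) >= 0).all()

    def test_ctp_without_observed_raw_rejected(self):
        raw = np.full((3, 1), np.nan)
        with pytest.raises(ValueError, match="no observed raw"):
            imp.repair_negative_nu(np.array([[-1.0]] * 3), "ctp", raw_nu=raw)


class TestCopyMask:
    def _mask(self, N=30, C=4):
        mask = np.zeros((N, C), dtype=bool)
        mask[0, [1, 2]] = True  # donor individual missing two cell types
        mask[1, 3] = True
        return mask

    def test_structure_is_copied_from_donors(self):
        mask = self._mask()
        plan = imp.copy_mask(mask, 0.10, np.random.default_rng(0))
        donor_patterns = [frozenset([1, 2]), frozenset([3])]
        per_recipient = {}
        for i, c in plan.masked_pairs:
            per_recipient.setdefault(i, set()).add(c)
        for cts in per_recipient.values():
            assert any(cts <= p for p in donor_patterns) or \
                any(p <= cts for p in donor_patterns)

    def test_fraction_near_target(self):
        mask = self._mask()
        plan = imp.copy_mask(mask, 0.10, np.random.default_rng(1))
        assert plan.fraction >= 0.10
        assert plan.fraction < 0.25

    def test_no_donor_rejected(self):
        with pytest.raises(ValueError, match="donate"):
            imp.copy_mask(np.zeros((5, 3), dtype=bool), 0.1,
                          np.random.default_rng(0))

    def test_perfect_imputer_scores_perfectly(self):
        rng = np.random.default_rng(10)
        genes = {"g1": rng.normal(size=(30, 4))}
        truth = genes["g1"]
        table = imp.copy_mask_evaluate(genes, self._mask(),
                                       imputer=lambda X: np.where(
                                           np.isnan(X), truth, X),
                                       n_replicates=3, seed=0)
        done = table.dropna(subset=["median_correlation"])
        assert len(done) > 0
        np.testing.assert_allclose(done["median_correlation"], 1.0)
        np.testing.assert_allclose(table["median_mse"].dropna(), 0.0,
                                   atol=1e-12)

    def test_constant_imputer_mse_is_truth_variance(self):
        rng = np.random.default_rng(11)
        genes = {"g1": rng.normal(size=(200, 4))}
        table = imp.copy_mask_evaluate(
            genes, self._mask(200, 4),
            imputer=lambda X: np.where(np.isnan(X), 0.0, X),
            n_replicates=5, fraction=0.2, seed=0)
        # for a constant-zero imputer, MSE approaches E[y^2] = 1
        mses = table["median_mse"].dropna()
        assert ((mses - 1.0).abs() < 0.5).all()
        assert table["median_correlation"].isna().all() or \
            (table["median_correlation"].dropna().abs() < 0.5).all()

    def test_lowrank_beats_column_mean_on_lowrank_truth(self):
        rng = np.random.default_rng(12)
        N, C = 40, 4
        factor = rng.normal(size=(N, 1))
        genes = {f"g{k}": factor @ rng.normal(size=(1, C))
                 + 0.05 * rng.normal(size=(N, C)) for k in range(5)}
        mask = self._mask(N, C)
        low = imp.copy_mask_evaluate(
            genes, mask, imputer=lambda X: imp.soft_impute(X, lam=0.0, rank=1),
            n_replicates=5, seed=0)
        base = imp.copy_mask_evaluate(
            genes, mask, imputer=imp.column_mean_impute,
            n_replicates=5, seed=0)
        assert low["median_correlation"].median() > \
            base["median_correlation"].fillna(0.0).median()
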