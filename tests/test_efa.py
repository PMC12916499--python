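"""Factor extraction, rotation, fit indices, bifactor and score machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import factorverse as fv
from factorverse.efa import identification_df
from factorverse.exceptions import (
    InvalidArgumentError,
    RankDeficiencyError,
    UndefinedFitIndexError,
)
from factorverse.rotation import gpa_oblique, quartimin_criterion, rotate_loadings

from conftest import random_correlation


def ml_discrepancy(R, L, psi):
    """Direct ML discrepancy F = log|S| + tr(R S^-1) - log|R| - p."""
    S = L @ L.T + np.diag(psi)
    sign, logdet_S = np.linalg.slogdet(S)
    _, logdet_R = np.linalg.slogdet(R)
    return logdet_S + np.trace(R @ np.linalg.inv(S)) - logdet_R - len(psi)


class TestExtractMl:
    def test_identity_matrix_no_common_variance(self):
        sol = fv.extract_ml(np.eye(6), 1, 500)
        assert np.abs(sol.loadings.to_numpy()).max() < 1e-3
        assert sol.communalities().max() < 1e-5

    def test_exact_model_recovery(self):
        lam = np.array([[0.8], [0.7], [0.6]])
        R = lam @ lam.T
        np.fill_diagonal(R, 1.0)
        sol = fv.extract_ml(R, 1, 500)
        got = np.abs(sol.loadings.to_numpy().ravel())
        np.testing.assert_allclose(got, [0.8, 0.7, 0.6], atol=1e-5)
        assert sol.discrepancy < 1e-8
        assert sol.converged

    def test_optimizer_oracle(self):
        """Profile-likelihood minimum matches a direct optimisation of the
        full (Lambda, Psi) parameterisation from 10 random starts."""
        rng = np.random.default_rng(21)
        R = random_correlation(8, rng)
        k = 2
        sol = fv.extract_ml(R, k, 400)

        def objective(theta):
            L = theta[: 8 * k].reshape(8, k)
            psi = np.exp(theta[8 * k:])
            return ml_discrepancy(R, L, psi)

        best = np.inf
        for _ in range(10):
            theta0 = np.concatenate([
                rng.normal(scale=0.3, size=8 * k),
                np.log(rng.uniform(0.2, 0.9, size=8)),
            ])
            res = minimize(objective, theta0, method="L-BFGS-B",
                           options={"maxiter": 2000})
            best = min(best, res.fun)
        assert sol.discrepancy == pytest.approx(best, abs=1e-5)

    def test_identification_bound_enforced(self):
        with pytest.raises(InvalidArgumentError):
            fv.extract_ml(np.eye(5), 3, 100)  # (5-3)^2 < 5+3

    def test_discrepancy_monotone_in_k(self, small_hetcor):
        n = 600
        f = [fv.extract_ml(small_hetcor, k, n).discrepancy for k in (1, 2, 3)]
        assert f[0] >= f[1] - 1e-8
        assert f[1] >= f[2] - 1e-8


class TestRotate:
    def test_k1_unchanged_up_to_sign(self, small_hetcor):
        sol = fv.extract_ml(small_hetcor, 1, 600)
        rot = fv.rotate(sol, "oblimin")
        np.testing.assert_allclose(np.abs(rot.loadings.to_numpy()),
                                   np.abs(sol.loadings.to_numpy()), atol=1e-12)

    def test_varimax_preserves_communalities(self, small_hetcor):
        sol = fv.extract_ml(small_hetcor, 3, 600)
        rot = fv.rotate(sol, "varimax")
        before = (sol.loadings.to_numpy() ** 2).sum(axis=1)
        after = (rot.loadings.to_numpy() ** 2).sum(axis=1)
        np.testing.assert_allclose(after, before, atol=1e-8)
        np.testing.assert_allclose(rot.factor_corr, np.eye(3))

    def test_oblimin_beats_random_rotations(self):
        """GPA quartimin value <= best of 10,000 random oblique rotations."""
        rng = np.random.default_rng(7)
        A = rng.normal(scale=0.5, size=(10, 2))
        _, _, f_gpa, conv = rotate_loadings(A, "oblimin", seed=1)
        assert conv
        best = np.inf
        for _ in range(10_000):
            T = rng.standard_normal((2, 2))
            T /= np.sqrt((T * T).sum(axis=0, keepdims=True))
            try:
                L = A @ np.linalg.inv(T).T
            except np.linalg.LinAlgError:
                continue
            best = min(best, quartimin_criterion(L)[0])
        assert f_gpa <= best + 1e-10

    def test_chi_square_unchanged_by_rotation(self, small_hetcor):
        sol = fv.extract_ml(small_hetcor, 2, 600)
        for method in ("oblimin", "varimax"):
            rot = fv.rotate(sol, method)
            assert rot.chi_square == sol.chi_square
            assert rot.df == sol.df

    def test_sign_and_order_convention(self, small_hetcor):
        rot = fv.rotate(fv.extract_ml(small_hetcor, 3, 600), "oblimin")
        L = rot.loadings.to_numpy()
        for j in range(3):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0
        ss = (L ** 2).sum(axis=0)
        assert (np.diff(ss) <= 1e-10).all()

    def test_oblimin_varimax_scores_correlate(self, small_dataset, small_hetcor):
        """On simple-structure data the oblique and orthogonal first-order
        solutions give nearly the same dimensions."""
        sol = fv.extract_ml(small_hetcor, 2, small_dataset.n)
        Z = (small_dataset.responses - small_dataset.responses.mean()) \
            / small_dataset.responses.std(ddof=0)
        R = fv.ensure_psd(small_hetcor).matrix
        scores = {}
        for method in ("oblimin", "varimax"):
            rot = fv.rotate(sol, method)
            W = fv.regression_score_weights(R, rot)
            scores[method] = Z.to_numpy() @ W.to_numpy()
        C = np.corrcoef(scores["oblimin"].T, scores["varimax"].T)[:2, 2:]
        matched = np.abs(C).max(axis=1)
        assert (matched > 0.9).all()


class TestFitIndices:
    def test_hand_arithmetic(self):
        rmsea, tli = fv.fit_indices(120, 60, 1200, 78, 500)
        assert rmsea == pytest.approx(np.sqrt(60 / (60 * 499)))
        ratio = 1200 / 78
        assert tli == pytest.approx((ratio - 2.0) / (ratio - 1.0))

    def test_exact_fit_floor(self):
        rmsea, _ = fv.fit_indices(60, 60, 600, 78, 500)
        assert rmsea == 0.0
        rmsea, _ = fv.fit_indices(30, 60, 600, 78, 500)
        assert rmsea == 0.0

    def test_undefined_tli(self):
        with pytest.raises(UndefinedFitIndexError):
            fv.fit_indices(50, 60, 70, 78, 500)


class TestRegressionScoreWeights:
    def test_identity_R_orthonormal_loadings(self):
        items = [f"item{i}" for i in range(4)]
        L = pd.DataFrame(np.zeros((4, 2)), index=items, columns=["F1", "F2"])
        L.iloc[0, 0] = L.iloc[2, 1] = 1.0
        sol = fv.FactorSolution(
            loadings=L, factor_corr=np.eye(2),
            uniquenesses=pd.Series(0.0, index=items), rotation="varimax",
            chi_square=0.0, df=1.0, chi_square_null=1.0, df_null=1.0,
            rmsea=0.0, tli=1.0, n_used=100, converged=True)
        W = fv.regression_score_weights(
            pd.DataFrame(np.eye(4), index=items, columns=items), sol)
        np.testing.assert_allclose(W.to_numpy(), L.to_numpy())

    def test_shape_contract(self, small_hetcor):
        sol = fv.rotate(fv.extract_ml(small_hetcor, 3, 600), "oblimin")
        W = fv.regression_score_weights(fv.ensure_psd(small_hetcor).matrix, sol)
        assert W.shape == (len(sol.items), 3)
        assert list(W.columns) == list(sol.loadings.columns)

    def test_regression_scores_are_best_linear_predictor(self):
        """On model-implied data the regression weights reach the analytic
        maximum correlation with the true factor among linear combinations."""
        rng = np.random.default_rng(3)
        lam = np.array([0.8, 0.7, 0.6, 0.5])[:, None]
        R = lam @ lam.T
        np.fill_diagonal(R, 1.0)
        n = 50_000
        f = rng.standard_normal(n)
        X = f[:, None] * lam.T + rng.standard_normal((n, 4)) * \
            np.sqrt(1 - lam.ravel() ** 2)[None, :]
        sol = fv.extract_ml(R, 1, n)
        W = fv.regression_score_weights(R, sol).to_numpy().ravel()
        scores = X @ W
        r_score = abs(np.corrcoef(scores, f)[0, 1])
        # analytic validity of the regression predictor
        r_best = float(np.sqrt(lam.ravel() @ np.linalg.solve(R, lam.ravel())))
        assert r_score == pytest.approx(r_best, abs=0.01)
        # no random linear combination does better
        for _ in range(50):
            w = rng.standard_normal(4)
            assert abs(np.corrcoef(X @ w, f)[0, 1]) <= r_score + 0.01


class TestBifactor:
    def test_orthogonal_factors_degenerate_hierarchy(self):
        rng = np.random.default_rng(4)
        L = np.zeros((12, 2))
        L[:6, 0] = rng.uniform(0.5, 0.8, 6)
        L[6:, 1] = rng.uniform(0.5, 0.8, 6)
        R = L @ L.T
        np.fill_diagonal(R, 1.0)
        bif = fv.bifactor_schmid_leiman(R, 2, 500)
        assert bif.degenerate_hierarchy
        assert np.abs(bif.general_loadings.to_numpy()).max() < 1e-8

    def test_simulated_bifactor_recovery(self):
        """General 0.5 / group 0.4 structure recovered from sample data."""
        rng = np.random.default_rng(9)
        p, n = 15, 5000
        general = np.full(p, 0.5)
        groups = np.zeros((p, 3))
        for j in range(3):
            groups[5 * j:5 * (j + 1), j] = 0.4
        Lo = np.column_stack([general, groups])
        uniq = 1.0 - (Lo ** 2).sum(axis=1)
        F = rng.standard_normal((n, 4))
        X = F @ Lo.T + rng.standard_normal((n, p)) * np.sqrt(uniq)[None, :]
        R = np.corrcoef(X, rowvar=False)
        bif = fv.bifactor_schmid_leiman(pd.DataFrame(R), 3, n)
        assert not bif.degenerate_hierarchy
        assert np.abs(bif.general_loadings.to_numpy() - 0.5).max() < 0.1

    def test_schmid_leiman_variance_identity(self, small_hetcor):
        bif = fv.bifactor_schmid_leiman(fv.ensure_psd(small_hetcor), 2, 600)
        total = (bif.general_loadings ** 2
                 + (bif.group_loadings ** 2).sum(axis=1))
        oblique_comm = bif.source.communalities()
        assert np.abs(total - oblique_comm).max() < 0.02

    def test_k_group_lower_bound(self, small_hetcor):
        with pytest.raises(InvalidArgumentError):
            fv.bifactor_schmid_leiman(small_hetcor, 1, 600)


class TestAndersonRubinScores:
    def test_identity_sample_covariance(self, small_dataset, small_hetcor):
        Z = (small_dataset.responses - small_dataset.responses.mean()) \
            / small_dataset.responses.std(ddof=0)
        sol = fv.rotate(fv.extract_ml(small_hetcor, 2, small_dataset.n), "oblimin")
        R = fv.ensure_psd(small_hetcor).matrix
        scores, _ = fv.anderson_rubin_scores(Z, R, sol.loadings)
        S = scores.to_numpy()
        C = (S.T @ S) / len(S)
        np.testing.assert_allclose(C, np.eye(2), atol=1e-6)

    def test_textbook_formula_oracle(self):
        """With R equal to the sample correlation matrix, the empirical
        orthogonalisation reproduces W = R^-1 L (L' R^-1 L)^{-1/2}."""
        rng = np.random.default_rng(14)
        n, p = 2000, 6
        F = rng.standard_normal((n, 2))
        L_true = np.zeros((p, 2))
        L_true[:3, 0] = 0.7
        L_true[3:, 1] = 0.6
        X = F @ L_true.T + rng.standard_normal((n, p)) * 0.6
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        R = (Z.T @ Z) / n
        scores, W = fv.anderson_rubin_scores(Z, pd.DataFrame(R), L_true)
        W0 = np.linalg.solve(R, L_true)
        M = L_true.T @ W0
        lam, vec = np.linalg.eigh(M)
        W_textbook = W0 @ (vec / np.sqrt(lam)) @ vec.T
        np.testing.assert_allclose(W.to_numpy(), W_textbook, atol=1e-8)

    def test_rank_deficient_loadings_rejected(self, small_hetcor):
        L = np.ones((len(small_hetcor.items), 2))
        with pytest.raises(RankDeficiencyError):
            fv.anderson_rubin_scores(
                np.zeros((10, len(small_hetcor.items))), small_hetcor.matrix, L)


class TestParameterRecovery:
    def test_identification_df_formula(self):
        assert identification_df(10, 2) == ((10 - 2) ** 2 - 12) / 2
        assert identification_df(3, 1) == 0
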