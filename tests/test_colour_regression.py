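"""OLS, best-subset Cp selection, collinearity and Durbin-Watson."""

import numpy as np
import pytest

from durumcolor.colour_regression import (
    best_subset_cp,
    durbin_watson,
    fit_ols,
    standardized_beta_from_correlations,
)


def normal_equations_oracle(y, X):
    """From-scratch OLS via the normal equations."""
    X1 = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(X1.T @ X1, X1.T @ y)


class TestFitOls:
    def test_exact_affine_fit(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        y = 1.5 + 2.0 * X[:, 0] - 0.5 * X[:, 1]
        m = fit_ols(y, X)
        assert m.sse == pytest.approx(0.0, abs=1e-18)
        assert m.r2 == pytest.approx(1.0)

    def test_simple_regression_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = rng.normal(size=40) + 0.8 * x
        m = fit_ols(y, x[:, None], ["x"])
        r = np.corrcoef(x, y)[0, 1]
        slope = r * y.std(ddof=1) / x.std(ddof=1)
        assert m.coef.loc["x", "B"] == pytest.approx(slope, rel=1e-10)
        assert m.coef.loc["x", "beta"] == pytest.approx(r, rel=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50) + X @ [1.0, -2.0, 0.5]
        m = fit_ols(y, X, ["a", "b", "c"])
        want = normal_equations_oracle(y, X)
        assert np.allclose(m.coef["B"].to_numpy(), want, atol=1e-8)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        y = rng.normal(size=40)
        m = fit_ols(y, X)
        assert abs(m.residuals.sum()) < 1e-8
        assert np.abs(X.T @ m.residuals).max() < 1e-8

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        with pytest.raises(ValueError, match="dep3"):
            fit_ols(rng.normal(size=30), X, ["dep1", "dep2", "dep3"])

    def test_two_predictor_tolerance_identity(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=100)
        x2 = 0.6 * x1 + rng.normal(size=100)
        X = np.column_stack([x1, x2])
        m = fit_ols(rng.normal(size=100), X, ["x1", "x2"])
        r12 = np.corrcoef(x1, x2)[0, 1]
        assert np.allclose(m.collinearity["tolerance"], 1 - r12**2, atol=1e-12)
        assert np.allclose(
            m.collinearity["vif"], 1 / m.collinearity["tolerance"], atol=1e-12
        )


class TestBestSubsetCp:
    def test_full_model_cp_identity(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 4))
        y = rng.normal(size=60) + X[:, 0]
        models = best_subset_cp(y, X, ["a", "b", "c", "d"])
        full = next(m for m in models if m.k == 4)
        assert full.cp == pytest.approx(5.0, abs=1e-9)

    def test_sse_monotone_in_subset_size(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50) + X @ [1.0, 0.5, 0.0, 0.0]
        models = best_subset_cp(y, X, ["a", "b", "c", "d"])
        best_by_k = {}
        for m in models:
            best_by_k[m.k] = min(best_by_k.get(m.k, np.inf), m.sse)
        ks = sorted(best_by_k)
        assert all(best_by_k[k1] >= best_by_k[k2] - 1e-10
                   for k1, k2 in zip(ks, ks[1:]))

    def test_generating_pair_recovered_monte_carlo(self):
        # y built from 2 of 8 standard-normal predictors with unit signal
        # coefficients and noise SD 0.5, n = 144, 200 simulations: the
        # minimum-Cp subset contains the generating pair >= 90% of the time,
        # and the pair is the best subset of its own size.  (Exact-pair wins
        # cannot reach 90% under Cp: a spurious predictor enters whenever its
        # partial F exceeds 2, which happens with appreciable probability per
        # noise predictor regardless of signal strength.)
        codes = list("abcdefgh")
        contains = best_pair = 0
        for s in range(200):
            rng = np.random.default_rng(30_000 + s)
            X = rng.normal(size=(144, 8))
            y = X[:, 2] + X[:, 5] + 0.5 * rng.normal(size=144)
            models = best_subset_cp(y, X, codes, top=None)
            contains += {"c", "f"} <= set(models[0].predictors)
            pair_models = [m for m in models if m.k == 2]
            best_pair += min(pair_models, key=lambda m: m.cp).predictors == ("c", "f")
        assert contains >= 180
        assert best_pair >= 180

    def test_zero_residual_full_model_rejected(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 2))
        y = X @ [1.0, 2.0] + 3.0
        with pytest.raises(ValueError, match="Cp undefined"):
            best_subset_cp(y, X, ["a", "b"])


class TestStandardizedBeta:
    def test_identity_correlation(self):
        r_xy = np.array([0.3, -0.2, 0.5])
        beta = standardized_beta_from_correlations(np.eye(3), r_xy)
        assert np.allclose(beta, r_xy)

    def test_published_two_predictor_surrogate(self, trait_corr):
        R_xx = trait_corr.loc[["BI_S", "YI_S"], ["BI_S", "YI_S"]].to_numpy()
        r_xy = trait_corr.loc[["BI_S", "YI_S"], "YI_P"].to_numpy()
        beta = standardized_beta_from_correlations(R_xx, r_xy)
        assert beta[1] == pytest.approx(0.962, abs=0.01)   # YI_S
        assert beta[0] == pytest.approx(-0.107, abs=0.01)  # BI_S
        assert beta @ r_xy == pytest.approx(0.868, abs=0.02)  # implied R^2

    def test_matches_matrix_inverse_oracle(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(3, 3))
        R = np.corrcoef(A @ rng.normal(size=(3, 200)))
        r_xy = np.array([0.4, 0.1, -0.3])
        beta = standardized_beta_from_correlations(R, r_xy)
        assert np.allclose(beta, np.linalg.inv(R) @ r_xy, atol=1e-12)

    def test_equals_standardized_variable_ols(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(80, 3))
        y = X @ [1.0, -0.5, 0.2] + rng.normal(size=80)
        m = fit_ols(y, X, ["a", "b", "c"])
        R_xx = np.corrcoef(X, rowvar=False)
        r_xy = np.array([np.corrcoef(X[:, j], y)[0, 1] for j in range(3)])
        beta = standardized_beta_from_correlations(R_xx, r_xy)
        assert np.allclose(m.coef["beta"].to_numpy()[1:], beta, atol=1e-10)

    def test_singular_system_rejected(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="singular"):
            standardized_beta_from_correlations(R, np.array([0.5, 0.5]))


class TestDurbinWatson:
    def test_constant_residuals(self):
        assert durbin_watson(np.full(10, 1.3)) == pytest.approx(0.0)

    def test_alternating_hand_value(self):
        assert durbin_watson(np.array([1.0, -1.0, 1.0, -1.0])) == pytest.approx(3.0)

    def test_white_noise_mean_near_two(self):
        rng = np.random.default_rng(11)
        ds = [durbin_watson(rng.normal(size=144)) for _ in range(500)]
        assert np.mean(ds) == pytest.approx(2.0, abs=0.05)

    def test_matches_statsmodels(self):
        from statsmodels.stats.stattools import durbin_watson as sm_dw

        rng = np.random.default_rng(12)
        e = rng.normal(size=50)
        assert durbin_watson(e) == pytest.approx(float(sm_dw(e)), abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            durbin_watson(np.zeros(5))
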