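"""Best-subset prediction of pasta yellowness from semolina traits.

The response is the pasta yellow index; candidate predictors are the eight
semolina traits (enzyme activities, pigments, colour indices) observed on
the same flattened G x E cell-mean sample. Every non-empty predictor
subset is fitted by OLS (intercept always included) and ranked by Mallow's
Cp::

    Cp = SSE_subset / sigma2_full + 2 (k + 1) - n

with ``sigma2_full = SSE_full / (n - p_full - 1)`` the full-model residual
variance, so the full model lands exactly at Cp = p_full + 1 and a
well-specified subset near k + 1.

Fitted subsets carry the diagnostics reported for the published winning
model: raw (B) and standardized (beta) coefficients with t tests,
multiple R / R^2 / adjusted R^2, the model error (root MSE), per-predictor
collinearity measures (tolerance, VIF, the R^2 of each predictor on its
co-predictors), partial and semi-partial correlations with the response,
and the Durbin-Watson statistic of the residuals in input row order (the
row order is genotype-major over the cell-mean grid and is part of the
statistic's definition, since no canonical ordering of cells exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SubsetModel",
    "fit_ols",
    "best_subset_cp",
    "standardized_beta_from_correlations",
    "durbin_watson",
    "DW_BOUNDS_N144_K2",
]

#: Tabulated 5% Durbin-Watson bounds (d_L, d_U) for n = 144, k = 2 — the
#: published design size — for users reading the d statistic.
DW_BOUNDS_N144_K2 = (1.468, 1.767)


@dataclass
class SubsetModel:
    """One fitted predictor subset with its selection and collinearity report."""

    predictors: tuple[str, ...]
    n: int
    sse: float
    ss_regression: float
    ss_total: float
    r: float
    r2: float
    r2_adj: float
    model_error: float
    f: float
    f_p: float
    dw: float
    cp: float | None = None
    #: index const + predictors; columns B, beta, se, t, p
    coef: pd.DataFrame = field(default=None, repr=False)
    #: index predictors; columns tolerance, vif, resid_r2, partial, semipartial
    collinearity: pd.DataFrame = field(default=None, repr=False)
    residuals: np.ndarray = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return len(self.predictors)


def _dependent_columns(X: np.ndarray, codes: list[str]) -> list[str]:
    rank = 0
    dep = []
    for j in range(X.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, : j + 1])
        if new_rank == rank:
            dep.append(codes[j])
        rank = new_rank
    return dep


def durbin_watson(residuals: np.ndarray) -> float:
    """d = sum (e_t - e_{t-1})^2 / sum e_t^2 on residuals in input order."""
    e = np.asarray(residuals, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise ValueError("need a 1-d residual vector of length >= 2")
    denom = float(e @ e)
    if denom == 0.0:
        raise ValueError("all residuals are zero: Durbin-Watson undefined")
    return float(np.sum(np.diff(e) ** 2) / denom)


def fit_ols(
    y: np.ndarray,
    X: np.ndarray,
    predictors: list[str] | None = None,
    cp: float | None = None,
) -> SubsetModel:
    """Ordinary least squares of y on X with intercept, full diagnostics.

    Requires n > k + 1 and full column rank (dependent columns are named in
    the error). The overall F tests the regression mean square against the
    residual with df (k, n - k - 1).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, k = X.shape
    codes = list(predictors) if predictors is not None else [f"x{j + 1}" for j in range(k)]
    if len(codes) != k:
        raise ValueError("predictor name count does not match X columns")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 observations (n={n}, k={k})")
    X1 = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X1) < k + 1:
        dep = _dependent_columns(X1, ["const"] + codes)
        raise ValueError(f"rank-deficient design; dependent columns: {dep}")

    res = sm.OLS(y, X1).fit()
    B = res.params
    sd_y = y.std(ddof=1)
    sd_x = X.std(axis=0, ddof=1)
    beta = B[1:] * sd_x / sd_y if sd_y > 0 else np.full(k, np.nan)

    coef = pd.DataFrame(
        {
            "B": B,
            "beta": np.concatenate(([np.nan], beta)),
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        },
        index=["const"] + codes,
    )

    # Collinearity: VIF_j from the inverse predictor correlation matrix.
    if k >= 2:
        Rxx = np.corrcoef(X, rowvar=False)
        vif = np.diag(np.linalg.inv(Rxx))
    else:
        vif = np.ones(1)
    tol = 1.0 / vif
    df_resid = n - k - 1
    t_vals = res.tvalues[1:]
    partial = t_vals / np.sqrt(t_vals**2 + df_resid)
    semipartial = t_vals * np.sqrt((1.0 - res.rsquared) / df_resid)
    collin = pd.DataFrame(
        {
            "tolerance": tol,
            "vif": vif,
            "resid_r2": 1.0 - tol,
            "partial": partial,
            "semipartial": semipartial,
        },
        index=codes,
    )

    return SubsetModel(
        predictors=tuple(codes),
        n=n,
        sse=float(res.ssr),
        ss_regression=float(res.ess),
        ss_total=float(res.centered_tss),
        r=float(np.sqrt(max(res.rsquared, 0.0))),
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        model_error=float(np.sqrt(res.mse_resid)),
        f=float(res.fvalue),
        f_p=float(res.f_pvalue),
        dw=durbin_watson(res.resid) if float(res.ssr) > 0 else float("nan"),
        cp=cp,
        coef=coef,
        collinearity=collin,
        residuals=np.asarray(res.resid),
    )


def _subset_sse(A: np.ndarray, b: np.ndarray, yty: float, idx: tuple[int, ...]) -> float:
    """SSE of the OLS fit restricted to design columns ``idx`` (0 = intercept),
    from the precomputed Gram matrix A = X1'X1 and moment vector b = X1'y."""
    sel = (0,) + tuple(i + 1 for i in idx)
    As = A[np.ix_(sel, sel)]
    bs = b[list(sel)]
    coef = np.linalg.solve(As, bs)
    return float(yty - bs @ coef)


def best_subset_cp(
    y: np.ndarray,
    X: np.ndarray,
    predictors: list[str],
    top: int | None = None,
) -> list[SubsetModel]:
    """Exhaustively rank all 2^p - 1 predictor subsets by Mallow's Cp.

    Ties are broken by smaller subset size, then lexicographic predictor
    codes. Returns fitted :class:`SubsetModel` objects for the ``top``
    subsets (all of them by default). Raises when the full model fits the
    response exactly, since sigma2_full = 0 leaves Cp undefined.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= p <= 20:
        raise ValueError("exhaustive enumeration supports 1..20 predictors")
    full = fit_ols(y, X, predictors)
    sigma2_full = full.sse / (n - p - 1)
    if full.sse <= 1e-12 * max(full.ss_total, 1.0):
        raise ValueError("full model has zero residual variance: Cp undefined")

    X1 = np.column_stack([np.ones(n), X])
    A = X1.T @ X1
    b = X1.T @ y
    yty = float(y @ y)

    ranked: list[tuple[float, int, tuple[str, ...], tuple[int, ...]]] = []
    for k in range(1, p + 1):
        for idx in combinations(range(p), k):
            sse = _subset_sse(A, b, yty, idx)
            cp = sse / sigma2_full + 2 * (k + 1) - n
            codes = tuple(predictors[i] for i in idx)
            ranked.append((cp, k, codes, idx))
    ranked.sort(key=lambda t: (t[0], t[1], t[2]))
    if top is not None:
        ranked = ranked[:top]
    return [
        fit_ols(y, X[:, list(idx)], list(codes), cp=cp)
        for cp, _, codes, idx in ranked
    ]


def standardized_beta_from_correlations(
    R_xx: np.ndarray, r_xy: np.ndarray
) -> np.ndarray:
    """Standardized coefficients from correlations alone: solve R_xx b = r_xy.

    This is the normal-equation system of the regression on standardized
    variables, so it reproduces the beta coefficients of a fitted model
    when fed that model's predictor and response correlations. The implied
    coefficient of determination is ``b @ r_xy``.
    """
    R_xx = np.asarray(R_xx, dtype=float)
    r_xy = np.asarray(r_xy, dtype=float)
    if R_xx.shape[0] != R_xx.shape[1] or R_xx.shape[0] != r_xy.shape[0]:
        raise ValueError("shape mismatch between R_xx and r_xy")
    try:
        return np.linalg.solve(R_xx, r_xy)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular predictor correlation matrix") from exc
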