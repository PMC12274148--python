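"""Per-CpG association p-values from the two regression routes.

Complete-set route (the integrative "IG" model): a first linear model regresses
the outcome on expression and covariates,

    E[Y_i | G_i, X_i] = alpha_0 + G_i' alpha_G + X_i' alpha_X,

and the fitted gene score s_i = G_i' alpha_G_hat is then regressed on one CpG
at a time,

    s_i = beta_0j + beta_Mj * M_ij + X_i' beta_X + u_ij,

with a two-sided t-test of H0: beta_Mj = 0.  The second stage treats the gene
score as data (plug-in): the standard error is the plain OLS one and does not
propagate the uncertainty of alpha_G_hat.

Incomplete-set route: a marginal linear model of the outcome on one CpG,

    Y_i = gamma_0j + gamma_Mj * M_ij + X_i' gamma_X + eps_ij,

again t-tested two-sided.  When the two-stage model generates the data, the
null gamma_Mj = 0 is equivalent to beta_Mj = 0, which is what licenses using
either route's p-value to weight the other's.

All fits are ordinary least squares via a QR decomposition.  Zero-residual
degenerate fits do not raise: they return the p-value floor with a flag so a
genome-scale loop keeps going.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateRegressorError,
    InsufficientSamplesError,
    SingularDesignError,
)

__all__ = [
    "P_FLOOR",
    "IGFit",
    "CpGStageResult",
    "fit_outcome_model",
    "test_cpg_ig",
    "test_cpg_lm",
    "ig_pvalues",
    "lm_pvalues",
]

#: Smallest positive normal double; p-values are floored here so that
#: -log10 and Cauchy-tangent transforms downstream stay finite.
P_FLOOR: float = float(np.finfo(np.float64).tiny)

# Relative threshold on R's diagonal below which a design column is treated
# as collinear, and on residual variance below which a fit is degenerate.
_RANK_RTOL = 1e-10
_RESID_RTOL = 1e-12


@dataclass
class IGFit:
    """First-stage fit of the outcome on expression (+ covariates)."""

    alpha0: float
    alphaG: np.ndarray
    alphaX: np.ndarray
    gene_score: np.ndarray


@dataclass
class CpGStageResult:
    """Slope, t-statistic and two-sided p-value for a single CpG regression."""

    beta_M: float
    se: float
    t_stat: float
    df: int
    p_value: float
    degenerate: bool = False


def _as_design(
    primary: Optional[np.ndarray], X: Optional[np.ndarray], n: int
) -> np.ndarray:
    """Stack [intercept, primary regressor(s), covariates] column-wise."""
    cols = [np.ones((n, 1))]
    if primary is not None:
        primary = np.asarray(primary, dtype=float)
        if primary.ndim == 1:
            primary = primary[:, None]
        cols.append(primary)
    if X is not None and np.asarray(X).size:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        cols.append(X)
    return np.hstack(cols)


def _qr_ols(design: np.ndarray, y: np.ndarray):
    """OLS via QR; returns (coef, XtX_inv_diag, sigma2, df, degenerate)."""
    n, p = design.shape
    if n <= p:
        raise InsufficientSamplesError(
            f"{n} rows cannot identify {p} regression coefficients"
        )
    Q, R = np.linalg.qr(design)
    diag = np.abs(np.diag(R))
    tol = _RANK_RTOL * diag.max()
    bad = np.flatnonzero(diag < tol)
    if bad.size:
        raise SingularDesignError(
            f"rank-deficient design: collinear column indices {bad.tolist()}"
        )
    coef = np.linalg.solve(R, Q.T @ y)
    resid = y - design @ coef
    df = n - p
    rss = float(resid @ resid)
    sigma2 = rss / df
    # (X'X)^-1 = R^-1 R^-T
    Rinv = np.linalg.solve(R, np.eye(p))
    xtx_inv_diag = np.einsum("ij,ij->i", Rinv, Rinv)
    tss = float(((y - y.mean()) ** 2).sum())
    degenerate = rss <= _RESID_RTOL * max(tss, 1.0)
    return coef, xtx_inv_diag, sigma2, df, degenerate


def fit_outcome_model(
    y1: np.ndarray,
    G1: np.ndarray,
    X1: Optional[np.ndarray] = None,
) -> IGFit:
    """OLS of the complete-set outcome on intercept, expression and covariates.

    Returns the coefficient estimates and the per-sample gene score
    ``G1 @ alphaG`` used as the second-stage response.
    """
    y1 = np.asarray(y1, dtype=float)
    G1 = np.asarray(G1, dtype=float)
    if G1.ndim == 1:
        G1 = G1[:, None]
    design = _as_design(G1, X1, len(y1))
    coef, *_ = _qr_ols(design, y1)
    d = G1.shape[1]
    alphaG = coef[1 : 1 + d]
    alphaX = coef[1 + d :]
    return IGFit(
        alpha0=float(coef[0]),
        alphaG=alphaG,
        alphaX=alphaX,
        gene_score=G1 @ alphaG,
    )


def _slope_test(
    response: np.ndarray,
    regressor: np.ndarray,
    X: Optional[np.ndarray],
) -> CpGStageResult:
    response = np.asarray(response, dtype=float)
    regressor = np.asarray(regressor, dtype=float)
    if np.ptp(regressor) == 0:
        raise DegenerateRegressorError("constant methylation column is not testable")
    design = _as_design(regressor, X, len(response))
    coef, xtx_inv_diag, sigma2, df, degenerate = _qr_ols(design, response)
    beta = float(coef[1])
    if degenerate:
        # Perfect fit: the t-statistic diverges; report the floor with a flag.
        return CpGStageResult(
            beta_M=beta,
            se=0.0,
            t_stat=np.inf if beta != 0 else 0.0,
            df=df,
            p_value=P_FLOOR,
            degenerate=True,
        )
    se = float(np.sqrt(sigma2 * xtx_inv_diag[1]))
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CpGStageResult(
        beta_M=beta, se=se, t_stat=t, df=df, p_value=max(p, P_FLOOR)
    )


def test_cpg_ig(
    gene_score: np.ndarray,
    mj1: np.ndarray,
    X1: Optional[np.ndarray] = None,
) -> CpGStageResult:
    """Second-stage test: regress the fitted gene score on one CpG (+ covariates).

    Two-sided p-value from t with n1 - r - 2 degrees of freedom.
    """
    return _slope_test(gene_score, mj1, X1)


def test_cpg_lm(
    y2: np.ndarray,
    mj2: np.ndarray,
    X2: Optional[np.ndarray] = None,
) -> CpGStageResult:
    """Marginal linear-model test of the outcome on one CpG (+ covariates)."""
    return _slope_test(y2, mj2, X2)


def _pvalue_loop(
    response: np.ndarray,
    M: np.ndarray,
    X: Optional[np.ndarray],
) -> tuple[np.ndarray, list[CpGStageResult | None]]:
    M = np.asarray(M, dtype=float)
    q = M.shape[1]
    pvals = np.full(q, np.nan)
    results: list[CpGStageResult | None] = [None] * q
    for j in range(q):
        try:
            res = _slope_test(response, M[:, j], X)
        except DegenerateRegressorError:
            continue  # flagged as NaN; do not abort the vector
        results[j] = res
        pvals[j] = res.p_value
    return pvals, results


def ig_pvalues(
    y1: np.ndarray,
    gene_block: np.ndarray,
    M1: np.ndarray,
    X1: Optional[np.ndarray] = None,
    fit: Optional[IGFit] = None,
) -> tuple[np.ndarray, list[CpGStageResult | None]]:
    """Complete-set integrative p-values for all q CpG columns.

    Fits the outcome model once on ``gene_block`` (raw expression or factor
    scores), then tests each CpG against the fitted gene score.  Per-CpG
    failures (constant columns) become NaN entries rather than aborting.
    """
    if fit is None:
        fit = fit_outcome_model(y1, gene_block, X1)
    return _pvalue_loop(fit.gene_score, M1, X1)


def lm_pvalues(
    y: np.ndarray,
    M: np.ndarray,
    X: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, list[CpGStageResult | None]]:
    """Marginal linear-model p-values for all q CpG columns on the given rows.

    Used on the incomplete set Z2 for the weighting schemes, and on all n
    samples for the all-subjects linear-model baseline.
    """
    return _pvalue_loop(np.asarray(y, dtype=float), M, X)
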