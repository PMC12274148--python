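"""SVD factor reduction for high-dimensional expression.

When the number of genes d approaches or exceeds the complete-set size n1, the
outcome model cannot be fit on raw expression.  Expression is assumed to follow
a factor model G_i = B f_i + U_i with k latent pathways f_i, cov(f) = I.  The
score matrix is estimated from the SVD of the column-standardized expression
matrix: F = sqrt(n1 - 1) * U_k, whose columns are orthogonal with unit sample
variance.  F replaces G in the two-stage model; the fitted gene score depends
only on the column space of F, so the scaling convention is immaterial to the
resulting p-values.

The rank k is chosen by Wold-style (speckled) tenfold cross-validation:
individual matrix entries are held out uniformly at random, a rank-k
reconstruction is fitted to the remaining entries by iterative SVD imputation,
and k minimizing the held-out squared error is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import DomainError
from .stage_models import CpGStageResult, ig_pvalues

__all__ = ["FactorReduction", "svd_factors", "select_k_cv", "ig_pvalues_highdim"]


@dataclass
class FactorReduction:
    """Latent-pathway scores and the rank-selection diagnostics."""

    scores: np.ndarray
    k: int
    singular_values: np.ndarray
    cv_curve: Optional[np.ndarray] = None


def svd_factors(G: np.ndarray, k: int) -> FactorReduction:
    """Top-k SVD scores of a column-standardized expression matrix.

    Returns F = sqrt(n1 - 1) * U_k.  Sign convention: each component is
    flipped so that the largest-magnitude gene loading is positive.
    """
    G = np.asarray(G, dtype=float)
    n1, d = G.shape
    if not 1 <= k <= min(n1, d):
        raise DomainError(f"k={k} outside [1, min(n1, d)={min(n1, d)}]")
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    return FactorReduction(
        scores=np.sqrt(n1 - 1) * U, k=k, singular_values=s
    )


def _rank_k_complete(
    G: np.ndarray,
    mask: np.ndarray,
    k: int,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Iterative-SVD completion: fill masked entries from a rank-k fit."""
    work = G.copy()
    observed = np.where(mask, 0.0, G)
    counts = (~mask).sum(axis=0)
    col_mean = observed.sum(axis=0) / np.maximum(counts, 1)
    work[mask] = np.broadcast_to(col_mean, G.shape)[mask]
    prev = work[mask]
    tall = G.shape[0] > G.shape[1]
    converged = False
    for _ in range(max_iter):
        # Rank-k truncation via the Gram matrix of the short side: the
        # projection U_k U_k' W equals the truncated SVD reconstruction.
        if tall:
            C = work.T @ work
            _, vecs = np.linalg.eigh(C)
            Vk = vecs[:, -k:]
            recon = (work @ Vk) @ Vk.T
        else:
            C = work @ work.T
            _, vecs = np.linalg.eigh(C)
            Uk = vecs[:, -k:]
            recon = Uk @ (Uk.T @ work)
        cur = recon[mask]
        work[mask] = cur
        denom = max(float(np.linalg.norm(prev)), 1e-12)
        if np.linalg.norm(cur - prev) / denom < tol:
            converged = True
            break
        prev = cur.copy()
    return work, converged


def select_k_cv(
    G: np.ndarray,
    k_max: int = 10,
    n_folds: int = 10,
    seed: Optional[int] = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[int, np.ndarray]:
    """Choose the factor rank by speckled-holdout cross-validated MSE.

    Entries of G are partitioned uniformly at random into ``n_folds`` masks.
    For every fold and candidate k, the held-out entries are treated as
    missing, completed by iterative rank-k SVD imputation, and scored by
    squared reconstruction error.  Returns (argmin k, cv_curve of mean squared
    errors for k = 1..k_max).
    """
    G = np.asarray(G, dtype=float)
    n1, d = G.shape
    if k_max > min(n1, d) - 1:
        raise DomainError(
            f"k_max={k_max} must be <= min(n1, d) - 1 = {min(n1, d) - 1}"
        )
    rng = np.random.default_rng(seed)
    fold_of = rng.integers(0, n_folds, size=G.shape)
    sse = np.zeros(k_max)
    n_held = np.zeros(k_max)
    n_unconverged = 0
    for fold in range(n_folds):
        mask = fold_of == fold
        if not mask.any():
            continue
        for k in range(1, k_max + 1):
            completed, converged = _rank_k_complete(G, mask, k, tol, max_iter)
            n_unconverged += not converged
            sse[k - 1] += float(((completed[mask] - G[mask]) ** 2).sum())
            n_held[k - 1] += int(mask.sum())
    if n_unconverged:
        warnings.warn(
            f"{n_unconverged} of {n_folds * k_max} completions did not reach "
            f"tolerance {tol} within {max_iter} iterations; using best-so-far",
            stacklevel=2,
        )
    cv_curve = sse / n_held
    return int(np.argmin(cv_curve) + 1), cv_curve


def ig_pvalues_highdim(
    y1: np.ndarray,
    G1: np.ndarray,
    M1: np.ndarray,
    X1: Optional[np.ndarray] = None,
    k: Optional[int] = None,
    k_max: int = 10,
    n_folds: int = 10,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, FactorReduction, list[CpGStageResult | None]]:
    """Integrative p-values with SVD factor scores in place of raw expression.

    When ``k`` is not given it is chosen by :func:`select_k_cv` on ``G1``.
    """
    G1 = np.asarray(G1, dtype=float)
    cv_curve = None
    if k is None:
        k, cv_curve = select_k_cv(G1, k_max=k_max, n_folds=n_folds, seed=seed)
    reduction = svd_factors(G1, k)
    reduction.cv_curve = cv_curve
    pvals, results = ig_pvalues(y1, reduction.scores, M1, X1)
    return pvals, reduction, results
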