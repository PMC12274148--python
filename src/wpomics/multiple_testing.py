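"""FWER and FDR control on (weight-adjusted) p-value vectors.

Because the weighting schemes divide the weights into the p-values up front,
family-wise error control reduces to plain Bonferroni applied to the adjusted
vector, and FDR control to Storey's q-value procedure.  With the null
proportion pinned at pi0 = 1, q-values coincide with Benjamini-Hochberg
adjusted p-values; the smoother estimate of pi0 is offered for genome-scale
vectors where it is stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .exceptions import DomainError

__all__ = ["DecisionSet", "bonferroni_reject", "storey_qvalues"]


@dataclass
class DecisionSet:
    """Rejection decisions at a nominal level, plus q-values in FDR mode."""

    alpha: float
    rejections: np.ndarray
    q_values: Optional[np.ndarray] = None
    pi0: Optional[float] = None


def _validate(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise DomainError("empty p-value vector")
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1] and be non-NaN")
    return p


def bonferroni_reject(p: np.ndarray, alpha: float = 0.05) -> DecisionSet:
    """Reject test j iff p_j <= alpha / q (Bonferroni on adjusted p-values)."""
    p = _validate(p)
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    return DecisionSet(alpha=alpha, rejections=p <= alpha / p.size)


def _pi0_smoother(p: np.ndarray) -> float:
    """Storey's smoother: spline pi0(lambda) over a lambda grid, read at 0.95."""
    m = p.size
    grid = np.arange(0.05, 0.96, 0.05)
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    spline = make_smoothing_spline(grid, pi0_lambda)
    pi0 = float(spline(grid[-1]))
    if pi0 <= 0.0:
        # Extremely signal-dense vector; fall back to the smallest positive
        # raw estimate so q-values stay defined.
        positive = pi0_lambda[pi0_lambda > 0]
        pi0 = float(positive.min()) if positive.size else 1.0 / m
    return min(pi0, 1.0)


def storey_qvalues(
    p: np.ndarray,
    pi0_mode: str = "auto",
    alpha: float = 0.05,
) -> DecisionSet:
    """Storey q-values with rejection at q <= alpha.

    ``pi0_mode`` is ``"fixed-1"`` (pi0 = 1, equivalent to Benjamini-Hochberg),
    ``"smoother"`` (Storey's spline estimate of the null proportion), or
    ``"auto"``: fixed-1 below 100 tests — where the smoother is unstable —
    and the smoother at genome scale.
    """
    p = _validate(p)
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    m = p.size
    if pi0_mode == "auto":
        pi0_mode = "fixed-1" if m < 100 else "smoother"
    if pi0_mode == "fixed-1":
        pi0 = 1.0
    elif pi0_mode == "smoother":
        pi0 = _pi0_smoother(p)
    else:
        raise DomainError(f"unknown pi0_mode {pi0_mode!r}")

    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * p[order] * m / ranks
    # Step-up accumulation: running minimum from the largest p downward.
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return DecisionSet(alpha=alpha, rejections=q <= alpha, q_values=q, pi0=pi0)
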