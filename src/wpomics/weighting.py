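"""Split-sample p-value weighting and the Cauchy-combination omnibus test.

The two halves of the sample split each yield a per-CpG p-value vector:
``p_IG`` from the complete set (two-stage integrative model) and ``p_LM`` from
the incomplete set (marginal linear model).  Because the sets are disjoint,
either vector can serve as an *independent* prior weight for the other:

* general scheme — weights built from ``p_LM`` adjust ``p_IG``:
  ``p1_j = p_IG_j / w*_Gj``;
* reverse scheme — weights built from ``p_IG`` adjust ``p_LM``:
  ``p2_j = p_LM_j / w*_Rj``.

A raw weight is ``sqrt(-log10 p)`` when ``p < 0.05`` and 1 otherwise; weights
are then divided by their mean so the normalized vector averages exactly 1,
which preserves type-I-error control on average.

The omnibus statistic mixes the two adjusted p-values through Cauchy tangent
transforms,

    T_j = (1 - lambda) * tan((0.5 - p1_j) * pi) + lambda * tan((0.5 - p2_j) * pi),

with the mixing weight lambda set to the expression missing proportion n2/n,
and converts back through the standard Cauchy upper tail
``p = 1/2 - arctan(T)/pi``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .stage_models import P_FLOOR, ig_pvalues, lm_pvalues

__all__ = [
    "WEIGHT_THRESHOLD",
    "WeightVector",
    "AdjustedPValues",
    "raw_weight",
    "normalize_weights",
    "adjust_pvalues",
    "general_scheme",
    "reverse_scheme",
    "acat_combine",
    "omnibus_pipeline",
]

#: p-value threshold below which a test contributes a weight > 1 (strict <).
WEIGHT_THRESHOLD: float = 0.05

# Below this, tan((0.5 - p) * pi) is replaced by 1/(p * pi): the float argument
# rounds onto pi/2 and the direct tangent loses all accuracy, while the
# stabilized form has relative error O(p).
_TAN_GUARD = 1e-15


@dataclass
class WeightVector:
    """Raw and mean-normalized weights over q tests."""

    raw: np.ndarray
    normalized: np.ndarray
    mean_raw: float


@dataclass
class AdjustedPValues:
    """Adjusted p-values from both schemes plus their omnibus combination."""

    p1: np.ndarray
    p2: np.ndarray
    p_omnibus: np.ndarray
    lambda_mix: float


def _validate_p(p: np.ndarray, name: str = "p") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise DomainError(f"{name} is empty")
    if np.any(p <= 0) or np.any(p > 1):
        raise DomainError(f"{name} must lie in (0, 1]")
    return p


def raw_weight(
    p: float | np.ndarray, threshold: float = WEIGHT_THRESHOLD
) -> float | np.ndarray:
    """Raw weight sqrt(-log10 p) for p below the threshold, else exactly 1.

    Inputs below the p-value floor are clipped up to the floor first.  Every
    raw weight is >= 1: p < 0.05 implies -log10 p > 1.3.
    """
    scalar = np.isscalar(p)
    arr = _validate_p(np.atleast_1d(np.asarray(p, dtype=float)))
    arr = np.maximum(arr, P_FLOOR)
    out = np.ones_like(arr)
    active = arr < threshold
    out[active] = np.sqrt(-np.log10(arr[active]))
    return float(out[0]) if scalar else out


def normalize_weights(raw: np.ndarray) -> WeightVector:
    """Divide weights by their mean so the normalized vector averages 1."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise DomainError("cannot normalize an empty weight vector")
    mean_raw = float(raw.mean())
    return WeightVector(raw=raw, normalized=raw / mean_raw, mean_raw=mean_raw)


def adjust_pvalues(p: np.ndarray, w_star: np.ndarray) -> np.ndarray:
    """Weighted adjustment p/w*, clipped into [floor, 1]."""
    p = np.asarray(p, dtype=float)
    w_star = np.asarray(w_star, dtype=float)
    if p.shape != w_star.shape:
        raise DomainError(
            f"length mismatch: {p.shape} p-values vs {w_star.shape} weights"
        )
    return np.clip(p / w_star, P_FLOOR, 1.0)


def general_scheme(
    p_ig: np.ndarray,
    p_lm: np.ndarray,
    threshold: float = WEIGHT_THRESHOLD,
) -> tuple[WeightVector, np.ndarray]:
    """Adjust the complete-set p-values with weights from the incomplete set."""
    p_ig = np.asarray(p_ig, dtype=float)
    p_lm = np.asarray(p_lm, dtype=float)
    if p_ig.shape != p_lm.shape:
        raise DomainError("p_ig and p_lm must have equal length")
    weights = normalize_weights(raw_weight(p_lm, threshold))
    return weights, adjust_pvalues(p_ig, weights.normalized)


def reverse_scheme(
    p_lm: np.ndarray,
    p_ig: np.ndarray,
    threshold: float = WEIGHT_THRESHOLD,
) -> tuple[WeightVector, np.ndarray]:
    """Adjust the incomplete-set p-values with weights from the complete set.

    Mirror image of :func:`general_scheme`; favored when the missing rate is
    high, because then the incomplete set carries most of the information.
    """
    return general_scheme(p_lm, p_ig, threshold)


def _cauchy_tan(p: np.ndarray) -> np.ndarray:
    out = np.empty_like(p)
    small = p < _TAN_GUARD
    out[~small] = np.tan((0.5 - p[~small]) * np.pi)
    out[small] = 1.0 / (p[small] * np.pi)
    return out


def acat_combine(
    p1: float | np.ndarray,
    p2: float | np.ndarray,
    lambda_mix: float,
) -> float | np.ndarray:
    """Cauchy-combination of two p-values with mixing weight lambda.

    Returns the standard-Cauchy upper-tail probability of the weighted sum of
    tangent transforms.  lambda = 0 returns p1, lambda = 1 returns p2 (the
    arctan-of-tan identity on (0, 1)).
    """
    if not 0.0 <= lambda_mix <= 1.0:
        raise DomainError(f"lambda must be in [0, 1], got {lambda_mix}")
    scalar = np.isscalar(p1) and np.isscalar(p2)
    a1 = _validate_p(np.atleast_1d(np.asarray(p1, dtype=float)), "p1")
    a2 = _validate_p(np.atleast_1d(np.asarray(p2, dtype=float)), "p2")
    T = (1.0 - lambda_mix) * _cauchy_tan(a1) + lambda_mix * _cauchy_tan(a2)
    with np.errstate(over="ignore", divide="ignore"):
        p = np.where(
            T > 1.0 / _TAN_GUARD,
            1.0 / (T * np.pi),  # upper-tail of a huge statistic, stabilized
            0.5 - np.arctan(T) / np.pi,
        )
    p = np.clip(p, P_FLOOR, 1.0)
    return float(p[0]) if scalar else p


def omnibus_pipeline(
    split,
    gene_block: Optional[np.ndarray] = None,
    lambda_override: Optional[float] = None,
    k: Optional[int] = None,
    k_max: int = 10,
    highdim_ratio: float = 0.5,
    seed: Optional[int] = None,
    threshold: float = WEIGHT_THRESHOLD,
) -> tuple[AdjustedPValues, pd.DataFrame]:
    """End-to-end per-CpG analysis of a split dataset.

    Computes p_IG on Z1 (through SVD factor reduction when the expression
    dimension is high relative to n1, i.e. d >= highdim_ratio * n1, or when
    ``k`` is given), p_LM on Z2, both weighting schemes, and the per-CpG
    omnibus combination with lambda equal to the missing rate (overridable).

    Returns the adjusted p-values and a per-CpG results table with columns
    cpg_id, p_ig, p_lm, w_general, w_reverse, p1, p2, p_omnibus.
    """
    from .factor_reduction import ig_pvalues_highdim  # local: avoid cycle

    z1, z2 = split.z1, split.z2
    lam = split.missing_rate if lambda_override is None else float(lambda_override)
    if not 0.0 <= lam <= 1.0:
        raise DomainError(f"lambda must be in [0, 1], got {lam}")

    cpg_ids = list(split.data.M.columns)
    y1 = z1.y.to_numpy(dtype=float)
    M1 = z1.M.to_numpy(dtype=float)
    X1 = None if z1.X is None else z1.X.to_numpy(dtype=float)

    if gene_block is not None:
        p_ig, _ = ig_pvalues(y1, np.asarray(gene_block, dtype=float), M1, X1)
    else:
        G1 = z1.G.to_numpy(dtype=float)
        if k is not None or G1.shape[1] >= highdim_ratio * G1.shape[0]:
            p_ig, _ = ig_pvalues_highdim(
                y1, G1, M1, X1, k=k, k_max=k_max, seed=seed
            )[:2]
        else:
            p_ig, _ = ig_pvalues(y1, G1, M1, X1)

    if z2.n2 > 0:
        y2 = z2.y.to_numpy(dtype=float)
        M2 = z2.M.to_numpy(dtype=float)
        X2 = None if z2.X is None else z2.X.to_numpy(dtype=float)
        p_lm, _ = lm_pvalues(y2, M2, X2)
    else:
        p_lm = None

    q = len(cpg_ids)
    if p_lm is None:
        warnings.warn(
            "incomplete set is empty: omnibus p-values degenerate to the "
            "complete-set p-values (lambda = 0)",
            stacklevel=2,
        )
        unit = WeightVector(np.ones(q), np.ones(q), 1.0)
        adjusted = AdjustedPValues(
            p1=p_ig.copy(), p2=np.full(q, np.nan), p_omnibus=p_ig.copy(),
            lambda_mix=0.0,
        )
        w_g, w_r = unit, unit
        p_lm = np.full(q, np.nan)
    elif z1.n1 == 0:
        warnings.warn(
            "complete set is empty: omnibus p-values degenerate to the "
            "incomplete-set p-values (lambda = 1)",
            stacklevel=2,
        )
        unit = WeightVector(np.ones(q), np.ones(q), 1.0)
        adjusted = AdjustedPValues(
            p1=np.full(q, np.nan), p2=p_lm.copy(), p_omnibus=p_lm.copy(),
            lambda_mix=1.0,
        )
        w_g, w_r = unit, unit
        p_ig = np.full(q, np.nan)
    else:
        w_g, p1 = general_scheme(p_ig, p_lm, threshold)
        w_r, p2 = reverse_scheme(p_lm, p_ig, threshold)
        p_omni = acat_combine(p1, p2, lam)
        adjusted = AdjustedPValues(p1=p1, p2=p2, p_omnibus=p_omni, lambda_mix=lam)

    table = pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "p_ig": p_ig,
            "p_lm": p_lm,
            "w_general": w_g.normalized,
            "w_reverse": w_r.normalized,
            "p1": adjusted.p1,
            "p2": adjusted.p2,
            "p_omnibus": adjusted.p_omnibus,
        }
    )
    return adjusted, table
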