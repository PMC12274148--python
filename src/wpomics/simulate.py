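"""Synthetic-data generators for the methylation -> expression -> phenotype
cascade, with block-missing expression.

Two regimes are covered:

* **Low-dimensional** (d = 8 genes): methylation M (n x q) and covariates X
  (n x r) are i.i.d. standard normal; the first CpG is causal.  Three causal
  genes follow

      G_i = gamma_0G + M_i1 * gamma_MG + X_i' gamma_XG + eps,   eps ~ N(0, I),

  the remaining d - 3 genes are i.i.d. N(mu_0G, 1) noise, and the outcome is

      Y_i = gamma_0Y + G_i(causal)' gamma_GY + X_i' gamma_XY + eps2.

* **High-dimensional** (d = 1000 genes): k latent pathway scores follow the
  same linear model as the causal genes above, the outcome loads on the
  pathways, and expression arises from a factor model G_i = B f_i + U_i with
  loading matrix B = (1/sqrt(n)) L' E, where L is an n x d standard-normal
  matrix and E holds the eigenvectors of L L' for its k largest eigenvalues.

Association strengths are heterogeneous across causal genes (or pathways):
each element of gamma_MG and gamma_GY is drawn i.i.d. N(mean, coef_sd^2)
afresh per replicate, with coef_sd = 1 by default.  A zero mean denotes the
absence of the association and yields an exactly zero vector, so null
scenarios remain null; coef_sd = 0 gives the deterministic equal-elements
variant.  Covariate effects gamma_XG, gamma_XY are fixed at 0.5.

Missingness is sample-level and completely at random: round(lambda * n)
samples, drawn without replacement, lose their entire expression row.

Intercepts default to 0: they are absorbed by every downstream model fit and
have no effect on any p-value, so the operating characteristics do not depend
on them (overrides are available in the config).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    OmicsMatrixSet,
    SplitOmicsDataset,
    split_dataset,
    standardize_expression,
)
from .exceptions import DomainError, InsufficientSamplesError

__all__ = [
    "SimulationConfig",
    "generate_lowdim",
    "generate_highdim",
    "apply_missingness",
]


@dataclass
class SimulationConfig:
    """Parameters of the generating cascade.

    Defaults are the study conditions of the evaluation harness: n = 150
    samples, q = 5 CpG sites, r = 2 covariates, 3 causal genes among d = 8
    (low-dimensional) or k = 5 latent pathways with d = 1000 genes
    (high-dimensional), covariate effects of 0.5 throughout.
    """

    n: int = 150
    q: int = 5
    d: int = 8
    r: int = 2
    gamma_MG: float = 0.0
    gamma_GY: float = 0.0
    coef_sd: float = 1.0
    gamma_XG: float = 0.5
    gamma_XY: float = 0.5
    gamma_0G: float = 0.0
    gamma_0Y: float = 0.0
    mu_0G: float = 0.0
    k: int = 5
    n_causal_genes: int = 3
    causal_cpgs: Sequence[int] = (0,)
    missing_rate: float = 0.7
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("n", "q", "d", "r", "k", "n_causal_genes"):
            if getattr(self, name) < 0 or (name in ("n", "q", "d") and getattr(self, name) == 0):
                raise DomainError(f"dimension {name} must be positive")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise DomainError("missing_rate must be in [0, 1]")
        if self.coef_sd < 0:
            raise DomainError("coef_sd must be nonnegative")
        if self.n_causal_genes > self.d:
            raise DomainError("n_causal_genes cannot exceed d")
        if any(j < 0 or j >= self.q for j in self.causal_cpgs):
            raise DomainError("causal_cpgs indices must lie in [0, q)")

    def to_dict(self) -> dict:
        out = asdict(self)
        out["causal_cpgs"] = list(self.causal_cpgs)
        return out


def _base_frames(config: SimulationConfig, rng: np.random.Generator):
    ids = pd.Index([f"s{i:04d}" for i in range(config.n)], name="sample_id")
    M = pd.DataFrame(
        rng.standard_normal((config.n, config.q)),
        index=ids,
        columns=[f"cg{j + 1:03d}" for j in range(config.q)],
    )
    X = None
    if config.r > 0:
        X = pd.DataFrame(
            rng.standard_normal((config.n, config.r)),
            index=ids,
            columns=[f"x{j + 1}" for j in range(config.r)],
        )
    return ids, M, X


def _coef_vector(
    mean: float, sd: float, width: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-replicate coefficient vector: i.i.d. N(mean, sd^2) elements.

    A zero mean denotes the absence of the association and returns an exactly
    zero vector, so null scenarios stay null; ``sd = 0`` gives the
    deterministic equal-elements variant.
    """
    if mean == 0.0:
        return np.zeros(width)
    if sd == 0.0:
        return np.full(width, mean)
    return rng.normal(mean, sd, size=width)


def _causal_methylation(config: SimulationConfig, M: pd.DataFrame) -> np.ndarray:
    return M.to_numpy()[:, list(config.causal_cpgs)].sum(axis=1)


def generate_lowdim(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[OmicsMatrixSet, dict]:
    """Low-dimensional generator; returns the dataset and a truth record."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ids, M, X = _base_frames(config, rng)
    n, d, nc = config.n, config.d, config.n_causal_genes

    gamma_mg = _coef_vector(config.gamma_MG, config.coef_sd, nc, rng)
    gamma_gy = _coef_vector(config.gamma_GY, config.coef_sd, nc, rng)
    m_causal = _causal_methylation(config, M)
    x_term = 0.0 if X is None else config.gamma_XG * X.to_numpy().sum(axis=1)
    G = np.empty((n, d))
    G[:, :nc] = (
        config.gamma_0G
        + np.outer(m_causal, gamma_mg)
        + np.asarray(x_term)[:, None]
        + rng.standard_normal((n, nc))
    )
    G[:, nc:] = config.mu_0G + rng.standard_normal((n, d - nc))

    y_x = 0.0 if X is None else config.gamma_XY * X.to_numpy().sum(axis=1)
    y = (
        config.gamma_0Y
        + G[:, :nc] @ gamma_gy
        + np.asarray(y_x)
        + rng.standard_normal(n)
    )

    G_frame = pd.DataFrame(
        G, index=ids, columns=[f"g{j + 1:04d}" for j in range(d)]
    )
    data = OmicsMatrixSet(
        y=pd.Series(y, index=ids, name="Y"), M=M, G=G_frame, X=X
    )
    truth = {
        "causal_cpgs": list(config.causal_cpgs),
        "causal_genes": list(range(nc)),
        "gamma_MG": gamma_mg.tolist(),
        "gamma_GY": gamma_gy.tolist(),
        "config": config.to_dict(),
    }
    return data, truth


def generate_highdim(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[OmicsMatrixSet, dict]:
    """High-dimensional factor-model generator; returns dataset and truth.

    The truth record carries the latent score matrix ``f`` (n x k) so tests
    can compare recovered factors against it.
    """
    if config.k < 1:
        raise DomainError("k must be >= 1 in the high-dimensional generator")
    if config.k > config.n:
        raise DomainError("k cannot exceed n")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ids, M, X = _base_frames(config, rng)
    n, d, k = config.n, config.d, config.k

    gamma_mg = _coef_vector(config.gamma_MG, config.coef_sd, k, rng)
    gamma_gy = _coef_vector(config.gamma_GY, config.coef_sd, k, rng)
    m_causal = _causal_methylation(config, M)
    x_term = 0.0 if X is None else config.gamma_XG * X.to_numpy().sum(axis=1)
    f = (
        np.outer(m_causal, gamma_mg)
        + np.asarray(x_term)[:, None]
        + rng.standard_normal((n, k))
    )

    y_x = 0.0 if X is None else config.gamma_XY * X.to_numpy().sum(axis=1)
    y = (
        config.gamma_0Y
        + f @ gamma_gy
        + np.asarray(y_x)
        + rng.standard_normal(n)
    )

    L = rng.standard_normal((n, d))
    eigvals, eigvecs = np.linalg.eigh(L @ L.T)
    E = eigvecs[:, ::-1][:, :k]  # eigenvectors of the k largest eigenvalues
    B = (L.T @ E) / np.sqrt(n)  # d x k loading matrix
    G = f @ B.T + rng.standard_normal((n, d))

    G_frame = pd.DataFrame(
        G, index=ids, columns=[f"g{j + 1:04d}" for j in range(d)]
    )
    data = OmicsMatrixSet(
        y=pd.Series(y, index=ids, name="Y"), M=M, G=G_frame, X=X
    )
    truth = {
        "causal_cpgs": list(config.causal_cpgs),
        "k": k,
        "factors": f,
        "loadings": B,
        "gamma_MG": gamma_mg.tolist(),
        "gamma_GY": gamma_gy.tolist(),
        "config": config.to_dict(),
    }
    return data, truth


def apply_missingness(
    data: OmicsMatrixSet,
    missing_rate: float,
    seed: Optional[int | np.random.Generator] = None,
    standardize: bool = True,
    d_effective: Optional[int] = None,
) -> SplitOmicsDataset:
    """Remove round(lambda * n) whole expression rows at random and split.

    The retained expression block is column-standardized over the complete
    set (the convention the analysis assumes for real data), unless
    ``standardize=False``.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise DomainError("missing_rate must be in [0, 1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = data.n
    n2 = int(round(missing_rate * n))
    if n - n2 < 2:
        raise InsufficientSamplesError(
            f"missing rate {missing_rate} leaves only {n - n2} complete samples"
        )
    drop = rng.choice(n, size=n2, replace=False)
    keep_mask = np.ones(n, dtype=bool)
    keep_mask[drop] = False
    kept_ids = data.sample_ids[keep_mask]
    G = data.G.loc[kept_ids]
    if standardize:
        G = standardize_expression(G)
    trimmed = OmicsMatrixSet(y=data.y, M=data.M, G=G, X=data.X)
    return split_dataset(trimmed, d_effective=d_effective)
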