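"""Monte Carlo harness: type-I-error, FDR and power estimation for the
weighting schemes and the in-scope baselines.

Three study designs are covered:

* Scenario 1 — global null (gamma_MG = gamma_GY = 0, low-dimensional):
  empirical FWER under weighted Bonferroni and empirical FDR (mean false
  discovery proportion) under the q-value rule, per method and missing rate.
* Scenario 2 — low-dimensional power grid over the methylation-gene and
  gene-phenotype effect sizes and the missing rate.
* Scenario 3 — high-dimensional power (factor-model expression, SVD
  reduction with cross-validated or cached rank k).

Methods compared: the two weighting schemes ("general", "reverse"), their
omnibus combination ("omnibus"), the complete-case integrative model
("ig_complete"), the all-subjects marginal linear model ("linear_all") and,
optionally, subject-space 10-nearest-neighbour imputation followed by the
integrative model ("knn_impute").

Within a replicate every method sees the same generated dataset and the same
missingness draw (paired comparison).  Per-replicate random streams are
spawned from the master seed, so every report is a pure function of
(config, n_iter, seed).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import OmicsMatrixSet, SplitOmicsDataset, standardize_expression
from .exceptions import DomainError
from .factor_reduction import select_k_cv, svd_factors
from .multiple_testing import bonferroni_reject, storey_qvalues
from .simulate import (
    SimulationConfig,
    apply_missingness,
    generate_highdim,
    generate_lowdim,
)
from .stage_models import ig_pvalues, lm_pvalues
from .weighting import acat_combine, general_scheme, reverse_scheme

__all__ = [
    "METHODS",
    "compute_fdp_fwer",
    "knn_impute_baseline",
    "run_scenario1",
    "run_scenario2",
    "run_scenario3",
]

METHODS = ("general", "reverse", "omnibus", "ig_complete", "linear_all")
OPTIONAL_METHODS = ("knn_impute",)


def compute_fdp_fwer(
    rejections: np.ndarray, truth: Iterable[int]
) -> tuple[bool, float, bool]:
    """Per-replicate tallies from a rejection vector and the causal index set.

    Returns (any_false_rejection, false_discovery_proportion, causal_detected)
    with FDP = |rejected & null| / max(|rejected|, 1).
    """
    rejections = np.asarray(rejections, dtype=bool)
    truth_set = set(truth)
    rejected = np.flatnonzero(rejections)
    false = [j for j in rejected if j not in truth_set]
    fdp = len(false) / max(len(rejected), 1)
    detected = any(j in truth_set for j in rejected)
    return bool(false), fdp, detected


def knn_impute_baseline(
    split: SplitOmicsDataset, k_neighbors: int = 10
) -> OmicsMatrixSet:
    """Complete the expression matrix by subject-space k-NN mean imputation.

    Each sample with a missing expression profile receives the mean expression
    row of its ``k_neighbors`` nearest complete samples, by Euclidean distance
    on the shared features (M, X, Y).
    """
    z1, z2 = split.z1, split.z2
    if z2.n2 == 0:
        raise DomainError("nothing to impute: incomplete set is empty")
    if k_neighbors > z1.n1:
        warnings.warn(
            f"k_neighbors={k_neighbors} exceeds the {z1.n1} complete samples; "
            "clipping",
            stacklevel=2,
        )
        k_neighbors = z1.n1

    def features(M, X, y):
        parts = [M.to_numpy(dtype=float)]
        if X is not None:
            parts.append(X.to_numpy(dtype=float))
        parts.append(y.to_numpy(dtype=float)[:, None])
        return np.hstack(parts)

    F1 = features(z1.M, z1.X, z1.y)
    F2 = features(z2.M, z2.X, z2.y)
    G1 = z1.G.to_numpy(dtype=float)
    d2 = ((F2[:, None, :] - F1[None, :, :]) ** 2).sum(axis=2)
    imputed = np.empty((z2.n2, G1.shape[1]))
    for i in range(z2.n2):
        nearest = np.argsort(d2[i], kind="stable")[:k_neighbors]
        imputed[i] = G1[nearest].mean(axis=0)
    G_full = pd.concat(
        [z1.G, pd.DataFrame(imputed, index=z2.y.index, columns=z1.G.columns)]
    )
    data = split.data
    G_full = G_full.loc[[s for s in data.sample_ids]]
    return OmicsMatrixSet(y=data.y, M=data.M, G=G_full, X=data.X)


def _arrays(split: SplitOmicsDataset):
    z1, z2 = split.z1, split.z2
    X1 = None if z1.X is None else z1.X.to_numpy(dtype=float)
    X2 = None if z2.X is None else z2.X.to_numpy(dtype=float)
    return (
        z1.y.to_numpy(dtype=float),
        z1.G.to_numpy(dtype=float),
        z1.M.to_numpy(dtype=float),
        X1,
        z2.y.to_numpy(dtype=float),
        z2.M.to_numpy(dtype=float),
        X2,
    )


def _replicate_pvalues(
    split: SplitOmicsDataset,
    methods: Sequence[str],
    k: Optional[int] = None,
    k_neighbors: int = 10,
) -> dict[str, np.ndarray]:
    """One replicate's per-CpG p-value vector for each requested method."""
    y1, G1, M1, X1, y2, M2, X2 = _arrays(split)
    gene_block = G1 if k is None else svd_factors(G1, k).scores
    p_ig, _ = ig_pvalues(y1, gene_block, M1, X1)
    p_lm, _ = lm_pvalues(y2, M2, X2)

    out: dict[str, np.ndarray] = {}
    if "ig_complete" in methods:
        out["ig_complete"] = p_ig
    if {"general", "omnibus"} & set(methods):
        _, p1 = general_scheme(p_ig, p_lm)
    if {"reverse", "omnibus"} & set(methods):
        _, p2 = reverse_scheme(p_lm, p_ig)
    if "general" in methods:
        out["general"] = p1
    if "reverse" in methods:
        out["reverse"] = p2
    if "omnibus" in methods:
        out["omnibus"] = acat_combine(p1, p2, split.missing_rate)
    if "linear_all" in methods:
        data = split.data
        Xall = None if data.X is None else data.X.to_numpy(dtype=float)
        out["linear_all"], _ = lm_pvalues(
            data.y.to_numpy(dtype=float), data.M.to_numpy(dtype=float), Xall
        )
    if "knn_impute" in methods:
        completed = knn_impute_baseline(split, k_neighbors)
        G_std = standardize_expression(completed.G).to_numpy(dtype=float)
        Xall = None if completed.X is None else completed.X.to_numpy(dtype=float)
        gene = G_std if k is None else svd_factors(G_std, k).scores
        out["knn_impute"], _ = ig_pvalues(
            completed.y.to_numpy(dtype=float),
            gene,
            completed.M.to_numpy(dtype=float),
            Xall,
        )
    return out


def _check_methods(methods: Sequence[str]) -> None:
    known = set(METHODS) | set(OPTIONAL_METHODS)
    unknown = [m for m in methods if m not in known]
    if unknown:
        raise DomainError(f"unknown method(s) {unknown}; choose from {sorted(known)}")


def _replicate_rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based per-replicate stream: same data for all methods."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def run_scenario1(
    config: Optional[SimulationConfig] = None,
    n_iter: int = 1000,
    methods: Sequence[str] = METHODS,
    missing_rates: Sequence[float] = (0.2, 0.5, 0.7),
    seed: int = 0,
    alpha: float = 0.05,
    pi0_mode: str = "auto",
) -> pd.DataFrame:
    """Global-null replication study: empirical FWER and FDR per method.

    Per replicate: generate the low-dimensional null dataset, remove a random
    expression block, compute each method's q p-values, then apply weighted
    Bonferroni (FWER tally: any rejection) and the q-value rule (FDR tally:
    false discovery proportion V / max(R, 1)).
    """
    if n_iter <= 0:
        raise DomainError("n_iter must be positive")
    _check_methods(methods)
    config = config or SimulationConfig()
    if config.gamma_MG != 0 or config.gamma_GY != 0:
        raise DomainError("the null scenario requires gamma_MG = gamma_GY = 0")

    rows = []
    for mi, lam in enumerate(missing_rates):
        any_fwer = {m: 0 for m in methods}
        fdp_sum = {m: 0.0 for m in methods}
        for it in range(n_iter):
            # data stream is independent of the missing rate: baselines that
            # ignore G see literally identical replicates across rates
            data, truth = generate_lowdim(config, _replicate_rng(seed, 0, it))
            split = apply_missingness(data, lam, _replicate_rng(seed, 1 + mi, it))
            pvals = _replicate_pvalues(split, methods)
            for m, p in pvals.items():
                rej_fwer = bonferroni_reject(p, alpha).rejections
                any_false, _, _ = compute_fdp_fwer(rej_fwer, truth["causal_cpgs"])
                # under the global null every CpG is null
                any_fwer[m] += int(rej_fwer.any())
                rej_fdr = storey_qvalues(p, pi0_mode, alpha).rejections
                _, fdp, _ = compute_fdp_fwer(rej_fdr, set())
                fdp_sum[m] += fdp
        for m in methods:
            fwer = any_fwer[m] / n_iter
            fdr = fdp_sum[m] / n_iter
            rows.append(
                {
                    "method": m,
                    "missing_rate": lam,
                    "fwer_hat": fwer,
                    "fdr_hat": fdr,
                    "fwer_se": float(np.sqrt(fwer * (1 - fwer) / n_iter)),
                    "fdr_se": float(np.sqrt(fdr * (1 - fdr) / n_iter)),
                    "n_iter": n_iter,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def _power_cell(
    config: SimulationConfig,
    n_iter: int,
    methods: Sequence[str],
    lam: float,
    seed: int,
    data_key: tuple[int, ...],
    miss_key: tuple[int, ...],
    alpha: float,
    rule: str,
    highdim: bool,
    k: Optional[int],
) -> dict[str, float]:
    detect = {m: 0 for m in methods}
    for it in range(n_iter):
        rng = _replicate_rng(seed, *data_key, it)
        if highdim:
            data, truth = generate_highdim(config, rng)
        else:
            data, truth = generate_lowdim(config, rng)
        split = apply_missingness(data, lam, _replicate_rng(seed, 99, *miss_key, it))
        rep_k = k
        if highdim and rep_k is None:
            rep_k, _ = select_k_cv(
                split.z1.G.to_numpy(dtype=float),
                seed=int(rng.integers(2**31)),
            )
        pvals = _replicate_pvalues(split, methods, k=rep_k)
        causal = set(truth["causal_cpgs"])
        for m, p in pvals.items():
            if rule == "bonferroni":
                rej = bonferroni_reject(p, alpha).rejections
            elif rule == "per_test":
                rej = np.asarray(p) <= alpha
            else:
                raise DomainError(f"unknown decision rule {rule!r}")
            _, _, detected = compute_fdp_fwer(rej, causal)
            detect[m] += int(detected)
    return {m: detect[m] / n_iter for m in methods}


def run_scenario2(
    gamma_mg_grid: Sequence[float] = (0.0, 0.1, 0.2, 0.5),
    gamma_gy_grid: Sequence[float] = (0.1, 0.2),
    missing_rates: Sequence[float] = (0.2, 0.5, 0.7),
    n_iter: int = 1000,
    methods: Sequence[str] = METHODS,
    seed: int = 0,
    alpha: float = 0.05,
    rule: str = "bonferroni",
    base_config: Optional[SimulationConfig] = None,
) -> pd.DataFrame:
    """Low-dimensional power grid: detection rate of the causal CpG.

    Power is the fraction of replicates in which the causal CpG is rejected;
    the default decision rule is weighted Bonferroni at ``alpha`` over the q
    tests (``rule="per_test"`` switches to an unadjusted per-test threshold).
    """
    if n_iter <= 0:
        raise DomainError("n_iter must be positive")
    if not len(gamma_mg_grid) or not len(gamma_gy_grid):
        raise DomainError("empty effect-size grid")
    _check_methods(methods)
    base = base_config or SimulationConfig()
    rows = []
    for ai, mg in enumerate(gamma_mg_grid):
        for bi, gy in enumerate(gamma_gy_grid):
            for ci, lam in enumerate(missing_rates):
                cfg = SimulationConfig(
                    **{**base.to_dict(), "gamma_MG": mg, "gamma_GY": gy}
                )
                power = _power_cell(
                    cfg, n_iter, methods, lam, seed,
                    (1, ai, bi), (2, ci), alpha, rule, highdim=False, k=None,
                )
                for m in methods:
                    est = power[m]
                    rows.append(
                        {
                            "method": m,
                            "missing_rate": lam,
                            "gamma_MG": mg,
                            "gamma_GY": gy,
                            "estimate": est,
                            "mc_se": float(np.sqrt(est * (1 - est) / n_iter)),
                            "n_iter": n_iter,
                            "seed": seed,
                        }
                    )
    return pd.DataFrame(rows)


def run_scenario3(
    gamma_mg_grid: Sequence[float] = (0.0, 0.1, 0.2, 0.5),
    gamma_gy_grid: Sequence[float] = (0.1, 0.2),
    missing_rate: float = 0.7,
    n_iter: int = 200,
    methods: Sequence[str] = ("omnibus", "ig_complete", "linear_all"),
    seed: int = 0,
    alpha: float = 0.05,
    rule: str = "bonferroni",
    k: Optional[int] = None,
    k_max: int = 10,
    reselect_k: bool = False,
    base_config: Optional[SimulationConfig] = None,
) -> pd.DataFrame:
    """High-dimensional power study with SVD factor reduction.

    The factor rank defaults to a cross-validated choice on one pilot
    replicate per cell, then is cached for the remaining replicates
    (``reselect_k=True`` re-runs the cross-validation inside every
    replicate; ``k`` fixes the rank outright).
    """
    if n_iter <= 0:
        raise DomainError("n_iter must be positive")
    _check_methods(methods)
    base = base_config or SimulationConfig(d=1000, k=5)
    rows = []
    for ai, mg in enumerate(gamma_mg_grid):
        for bi, gy in enumerate(gamma_gy_grid):
            cfg = SimulationConfig(
                **{**base.to_dict(), "gamma_MG": mg, "gamma_GY": gy}
            )
            cell_k = k
            if cell_k is None and not reselect_k:
                rng = _replicate_rng(seed, 3, ai, bi)
                data, _ = generate_highdim(cfg, rng)
                split = apply_missingness(data, missing_rate, rng)
                cell_k, _ = select_k_cv(
                    split.z1.G.to_numpy(dtype=float),
                    k_max=k_max,
                    seed=int(rng.integers(2**31)),
                )
            power = _power_cell(
                cfg, n_iter, methods, missing_rate, seed,
                (3, ai, bi), (3, ai, bi), alpha, rule, highdim=True, k=cell_k,
            )
            for m in methods:
                est = power[m]
                rows.append(
                    {
                        "method": m,
                        "missing_rate": missing_rate,
                        "gamma_MG": mg,
                        "gamma_GY": gy,
                        "k": cell_k,
                        "estimate": est,
                        "mc_se": float(np.sqrt(est * (1 - est) / n_iter)),
                        "n_iter": n_iter,
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)
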