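import numpy as np
import pytest
from scipy import stats

from wpomics import (
    SimulationConfig,
    apply_missingness,
    generate_highdim,
    generate_lowdim,
)
from wpomics.exceptions import DomainError, InsufficientSamplesError


def test_lowdim_shapes_and_seed_reproducibility():
    cfg = SimulationConfig(seed=1)
    a, truth = generate_lowdim(cfg)
    b, _ = generate_lowdim(cfg)
    assert (a.n, a.q, a.d, a.r) == (150, 5, 8, 2)
    assert truth["causal_cpgs"] == [0] and truth["causal_genes"] == [0, 1, 2]
    for attr in ("y", "M", "G", "X"):
        assert np.array_equal(
            np.asarray(getattr(a, attr), dtype=float),
            np.asarray(getattr(b, attr), dtype=float),
        )


def test_missingness_counts_and_determinism():
    data, _ = generate_lowdim(SimulationConfig(seed=2))
    s1 = apply_missingness(data, 0.7, 5)
    assert (s1.n1, s1.n2) == (45, 105)
    assert s1.missing_rate == pytest.approx(0.7)
    s2 = apply_missingness(data, 0.7, 5)
    assert list(s1.z1.y.index) == list(s2.z1.y.index)
    s0 = apply_missingness(data, 0.0, 5)
    assert s0.z2.n2 == 0
    with pytest.raises(InsufficientSamplesError):
        apply_missingness(data, 0.995, 5)


def test_marginal_moments():
    data, _ = generate_lowdim(SimulationConfig(n=5000, seed=3))
    M = data.M.to_numpy()
    X = data.X.to_numpy()
    for arr in (M, X):
        assert np.all(np.abs(arr.mean(0)) < 0.05)
        assert np.all(np.abs(arr.var(0) - 1) < 0.07)


def test_null_generator_uncorrelated():
    rng = np.random.default_rng(4)
    corrs = []
    for i in range(300):
        data, _ = generate_lowdim(SimulationConfig(n=80, seed=None), rng)
        corrs.append(np.corrcoef(data.M.iloc[:, 0], data.y)[0, 1])
    assert abs(np.mean(corrs)) < 0.015


def test_causal_gene_correlation_exceeds_null_genes():
    rng = np.random.default_rng(5)
    causal, null = [], []
    for _ in range(200):
        data, _ = generate_lowdim(
            SimulationConfig(n=150, gamma_MG=0.5, coef_sd=0.0, seed=None), rng
        )
        m1 = data.M.iloc[:, 0]
        causal.append(np.corrcoef(m1, data.G.iloc[:, 0])[0, 1])
        null.append(np.corrcoef(m1, data.G.iloc[:, -1])[0, 1])
    assert np.mean(causal) > 0.25 > abs(np.mean(null))


def test_outcome_variance_decomposition():
    """Var(Y) = nc^2*gGY^2*Var(sum causal G | shared M1) + r*gXY^2 + 1 ...
    checked empirically against the analytic total at one parameter point."""
    cfg = SimulationConfig(n=20000, gamma_MG=0.5, gamma_GY=0.2, coef_sd=0.0, seed=6)
    data, _ = generate_lowdim(cfg)
    # sum of 3 causal genes: 3*0.5*M1 + 3*0.5*(X1+X2) + sum eps -> plus Y noise
    g, gm, gx, gy, xy, r, nc = (
        cfg.gamma_GY, cfg.gamma_MG, cfg.gamma_XG, cfg.gamma_GY, cfg.gamma_XY,
        cfg.r, cfg.n_causal_genes,
    )
    var_sum_g = (nc * gm) ** 2 + r * (nc * gx) ** 2 + nc
    expected = g**2 * var_sum_g + 2 * g * nc * gx * xy * r + r * xy**2 + 1
    assert data.y.var() == pytest.approx(expected, rel=0.05)


def test_missingness_is_mcar():
    """Outcome distribution identical across complete/incomplete sets."""
    rng = np.random.default_rng(7)
    y1_all, y2_all = [], []
    for _ in range(100):
        data, _ = generate_lowdim(SimulationConfig(n=100, seed=None), rng)
        split = apply_missingness(data, 0.5, rng)
        y1_all.append(split.z1.y.to_numpy())
        y2_all.append(split.z2.y.to_numpy())
    ks = stats.ks_2samp(np.concatenate(y1_all), np.concatenate(y2_all))
    assert ks.pvalue > 0.001


def test_highdim_shapes_and_structure():
    cfg = SimulationConfig(d=1000, k=5, seed=8)
    data, truth = generate_highdim(cfg)
    assert data.G.shape == (150, 1000)
    assert truth["k"] == 5 and truth["factors"].shape == (150, 5)
    # loadings derive from orthonormal eigenvectors: column Gram near-diagonal
    B = truth["loadings"]
    gram = B.T @ B
    off = gram - np.diag(np.diag(gram))
    assert np.all(np.abs(off) < np.diag(gram).min() * 0.05)
    assert np.isfinite(B).all()


def test_highdim_null_ig_pvalue_uniform():
    """With no methylation effect the factor scores are independent of M1."""
    from wpomics import ig_pvalues, svd_factors
    from wpomics.datamodel import standardize_expression

    rng = np.random.default_rng(9)
    pvals = []
    for _ in range(200):
        data, _ = generate_highdim(
            SimulationConfig(n=60, d=200, k=3, seed=None), rng
        )
        split = apply_missingness(data, 0.5, rng)
        z1 = split.z1
        scores = svd_factors(z1.G.to_numpy(), 3).scores
        p, _ = ig_pvalues(z1.y.to_numpy(), scores, z1.M.to_numpy(), z1.X.to_numpy())
        pvals.append(p[0])
    assert stats.kstest(pvals, "uniform").pvalue > 0.001


def test_config_validation():
    with pytest.raises(DomainError):
        SimulationConfig(missing_rate=1.2)
    with pytest.raises(DomainError):
        SimulationConfig(coef_sd=-1.0)
    with pytest.raises(DomainError):
        SimulationConfig(n_causal_genes=9, d=8)
    with pytest.raises(DomainError):
        SimulationConfig(causal_cpgs=(7,), q=5)
    with pytest.raises(DomainError):
        generate_highdim(SimulationConfig(k=200, n=150))


def test_multi_causal_cpg_variant():
    data, truth = generate_lowdim(
        SimulationConfig(causal_cpgs=(0, 2), gamma_MG=0.4, coef_sd=0.0, seed=10)
    )
    assert truth["causal_cpgs"] == [0, 2]
    m_sum = data.M.iloc[:, [0, 2]].sum(axis=1)
    assert np.corrcoef(m_sum, data.G.iloc[:, 0])[0, 1] > 0.2


def test_heterogeneous_coefficients_recorded_and_null_exact():
    _, truth = generate_lowdim(SimulationConfig(gamma_MG=0.2, gamma_GY=0.2, seed=12))
    gmg, ggy = np.array(truth["gamma_MG"]), np.array(truth["gamma_GY"])
    assert gmg.shape == (3,) and ggy.shape == (3,)
    assert gmg.std() > 0  # elements drawn, not broadcast
    _, null_truth = generate_lowdim(SimulationConfig(seed=12))
    assert np.all(np.array(null_truth["gamma_MG"]) == 0.0)
    assert np.all(np.array(null_truth["gamma_GY"]) == 0.0)
    _, fixed = generate_lowdim(SimulationConfig(gamma_MG=0.2, coef_sd=0.0, seed=12))
    assert np.allclose(fixed["gamma_MG"], 0.2)
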