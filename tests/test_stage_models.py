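import numpy as np
import pytest
from scipy import stats

from wpomics import P_FLOOR, fit_outcome_model, ig_pvalues, lm_pvalues
from wpomics import test_cpg_ig as cpg_ig_test
from wpomics import test_cpg_lm as cpg_lm_test
from wpomics.exceptions import DegenerateRegressorError, SingularDesignError


def textbook_ols_p(design, y, j):
    """Independent oracle: normal equations + t survival function."""
    xtx = design.T @ design
    beta = np.linalg.solve(xtx, design.T @ y)
    resid = y - design @ beta
    df = len(y) - design.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(xtx)[j, j])
    t = beta[j] / se
    return 2 * stats.t.sf(abs(t), df)


def test_hand_computed_slope_test():
    """y=[2,1,4,3] on x=[1,2,3,4]: slope 0.6, se sqrt(0.32), p=0.4 at df=2."""
    for route in (cpg_ig_test, cpg_lm_test):
        res = route(np.array([2.0, 1.0, 4.0, 3.0]), np.array([1.0, 2.0, 3.0, 4.0]))
        assert res.beta_M == pytest.approx(0.6, abs=1e-12)
        assert res.se == pytest.approx(np.sqrt(0.32), abs=1e-12)
        assert res.t_stat == pytest.approx(0.6 / np.sqrt(0.32), abs=1e-12)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.4, abs=1e-12)


@pytest.mark.parametrize("n,r,seed", [(10, 0, 1), (25, 2, 2), (40, 3, 3), (15, 1, 4)])
def test_matches_textbook_ols(n, r, seed):
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(n)
    m = rng.standard_normal(n)
    X = rng.standard_normal((n, r)) if r else None
    res = cpg_lm_test(y, m, X)
    design = np.column_stack(
        [np.ones(n), m] + ([X] if X is not None else [])
    )
    assert res.p_value == pytest.approx(textbook_ols_p(design, y, 1), abs=1e-10)


def test_first_stage_matches_statsmodels(rng):
    sm = pytest.importorskip("statsmodels.api")
    n, d, r = 30, 4, 2
    G = rng.standard_normal((n, d))
    X = rng.standard_normal((n, r))
    y = rng.standard_normal(n)
    fit = fit_outcome_model(y, G, X)
    design = np.column_stack([np.ones(n), G, X])
    ref = sm.OLS(y, design).fit()
    assert np.allclose(fit.alphaG, ref.params[1 : 1 + d], atol=1e-10)
    assert np.allclose(fit.gene_score, G @ ref.params[1 : 1 + d], atol=1e-10)


def test_exact_interpolation_recovers_coefficients():
    rng = np.random.default_rng(0)
    G = rng.standard_normal((20, 2))
    y = 1.0 + G @ np.array([0.5, 0.5])
    fit = fit_outcome_model(y, G)
    assert np.allclose(fit.alphaG, [0.5, 0.5], atol=1e-12)
    assert fit.alpha0 == pytest.approx(1.0, abs=1e-12)


def test_underdetermined_design_raises():
    rng = np.random.default_rng(1)
    with pytest.raises(Exception):
        fit_outcome_model(rng.standard_normal(3), rng.standard_normal((3, 8)))


def test_collinear_design_raises():
    rng = np.random.default_rng(2)
    g = rng.standard_normal(20)
    G = np.column_stack([g, g])  # duplicated gene
    with pytest.raises(SingularDesignError):
        fit_outcome_model(rng.standard_normal(20), G)


def test_zero_residual_degeneracy_flag():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    res = cpg_ig_test(x, x)  # gene score identical to the CpG
    assert res.degenerate and res.p_value == P_FLOOR
    res2 = cpg_lm_test(3.0 * x, x)  # outcome an exact multiple
    assert res2.degenerate and res2.p_value == P_FLOOR


def test_constant_cpg_isolated_in_vector_loop():
    rng = np.random.default_rng(3)
    n = 20
    y = rng.standard_normal(n)
    M = rng.standard_normal((n, 3))
    M[:, 1] = 7.0  # constant CpG
    p, results = lm_pvalues(y, M)
    assert np.isnan(p[1]) and results[1] is None
    assert np.isfinite(p[[0, 2]]).all()
    with pytest.raises(DegenerateRegressorError):
        cpg_lm_test(y, M[:, 1])


def test_ig_pvalues_shape_and_determinism(lowdim_split):
    split, _ = lowdim_split
    z1 = split.z1
    args = (
        z1.y.to_numpy(),
        z1.G.to_numpy(),
        z1.M.to_numpy(),
        z1.X.to_numpy(),
    )
    p_a, _ = ig_pvalues(*args)
    p_b, _ = ig_pvalues(*args)
    assert p_a.shape == (5,)
    assert np.all((p_a > 0) & (p_a <= 1))
    assert np.array_equal(p_a, p_b)


@pytest.mark.parametrize("route", ["ig", "lm"])
def test_null_pvalues_uniform(route):
    """Under independence both routes give Uniform(0,1) p-values (KS test)."""
    rng = np.random.default_rng(99)
    n, d = 30, 3
    pvals = np.empty(2000)
    for i in range(2000):
        m = rng.standard_normal(n)
        y = rng.standard_normal(n)
        if route == "ig":
            G = rng.standard_normal((n, d))
            fit = fit_outcome_model(y, G)
            pvals[i] = cpg_ig_test(fit.gene_score, m).p_value
        else:
            pvals[i] = cpg_lm_test(y, m).p_value
    assert stats.kstest(pvals, "uniform").pvalue > 0.001


def test_marginal_test_consistent_under_two_stage_truth():
    """When the cascade holds, the marginal-model power approaches 1 iff the
    methylation effect is nonzero (the route-equivalence property)."""
    rng = np.random.default_rng(5)
    n2 = 5000
    m = rng.standard_normal(n2)
    g = 0.5 * m + rng.standard_normal(n2)  # expression driven by methylation
    y_alt = 0.5 * g + rng.standard_normal(n2)
    y_null = rng.standard_normal(n2)
    assert cpg_lm_test(y_alt, m).p_value < 1e-6
    assert cpg_lm_test(y_null, m).p_value > 0.01
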