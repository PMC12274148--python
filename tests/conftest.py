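import numpy as np
import pandas as pd
import pytest

from wpomics import OmicsMatrixSet, SimulationConfig, apply_missingness, generate_lowdim


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_dataset():
    """Six samples, two of which lack expression."""
    ids = pd.Index([f"s{i}" for i in range(6)], name="sample_id")
    rng = np.random.default_rng(7)
    y = pd.Series(rng.standard_normal(6), index=ids, name="Y")
    M = pd.DataFrame(rng.standard_normal((6, 3)), index=ids,
                     columns=["cg1", "cg2", "cg3"])
    X = pd.DataFrame(rng.standard_normal((6, 2)), index=ids,
                     columns=["x1", "x2"])
    G = pd.DataFrame(rng.standard_normal((4, 2)), index=ids[:4],
                     columns=["g1", "g2"])
    return OmicsMatrixSet(y=y, M=M, G=G, X=X)


@pytest.fixture
def lowdim_split():
    """Default-condition null dataset at 70% missing expression."""
    data, truth = generate_lowdim(SimulationConfig(seed=11))
    return apply_missingness(data, 0.7, 12), truth
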