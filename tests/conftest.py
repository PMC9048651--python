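import numpy as np
import pytest

import grninfer as gi


@pytest.fixture
def small_expr():
    """3 genes x 4 samples of counts."""
    values = np.array([[1, 0, 2, 3],
                       [2, 3, 0, 1],
                       [0, 5, 5, 0]], float)
    return gi.GeneExpressionMatrix(values, ["g1", "g2", "g3"],
                                   ["s1", "s2", "s3", "s4"])


@pytest.fixture
def small_prior():
    """2 TFs x 3 genes signed prior."""
    values = np.array([[1.0, 0.0, -1.0],
                       [0.0, 1.0, 1.0]])
    return gi.AdjacencyNetwork(values, ["A", "B"], ["g1", "g2", "g3"])


@pytest.fixture
def small_truth():
    return gi.generate_truth(50, 8, 0.1, seed=7)


@pytest.fixture
def small_dataset(small_truth):
    expr, act = gi.simulate_dataset(small_truth, 150, 0.5, seed=8)
    return small_truth, expr, act


@pytest.fixture
def regression_instance():
    """Centered/standardized regression data with a known sparse signal."""
    rng = np.random.default_rng(11)
    n, p = 120, 6
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.zeros(p)
    beta[0], beta[2] = 2.0, -1.5
    y = X @ beta + rng.normal(0, 0.5, n)
    y = y - y.mean()
    return y, X, beta
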