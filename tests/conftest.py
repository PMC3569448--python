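import numpy as np
import pytest

from pplsda.dataio import ExpressionDataset
from pplsda.simulate import SimulationDesign, simulate_case


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    """4 samples x 3 features, cleanly separable along feature 0."""
    X = np.array(
        [
            [2.0, 0.5, 1.0],
            [1.5, -0.5, 1.2],
            [-2.0, 0.4, 0.9],
            [-1.6, -0.3, 1.1],
        ]
    )
    return ExpressionDataset(
        matrix=X,
        labels=np.array(["A", "A", "B", "B"]),
        sample_ids=np.array(["s1", "s2", "s3", "s4"]),
        feature_ids=np.array(["f1", "f2", "f3"]),
    )


@pytest.fixture
def symmetric_toy():
    """The rank-1 between-group example: means at (1,1) and (-1,-1)."""
    X = np.array([[2.0, 0.0], [0.0, 2.0], [-2.0, 0.0], [0.0, -2.0]])
    return X, np.array(["A", "A", "B", "B"])


def make_separable(n_per_class=20, p=30, gap=20.0, seed=0):
    """Two far clusters, trivially separable along feature 0."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, size=(2 * n_per_class, p))
    X[:n_per_class, 0] += gap
    labels = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    return ExpressionDataset(
        matrix=X,
        labels=labels,
        sample_ids=np.array([f"s{i}" for i in range(2 * n_per_class)]),
        feature_ids=np.array([f"f{j}" for j in range(p)]),
    )


@pytest.fixture
def separable_dataset():
    return make_separable()


@pytest.fixture
def case3_train():
    """A balanced outer training set from one case-3 simulation."""
    from pplsda.evaluate import outer_split

    ds = simulate_case(SimulationDesign.case(3), np.random.default_rng(77))
    split = outer_split(ds, np.random.default_rng(78))
    return ds.subset(split.train)
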