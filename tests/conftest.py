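import numpy as np
import pytest

from linkstack.graphio import Network, SyntheticSpec, generate_synthetic


@pytest.fixture
def k2():
    """Single edge 0-1."""
    return Network(["a", "b"], {(0, 1)})


@pytest.fixture
def path3():
    """Path 0-1-2."""
    return Network(["a", "b", "c"], {(0, 1), (1, 2)})


@pytest.fixture
def triangle():
    return Network(["a", "b", "c"], {(0, 1), (1, 2), (0, 2)})


@pytest.fixture
def cycle4():
    """4-cycle 0-1-2-3-0."""
    return Network(list("abcd"), {(0, 1), (1, 2), (2, 3), (0, 3)})


def random_er_graphs(n_graphs: int, seed: int = 0, n_range=(5, 30)):
    """Seeded ER graphs of varying size/density for oracle sweeps."""
    rng = np.random.default_rng(seed)
    graphs = []
    for g in range(n_graphs):
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        p = float(rng.uniform(0.1, 0.5))
        graphs.append(
            generate_synthetic(
                SyntheticSpec("erdos_renyi", n, {"p": p}, seed=int(rng.integers(2**31)))
            )
        )
    return graphs


@pytest.fixture(scope="session")
def er_suite():
    """The 50-graph oracle-equivalence suite."""
    return random_er_graphs(50, seed=12345)


@pytest.fixture(scope="session")
def sbm_net():
    """Two 100-node communities; the standard planted-signal fixture."""
    return generate_synthetic(
        SyntheticSpec(
            "stochastic_block", 200,
            {"sizes": [100, 100], "p_in": 0.15, "p_out": 0.01}, seed=7,
        )
    )


def planted_table(n_rows=300, n_noise=11, seed=0, label_copy=True):
    """Feature table with one label-copy column among noise columns."""
    from linkstack.dataset import FeatureTable

    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n_rows)
    X = rng.normal(size=(n_rows, n_noise + (1 if label_copy else 0)))
    names = [f"noise{i}" for i in range(n_noise)]
    if label_copy:
        X[:, 0] = y.astype(float)
        names = ["signal"] + names
    pairs = [(2 * r, 2 * r + 1) for r in range(n_rows)]
    return FeatureTable(pairs, X, y, names)
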