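import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import netvgk as nv

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort() -> nv.BulkCohort:
    """Default-structure cohort at reduced gene count (fast)."""
    return nv.generate_bulk_cohort(nv.BulkSimParams(n_genes=300, seed=11))


@pytest.fixture(scope="session")
def sc_dataset() -> nv.SingleCellDataset:
    ds = nv.generate_sc_dataset(nv.SCSimParams(seed=11))
    ds.normalize()
    return ds


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_graph(rng: np.random.Generator, n_max: int = 6):
    """Random simple graph on <= n_max nodes (possibly disconnected/edgeless)."""
    import networkx as nx

    n = int(rng.integers(1, n_max + 1))
    p = float(rng.uniform(0, 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g


def make_matrix(values, genes=None, samples=None, space="lognorm") -> nv.ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return nv.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), space=space)
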