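import numpy as np
import pandas as pd
import pytest

from coelnet.classifier import PredictedNetwork
from coelnet.synthetic import WorldConfig, generate_world


@pytest.fixture(scope="session")
def tiny_config():
    """A small, fast world: 60 proteins, 8 complexes, 20 fractions."""
    return WorldConfig(
        n_proteins=60,
        n_complexes=8,
        complex_size_range=(3, 4),
        n_fractions=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    return generate_world(tiny_config)


def make_network(edges, scores=None):
    """Build a PredictedNetwork from a list of (a, b) pairs."""
    edges = [tuple(sorted(e)) for e in edges]
    if scores is None:
        scores = np.linspace(1.0, 0.5, num=len(edges))
    df = pd.DataFrame(
        {
            "id_a": [a for a, _ in edges],
            "id_b": [b for _, b in edges],
            "score": scores,
            "rank": np.arange(1, len(edges) + 1),
        }
    )
    return PredictedNetwork(df)


@pytest.fixture
def clique_network():
    """Two disjoint 4-cliques plus an isolated edge."""
    c1 = ["A1", "A2", "A3", "A4"]
    c2 = ["B1", "B2", "B3", "B4"]
    edges = []
    for grp in (c1, c2):
        for i in range(4):
            for j in range(i + 1, 4):
                edges.append((grp[i], grp[j]))
    edges.append(("C1", "C2"))
    return make_network(edges)
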