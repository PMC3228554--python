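import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dart import PathwaySignature, RelevanceNetwork


def make_network(edges, nodes=(), p_threshold=1e-4, n_samples=50):
    """Build a RelevanceNetwork directly from (u, v, observed_sign[, corr]) tuples."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for e in edges:
        u, v, sign = e[:3]
        corr = e[3] if len(e) > 3 else 0.5 * sign
        g.add_edge(u, v, corr=corr, y=float(np.arctanh(corr)), p=1e-6,
                   observed_sign=sign, collinear=False)
    return RelevanceNetwork(graph=g, p_threshold=p_threshold, n_samples=n_samples)


@pytest.fixture
def toy_matrix():
    """3 genes x 4 samples with simple integer values."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0], [0.0, 0.0, 1.0, 1.0]],
        index=["A", "B", "C"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def up_down_sig():
    return PathwaySignature("toy", {"u1": +1, "u2": +1, "d1": -1, "d2": -1})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
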