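import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import radrank as rr

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix():
    """3 probes x 4 samples, linear scale, two groups of two."""
    data = pd.DataFrame(
        [[8.0, 4.0, 2.0, 1.0], [1.0, 2.0, 4.0, 8.0], [5.0, 5.0, 5.0, 5.0]],
        index=["p1", "p2", "p3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    labels = pd.Series(["a", "a", "b", "b"], index=data.columns)
    return rr.ExpressionMatrix(data=data, scale="linear", labels=labels)


@pytest.fixture
def two_group_matrix(rng):
    """20 probes x 6 samples (3 vs 3) of Gaussian log2 intensities."""
    data = pd.DataFrame(
        rng.normal(8, 1, size=(20, 6)),
        index=[f"p{i}" for i in range(20)],
        columns=[f"s{i}" for i in range(6)],
    )
    labels = pd.Series(["a"] * 3 + ["b"] * 3, index=data.columns)
    return rr.ExpressionMatrix(data=data, scale="log2", labels=labels)


def make_network(edges):
    """Build a directed network from (source, target, ref_count) triples."""
    net = rr.new_network()
    for u, v, r in edges:
        rr.add_interaction(net, u, v, ref_count=r)
    return net


@pytest.fixture
def chain_net():
    return make_network([("A", "B", 1), ("B", "C", 1)])
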