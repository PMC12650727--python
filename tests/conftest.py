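import numpy as np
import pytest

from dynetsim.core import DynamicNetwork, edge_index_pairs


def net_from_edges(edge_series: np.ndarray, n: int) -> DynamicNetwork:
    """Build a dynamic network from a (T, m) edge-series block."""
    edge_series = np.atleast_2d(np.asarray(edge_series, dtype=float))
    T, m = edge_series.shape
    iu, ju = edge_index_pairs(n)
    assert iu.size == m
    weights = np.zeros((T, n, n))
    weights[:, iu, ju] = edge_series
    weights[:, ju, iu] = edge_series
    return DynamicNetwork(weights)


def single_edge_net(series) -> DynamicNetwork:
    """A 2-node network whose only edge follows ``series``."""
    return net_from_edges(np.asarray(series, dtype=float)[:, None], 2)


def random_net(rng: np.random.Generator, n: int, T: int) -> DynamicNetwork:
    m = n * (n - 1) // 2
    return net_from_edges(rng.normal(1.0, 0.5, size=(T, m)), n)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def net3x1():
    """3-node, single-timepoint network with upper triangle [1, 2, 3]."""
    return DynamicNetwork(np.array([[[0.0, 1, 2], [1, 0, 3], [2, 3, 0]]]))
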