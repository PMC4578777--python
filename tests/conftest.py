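import numpy as np
import pytest

from hcc_clinde.grn_data import DelayedEdge, DelayedGRN, ExpressionSegments


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def star_grn():
    """Hidden hub with two observed parents and three observed children."""
    g = DelayedGRN(n_observed=5, n_hidden=1)
    h = 5
    g.add_edge(DelayedEdge(0, h, 2, 1.0))
    g.add_edge(DelayedEdge(1, h, 1, -0.8))
    g.add_edge(DelayedEdge(h, 2, 1, 1.2))
    g.add_edge(DelayedEdge(h, 3, 3, -1.1))
    g.add_edge(DelayedEdge(h, 4, 2, 0.7))
    return g


def make_segments(arrays, genes=None):
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    if genes is None:
        genes = [f"G{i}" for i in range(arrays[0].shape[1])]
    return ExpressionSegments(arrays, genes)
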