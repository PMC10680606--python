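import numpy as np
import pytest

import grnsup as g


@pytest.fixture(scope="session")
def tiny_params():
    """Smallest benchmark geometry that still exercises every layer."""
    return g.TopologyParams(n_mr=2, n_tf=5, n_g=5, d_mr_tf=2, d_tf_g_range=(1, 3), n_grn=2)


@pytest.fixture(scope="session")
def tiny_net(tiny_params):
    net = g.sample_topology(tiny_params, seed=7)
    return g.sample_interactions(net, seed=8)


@pytest.fixture(scope="session")
def tiny_benchmark(tiny_params):
    return g.generate_benchmark(tiny_params, m=20, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
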