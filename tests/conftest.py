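import numpy as np
import pytest

import ktnreduce as kr


@pytest.fixture
def chain3():
    """Three-state chain 1-2-3 with all six rates equal to one."""
    K = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    return kr.RateNetwork.from_rates(K)


@pytest.fixture
def chain4():
    """Four-state chain 1-2-3-4 with all rates equal to one."""
    K = np.zeros((4, 4))
    for a, b in [(0, 1), (1, 2), (2, 3)]:
        K[a, b] = K[b, a] = 1.0
    return kr.RateNetwork.from_rates(K)


@pytest.fixture(scope="session")
def metastable_net():
    """Four-community 2x2 landscape, 15 nodes/community, with metastability
    ratio lambda0*tau_m <= 1e-2 in every community."""
    cfg = kr.LandscapeConfig(
        grid=(2, 2),
        nodes_per_community=15,
        seed=3,
        inter_edges_per_pair=3,
        target_mean_degree=5.0,
        inter_barrier_min=4.0,
        inter_barrier_scale=3.0,
    )
    net, part = kr.generate(cfg)
    return net, part


@pytest.fixture(scope="session")
def nine_well_net():
    """Scaled-down nine-community landscape (20 nodes per well)."""
    cfg = kr.LandscapeConfig(nodes_per_community=20, seed=11,
                             target_mean_degree=6.0, inter_edges_per_pair=3)
    net, part = kr.generate(cfg)
    return net, part
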