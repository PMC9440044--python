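import numpy as np
import pytest

from ltmcascades import build_network


@pytest.fixture
def and_motif_net():
    """The AND automaton: u adjacent to seeds a, b with phi_u > 1/2."""
    return build_network(
        n=3,
        edges=[(0, 2), (1, 2)],
        thresholds=[0.5, 0.5, 0.6],
        seed_nodes=[0, 1],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
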