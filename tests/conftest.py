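import numpy as np
import pytest

from resilnet import GeneratorConfig, IsingNetwork, generate_panel
from resilnet.panel import DEFAULT_LABELS


@pytest.fixture(scope="session")
def chain_network():
    """Known sparse 5-node network: two chain edges of weight 1.5."""
    W = np.zeros((5, 5))
    W[0, 1] = W[1, 0] = 1.5
    W[1, 2] = W[2, 1] = 1.5
    return IsingNetwork(labels=DEFAULT_LABELS, W=W, tau=np.full(5, -3.0))


@pytest.fixture(scope="session")
def independence_network():
    return IsingNetwork(labels=DEFAULT_LABELS, W=np.zeros((5, 5)),
                        tau=np.full(5, -1.0))


@pytest.fixture(scope="session")
def small_panel():
    """Medium synthetic rotating panel shared across tests (n=800/year)."""
    cfg = GeneratorConfig(seed=123, n_target=800)
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=123)
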