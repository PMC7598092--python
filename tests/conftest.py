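import numpy as np
import pytest

import neuromass as nm


@pytest.fixture
def params():
    return nm.PopulationParams()


@pytest.fixture
def tiny_connectome():
    """Deterministic dense 3-region connectome with integer-step delays."""
    S = np.array([[0, 40, 90], [25, 0, 60], [120, 35, 0]], dtype=float)
    L = np.array([[0, 21, 35], [28, 0, 42], [35, 49, 0]], dtype=float)
    return nm.Connectome(S=S, L=L, W=nm.init_weights(S), D=nm.compute_delays(L))


@pytest.fixture
def small_random_connectome():
    return nm.generate_synthetic_connectome(n=10, p=0.4, seed=7)
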