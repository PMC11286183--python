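import numpy as np
import pytest

from citexposure import MemoryParams, run_memory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def consistency_runs():
    """Five scaled memory-model replicates at a fixed encoding value.

    The run-to-run consistency condition: R=200 articles, C=10,000
    epochs, n=20 features, L=0.5, Sim=0.1, seeds 1-5.
    """
    params = MemoryParams(L=0.5, Sim=0.1, n_features=20)
    return [run_memory(200, 10_000, params=params, seed=s) for s in range(1, 6)]
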