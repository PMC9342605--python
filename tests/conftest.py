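import numpy as np
import pytest

from bglearn import DAParams, NetworkParams, PlasticWeights
from bglearn.config import RunConfig
from bglearn.experiment import run_experiment


@pytest.fixture(scope="session")
def control_params() -> DAParams:
    return DAParams.control()


@pytest.fixture(scope="session")
def imbalance_params() -> DAParams:
    return DAParams.imbalance()


@pytest.fixture(scope="session")
def net_params() -> NetworkParams:
    return NetworkParams()


@pytest.fixture()
def naive_weights() -> PlasticWeights:
    return PlasticWeights.naive()


@pytest.fixture(scope="session")
def strong_weights() -> PlasticWeights:
    """A fully differentiated weight state (as after successful training)."""
    W = PlasticWeights.naive()
    W.wGS = np.full((4, 4), 0.25)
    np.fill_diagonal(W.wGS, 1.0)
    W.wNS = np.full((4, 4), 0.2)
    W.wGC = np.diag(np.full(4, 1.0))
    W.wNC = np.diag(np.full(4, 0.1))
    return W


@pytest.fixture(scope="session")
def cohort_result():
    """Full reference experiment (10 + 10 subjects, 1,000 epochs, 100 test
    stimuli), shared by the acceptance tests; runs once per session."""
    cfg = RunConfig(base_seed=0)
    return run_experiment(cfg)
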