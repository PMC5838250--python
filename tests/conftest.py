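import numpy as np
import pytest

from pkaswarm import OptimizerConfig


@pytest.fixture(autouse=True, scope="session")
def _quiet_rdkit():
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")


@pytest.fixture
def tiny_config():
    """Small optimizer budget for fast structural tests."""
    return OptimizerConfig(m=10, it_max=40)


def sphere(X):
    X = np.atleast_2d(X)
    return np.sum(X**2, axis=1)
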