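import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/_oracles.py

from rosette.simulate import SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240916)


@pytest.fixture(scope="session")
def default_bundle():
    """Default seeded synthetic bundle (noise on), shared across tests."""
    return generate(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def noisefree_bundle():
    """Deterministic noise-free bundle: exact planted structure."""
    return generate(SyntheticConfig(seed=5, noise=False, n_se_clusters=5))
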