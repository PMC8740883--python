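import numpy as np
import pytest

import scpowersim as sp


@pytest.fixture(scope="session")
def small_prototype():
    """A small synthetic prototype with known generating parameters."""
    spec = sp.PrototypeSpec(k=3, n_pcs=5, n_samples=12, n_batches=4,
                            cells_per_sample=80, centroid_separation=10.0,
                            batch_sd=0.3, sample_sd=0.2, residual_sd=1.0,
                            logfreq_sd=0.4, seed=42)
    return sp.generate_prototype(spec)


@pytest.fixture(scope="session")
def small_params(small_prototype):
    data, _ = small_prototype
    return sp.estimate_params(data)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
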