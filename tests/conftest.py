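import numpy as np
import pytest

from slideattn.synthetic import BagSimConfig, generate_bags


@pytest.fixture(scope="session")
def easy_bags():
    """Well-separated bags for quick optimization sanity checks."""
    cfg = BagSimConfig(n_bags=30, bag_size=20, dim=5, witness_rate=0.5,
                       mu_pos=3.0, seed=11)
    return generate_bags(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
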