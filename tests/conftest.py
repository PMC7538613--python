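import numpy as np
import pytest
from hypothesis import settings

import pcoma as pc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_phantom():
    """One rendered circle-of-Willis phantom with planted PcomA SNR 12."""
    config = pc.willis_phantom_config(seed=0)
    volume, truth = pc.make_angiophantom(config)
    return config, volume, truth


@pytest.fixture(scope="session")
def phantom_batch():
    """Five phantoms (seeds 0..4) with planted PcomA SNR 12 on both sides."""
    out = []
    for seed in range(5):
        config = pc.willis_phantom_config(seed=seed)
        out.append((config, *pc.make_angiophantom(config)))
    return out


@pytest.fixture(scope="session")
def rayleigh_volume():
    """Pure-noise magnitude volume (channel sigma 1.0), > 1e5 voxels."""
    rng = np.random.default_rng(1234)
    n1 = rng.normal(0.0, 1.0, (64, 64, 40))
    n2 = rng.normal(0.0, 1.0, (64, 64, 40))
    return pc.AngioVolume(np.hypot(n1, n2))
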