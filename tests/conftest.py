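import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_panel(rng, n_hap, n_sites, mosaic=True):
    """Random allele matrix, optionally with founder-mosaic sharing."""
    if not mosaic:
        return rng.integers(0, 2, (n_hap, n_sites)).astype(np.int8)
    n_f = max(2, n_hap // 4)
    founders = rng.integers(0, 2, (n_f, n_sites))
    rows = founders[rng.integers(n_f, size=n_hap)]
    flips = rng.random((n_hap, n_sites)) < 0.05
    return (rows ^ flips).astype(np.int8)
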