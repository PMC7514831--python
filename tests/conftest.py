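import numpy as np
import pytest

from compressed_mhde.compression import SensingSpec, compress_stream
from compressed_mhde.simstudy import simulate_raw_blocks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(
    mu=2.0,
    sigma=1.0,
    spec: SensingSpec | None = None,
    B=100,
    seed=0,
):
    """Simulate raw N(mu, sigma^2) blocks and compress them."""
    spec = spec or SensingSpec.gaussian(0.1, S=1, J=1000)
    root = np.random.SeedSequence(seed)
    raw_ss, sens_ss = root.spawn(2)
    blocks = simulate_raw_blocks(mu, sigma, spec.J, B, np.random.default_rng(raw_ss))
    return compress_stream(blocks, spec, seed=sens_ss)


@pytest.fixture
def small_degenerate_dataset():
    return make_dataset(spec=SensingSpec.degenerate(S=1, J=100), B=50, seed=3)
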