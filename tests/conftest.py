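import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160418)


@pytest.fixture
def monotone_block(rng):
    """65 monotone nondecreasing values with mixed small/large steps."""
    steps = rng.integers(0, 200, 64)
    steps[40] = 3000  # one repetitive-k-mer-style jump
    return np.cumsum(np.concatenate([[12345], steps]))


def make_offsets(kind: str, n: int, seed: int = 0) -> np.ndarray:
    """Offset arrays with the difference profiles the codecs must handle."""
    rng = np.random.default_rng(seed)
    if kind == "constant":
        return np.full(n, 7, dtype=np.uint32)
    if kind == "unit":
        return np.arange(n, dtype=np.uint32)
    if kind == "heavy":
        d = np.zeros(n - 1, dtype=np.int64)
        nz = rng.random(n - 1) >= 0.85
        d[nz] = np.minimum(rng.zipf(1.4, int(nz.sum())), 1 << 16)
        out = np.zeros(n, dtype=np.int64)
        np.cumsum(d, out=out[1:])
        return out.astype(np.uint32)
    if kind == "wide":  # forces width-32 blocks next to width-0 blocks
        d = np.zeros(n - 1, dtype=np.int64)
        d[:: max(1, (n - 1) // 4)] = (1 << 32) - 1 - 4  # huge isolated jumps
        out = np.zeros(n, dtype=np.int64)
        np.cumsum(np.minimum(d, ((1 << 32) - 1) // 5), out=out[1:])
        return out.astype(np.uint32)
    raise ValueError(kind)
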