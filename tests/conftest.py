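import numpy as np
import pytest

from hetchrom import synth
from hetchrom.intervals import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_genome():
    """Default 2 x 100 kb genome with its repeat annotation."""
    spec = synth.SyntheticGenomeSpec(seed=7)
    genome, elements = synth.make_genome(spec)
    return genome, elements


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=300):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        out.append(
            GenomicInterval(
                str(rng.choice(chroms)),
                start,
                start + int(rng.integers(1, max_len)),
                score=float(rng.uniform(0, 500)),
            )
        )
    return out
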