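import numpy as np
import pytest

from ecgi.intervals import GenomicInterval
from ecgi.synth import SynthConfig, generate


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=100_000, max_len=500):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def brute_force_overlap(a, b):
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@pytest.fixture(scope="session")
def dataset():
    """Default noise-free synthetic dataset shared by read-only tests."""
    return generate(SynthConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
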