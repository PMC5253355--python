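import numpy as np
import pytest

from virobench.seqio import GenomeRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(n: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_genomes(rng):
    """Five linear 10 kb genomes."""
    return [GenomeRecord(f"g{i + 1}", random_dna(10_000, rng)) for i in range(5)]
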