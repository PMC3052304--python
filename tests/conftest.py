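import numpy as np
import pytest

import readscrub as rs


@pytest.fixture(scope="session")
def small_genome() -> rs.SequenceRecord:
    """50 kbp seeded random genome shared by alignment tests."""
    return rs.make_synthetic_genome(50_000, seed=1234, id="smallG")


@pytest.fixture(scope="session")
def small_index(small_genome) -> rs.FMIndex:
    chunk = rs.ReferenceChunk("c1", [small_genome], role="remove")
    return rs.build_index(chunk, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
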