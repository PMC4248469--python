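import numpy as np
import pytest

from bloomec.bloom import ExactKmerSet
from bloomec.kmers import canonical_codes, seq_to_codes


def random_seq(rng, n):
    return "".join("ACGT"[c] for c in rng.integers(0, 4, size=n))


def genome_kmer_set(genome: str, k: int) -> ExactKmerSet:
    """Exact canonical k-mer set of a genome string."""
    canon, valid = canonical_codes(seq_to_codes(genome), k)
    return ExactKmerSet(canon[valid].tolist())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toy_genome():
    """A 400-bp random genome, repeat-free at k=9 (checked below)."""
    g = np.random.default_rng(11).integers(0, 4, size=400)
    seq = "".join("ACGT"[c] for c in g)
    canon, _ = canonical_codes(seq_to_codes(seq), 9)
    assert len(np.unique(canon)) == len(canon), "fixture genome must be repeat-free"
    return seq
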