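import numpy as np
import pytest

from damtrack.genome import GatcIndex, GenomeSequence, build_fragment_map, scan_gatc_sites


@pytest.fixture
def toy_genome() -> GenomeSequence:
    # chr1 has GATC at 4 and 12; chr2 has none
    return GenomeSequence({"c1": "AAAAGATCAAAAGATCAAAA", "c2": "ACGTACGTAC"})


@pytest.fixture
def toy_fmap(toy_genome):
    return build_fragment_map(scan_gatc_sites(toy_genome), toy_genome.lengths)


@pytest.fixture
def uniform_fmap():
    """5000 fragments of 100 bp on one contig."""
    n = 5000
    sites = np.arange(1, n, dtype=np.int64) * 100 - 2
    return build_fragment_map(GatcIndex({"c1": sites}), {"c1": n * 100})


def random_genome(rng: np.random.Generator, length: int, alphabet: str = "ACGTN") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def brute_force_scan(seq: str, motif: str = "GATC"):
    return [i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]
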