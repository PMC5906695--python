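import numpy as np
import pytest

from mutrec.genome import GenomeSequence, build_masked_genome
from mutrec.intervals import IntervalSet


@pytest.fixture
def tiny_genome():
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {
        "chr1": bases[rng.integers(0, 4, 1000)].tobytes().decode(),
        "chr2": bases[rng.integers(0, 4, 600)].tobytes().decode(),
    }
    return GenomeSequence(seqs)


@pytest.fixture
def tiny_masked(tiny_genome):
    return build_masked_genome(tiny_genome)


@pytest.fixture
def masked_with_holes(tiny_genome):
    cds = IntervalSet([("chr1", 100, 200)])
    ig = IntervalSet([("chr1", 150, 300)])
    return build_masked_genome(tiny_genome, cds=cds, ig_loci=ig)
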