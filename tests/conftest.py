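import numpy as np
import pytest

from crossonc import synthetic as syn
from crossonc.model import CnaTruth, TruthSegment


@pytest.fixture(scope="session")
def small_genome():
    """Two 1 Mb chromosomes, 8 genes each, probes every ~5.5 kb."""
    return syn.make_genome(
        n_chrom=2, chrom_len=1_000_000, gene_count=8, probe_spacing=5_500, seed=42
    )


@pytest.fixture()
def amp_truth():
    return CnaTruth("t1", [TruthSegment("chr1", 200_000, 420_000, 1.0, "amp")])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
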