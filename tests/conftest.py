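import pytest

from riboshift.genome import TranscriptModel
from riboshift.simulate import SimConfig, simulate_transcriptome


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=40, library_size=30_000, seed=5)


@pytest.fixture(scope="session")
def small_txome(small_config):
    return simulate_transcriptome(small_config, seed=5)


@pytest.fixture
def single_exon_model():
    """100 nt 5'UTR, 300 nt CDS, 100 nt 3'UTR on one plus-strand exon."""
    return TranscriptModel("TX1", "G1", "chr1", "+", [(1000, 1500)], (100, 400))


@pytest.fixture
def minus_two_exon_model():
    """Minus-strand transcript with two exons (lengths 10 + 10)."""
    return TranscriptModel("TXM", "GM", "chr1", "-", [(120, 130), (100, 110)])
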