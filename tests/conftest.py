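import numpy as np
import pytest

from chorseq.genomic_io import GenomeLayout, GenomicInterval


@pytest.fixture
def layout():
    """Two small target chromosomes."""
    return GenomeLayout({"chr1": 10_000, "chr2": 5_000}, origin="target")


@pytest.fixture
def spike_layout():
    return GenomeLayout({"spike_2L": 2_000}, origin="spikein")


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_921)


def random_intervals(rng, n, chrom="chr1", chrom_len=10_000, max_len=400, stranded=False):
    starts = rng.integers(0, chrom_len - max_len, n)
    lengths = rng.integers(1, max_len, n)
    strands = rng.choice(["+", "-"], n) if stranded else ["."] * n
    return [
        GenomicInterval(chrom, int(s), int(s + l), str(st))
        for s, l, st in zip(starts, lengths, strands)
    ]
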