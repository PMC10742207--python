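import numpy as np
import pytest

from fusebind.intervals import GeneModel, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=300):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def brute_force_overlaps(a, b):
    """All-pairs O(n*m) overlap oracle: a-intervals overlapping any b."""
    return [
        iv for iv in a
        if any(
            iv.chrom == other.chrom
            and iv.start < other.end
            and other.start < iv.end
            for other in b
        )
    ]


@pytest.fixture
def gene_panel():
    """Six genes on two chromosomes with both strands, well separated."""
    return [
        GeneModel("gA", "chr1", "+", 20_000, 25_000),
        GeneModel("gB", "chr1", "-", 60_000, 66_000),
        GeneModel("gC", "chr1", "+", 100_000, 104_000),
        GeneModel("gD", "chr2", "-", 30_000, 37_000),
        GeneModel("gE", "chr2", "+", 80_000, 85_000),
        GeneModel("gF", "chr2", "+", 140_000, 145_000),
    ]
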