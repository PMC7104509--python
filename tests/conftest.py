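import numpy as np
import pytest

from cnvburden.cnv import CNVCall, DELETION, DUPLICATION
from cnvburden.genesets import GeneRecord
from cnvburden.intervals import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_call(
    sample="s1",
    chrom="chr1",
    start=0,
    end=100_000,
    cn=3,
    n_probes=50,
):
    cnv_type = DELETION if cn < 2 else DUPLICATION
    return CNVCall(sample, GenomicInterval(chrom, start, end), cnv_type, n_probes, cn)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_coord=100_000):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_coord - 1))
        end = int(rng.integers(start + 1, max_coord))
        out.append(GenomicInterval(chrom, start, end))
    return out


def coverage_mask(intervals, chroms, max_coord):
    """Per-base boolean coverage oracle."""
    masks = {c: np.zeros(max_coord, dtype=bool) for c in chroms}
    for iv in intervals:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


@pytest.fixture
def toy_genes():
    return [
        GeneRecord("gA", GenomicInterval("chr1", 100, 200), "ohnolog_no_ssd"),
        GeneRecord("gB", GenomicInterval("chr1", 300, 400), "singleton"),
        GeneRecord("gC", GenomicInterval("chr1", 500, 600), "ohnolog_ssd"),
        GeneRecord("gD", GenomicInterval("chr2", 100, 200), "non_ohnolog_duplicate"),
    ]
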