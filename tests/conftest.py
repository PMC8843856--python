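import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from polyte.core import GenomicInterval
from polyte.landscape import GeneModel, TEAnnotation
from polyte.popgen import HaplotypeBlock


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_block(matrix, window_bp=1000, positions=None, chrom="chr1", prune=True):
    matrix = np.asarray(matrix, dtype=np.uint8)
    if positions is None:
        positions = np.arange(matrix.shape[1]) * 10
    return HaplotypeBlock(
        positions=np.asarray(positions),
        matrix=matrix,
        window=GenomicInterval(chrom, 0, window_bp),
        prune=prune,
    )


def make_gene(gene_id, start, end, strand="+", exons=None, cds=None, chrom="chr1"):
    iv = GenomicInterval(chrom, start, end, strand)
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in (exons or [(start, end)])]
    cds = [GenomicInterval(chrom, s, e, strand) for s, e in (cds or [])]
    return GeneModel(gene_id=gene_id, interval=iv, exons=exons, cds=cds)


def make_te(te_id, start, end, superfamily="other", chrom="chr1"):
    return TEAnnotation(
        te_id=te_id,
        interval=GenomicInterval(chrom, start, end),
        superfamily=superfamily,
    )
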