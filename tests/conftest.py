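import numpy as np
import pytest
from hypothesis import settings

from occupeak import Gene, GeneModel, GenomicInterval, PeakSet

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_model() -> GeneModel:
    """Four hand-built genes covering every element type and both strands."""
    gene_a = Gene(
        gene_id="geneA", chrom="chr1", start=1000, end=10000, strand="+",
        biotype="protein_coding",
        exons=((1000, 1400), (3000, 3500), (6000, 6600), (9000, 10000)),
        cds=((1200, 1400), (3000, 3500), (6000, 6600), (9000, 9500)),
    )
    gene_b = Gene(
        gene_id="geneB", chrom="chr1", start=15000, end=20000, strand="-",
        biotype="lncRNA",
        exons=((15000, 16000), (18000, 20000)),
    )
    gene_c = Gene(
        gene_id="geneC", chrom="chr2", start=500, end=700, strand="+",
        biotype="snoRNA", exons=((500, 700),),
    )
    gene_d = Gene(
        gene_id="geneD", chrom="chr2", start=5000, end=12000, strand="-",
        biotype="protein_coding",
        exons=((5000, 6500), (9000, 9800), (11000, 12000)),
        cds=((6000, 6500), (9000, 9800), (11000, 11500)),
    )
    return GeneModel([gene_a, gene_b, gene_c, gene_d],
                     chrom_sizes={"chr1": 30000, "chr2": 20000})


def random_peakset(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                   max_pos: int = 50_000, max_len: int = 200,
                   label: str = "") -> PeakSet:
    ivs = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len + 1))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return PeakSet(ivs, label=label)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
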