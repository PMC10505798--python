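import numpy as np
import pytest

from haplomarker import GeneModel, paper_mimic_suite
from haplomarker.gene_region_effects import extract_gene_region


def random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def make_toy_gene(rng, n_exons: int = 2, exon_len: int = 45,
                  intron_len: int = 30, upstream: int = 120,
                  downstream: int = 80, strand: str = "+"):
    """A small random gene with a valid ORF, plus its chromosome."""
    n_codons = n_exons * exon_len // 3
    codons = []
    stops = {"TAA", "TAG", "TGA"}
    while len(codons) < n_codons - 2:
        c = random_seq(rng, 3)
        if c not in stops:
            codons.append(c)
    cds = "ATG" + "".join(codons) + "TAA"
    pieces, coords = [], []
    pos = upstream + 21  # 20 bp pad before the region
    cpos = 0
    for i in range(n_exons):
        coords.append((pos, pos + exon_len - 1))
        pieces.append(cds[cpos:cpos + exon_len])
        cpos += exon_len
        pos += exon_len
        if i < n_exons - 1:
            pieces.append("GT" + random_seq(rng, intron_len - 4) + "AG")
            pos += intron_len
    body = "".join(pieces)
    chrom_plus = (random_seq(rng, 20) + random_seq(rng, upstream) + body
                  + random_seq(rng, downstream) + random_seq(rng, 20))
    if strand == "+":
        gene = GeneModel("toy", "chr", "+", upstream + 21,
                         upstream + 20 + len(body), tuple(coords),
                         upstream, downstream)
        return gene, chrom_plus
    # mirror everything onto the minus strand
    from haplomarker.genomic_io import revcomp
    L = len(chrom_plus)
    chrom = revcomp(chrom_plus)
    flip = lambda a, b: (L - b + 1, L - a + 1)
    coords_m = [flip(a, b) for a, b in coords]
    gene = GeneModel("toy", "chr", "-", L - (upstream + 21) + 1,
                     L - (upstream + 20 + len(body)) + 1,
                     tuple(coords_m), upstream, downstream)
    return gene, chrom


@pytest.fixture(scope="session")
def toy_gene():
    rng = np.random.default_rng(42)
    gene, chrom = make_toy_gene(rng)
    region = extract_gene_region({"chr": chrom}, gene)
    return gene, chrom, region


@pytest.fixture(scope="session")
def mimic_suite():
    return paper_mimic_suite()


@pytest.fixture(scope="session")
def mimic_markers(mimic_suite):
    from haplomarker.pipeline import design_suite_markers
    return design_suite_markers(mimic_suite)
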