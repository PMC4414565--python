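"""Shared fixtures: tiny hand-built files and random panel factories."""

from __future__ import annotations

import numpy as np
import pytest

from elitevar.genomics_io import (
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    VariantSite,
)

# Toy chromosome (60 bp) carrying a plus-strand single-exon gene and a
# minus-strand two-exon gene; layout (1-based):
#   11-19  tx1 (+) CDS "ATGGGATGG" -> M G W
#   31-36  tx2 (-) second CDS segment (genomic "TTACAG")
#   41-46  tx2 (-) first CDS segment (genomic "GGTCAT")
# tx2 spliced CDS (5'->3') = revcomp("GGTCAT") + revcomp("TTACAG")
#                          = "ATGACC" + "CTGTAA" -> M T L *
TOY_CHR1 = (
    "AAAAAAAAAA"   # 1-10
    "ATGGGATGG"    # 11-19
    "CCCCCCCCCCC"  # 20-30
    "TTACAG"       # 31-36
    "AAAA"         # 37-40
    "GGTCAT"       # 41-46
    "AAAAAAAAAAAAAA"  # 47-60
)

TOY_GFF = """##gff-version 3
chr1\ttest\tgene\t11\t19\t.\t+\t.\tID=gene1
chr1\ttest\tmRNA\t11\t19\t.\t+\t.\tID=tx1;Parent=gene1
chr1\ttest\tCDS\t11\t19\t.\t+\t0\tID=cds1;Parent=tx1
chr1\ttest\tgene\t31\t46\t.\t-\t.\tID=gene2
chr1\ttest\tmRNA\t31\t46\t.\t-\t.\tID=tx2;Parent=gene2
chr1\ttest\tCDS\t41\t46\t.\t-\t0\tID=cds2a;Parent=tx2
chr1\ttest\tCDS\t31\t36\t.\t-\t0\tID=cds2b;Parent=tx2
"""

TINY_VCF = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tC\tT\t.\t.\t.\tGT\t./.\t0/0\t1/1
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return path


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fa"
    path.write_text(f">chr1\n{TOY_CHR1}\n")
    return path


@pytest.fixture
def toy_gff(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF)
    return path


def random_matrix(
    rng: np.random.Generator,
    n_sites: int = 50,
    n_samples: int = 8,
    missing_rate: float = 0.1,
    chroms: tuple[str, ...] = ("chr1", "chr2"),
    span: int = 10_000,
) -> GenotypeMatrix:
    """A random valid genotype matrix for property tests."""
    sites = []
    per_chrom = max(1, n_sites // len(chroms))
    for chrom in chroms:
        n = per_chrom if chrom != chroms[-1] else n_sites - per_chrom * (
            len(chroms) - 1
        )
        positions = np.sort(
            rng.choice(np.arange(1, span + 1), size=n, replace=False)
        )
        for pos in positions:
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            sites.append(VariantSite(chrom, int(pos), str(ref), str(alt)))
    geno = rng.integers(0, 3, size=(len(sites), n_samples)).astype(np.int8)
    geno[rng.random(geno.shape) < missing_rate] = MISSING
    samples = [f"S{i + 1}" for i in range(n_samples)]
    return GenotypeMatrix(sites, samples, geno)


@pytest.fixture
def small_panel():
    """A 60-site, 8-sample panel split over two populations."""
    rng = np.random.default_rng(42)
    matrix = random_matrix(rng, n_sites=60, n_samples=8)
    popmap = PopulationMap(
        {s: ("popA" if i < 4 else "popB") for i, s in enumerate(matrix.samples)}
    )
    return matrix, popmap
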