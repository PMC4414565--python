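"""Per-site allele statistics and the progressive SNP filter cascade.

The cascade has three stages, each consuming the previous stage's output:

1. remove SNPs inside annotated repetitive regions;
2. remove singleton SNPs (minor allele carried by exactly one variety)
   and SNPs in 100 bp bins where at least ``min_cnv_varieties`` samples
   report a copy number other than two;
3. remove SNPs in bins where any sample reports copy number variation,
   SNPs closer than ``min_spacing_bp`` to another SNP of the input set
   (both members of a close pair are removed), and SNPs genotyped in
   fewer than ``min_genotyped`` samples.

Because each stage only removes sites, the surviving site sets are nested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genomics_io import (
    MISSING,
    GenomicsIOError,
    GenotypeMatrix,
    IntervalSet,
    PopulationMap,
)


@dataclass
class SiteStats:
    """Allele statistics for one site over a chosen sample subset.

    ``ref_allele_freq`` is the frequency f of the reference allele among
    non-missing allele calls, f = (2*hom_ref + het) / (2*n_genotyped);
    ``maf`` = min(f, 1-f). Sites with no genotyped sample are flagged
    ``undefined`` and carry NaN frequencies.
    """

    chrom: str
    pos: int
    n_genotyped: int
    ref_allele_freq: float
    maf: float
    minor_allele_carriers: int
    undefined: bool = False


@dataclass
class FilterReport:
    """Accounting of one filter stage."""

    stage: str
    sites_in: int
    sites_out: int
    removals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.sites_out <= self.sites_in


def compute_site_stats(
    matrix: GenotypeMatrix, subset: Sequence[str] | None = None
) -> list[SiteStats]:
    """Allele statistics for every site, restricted to ``subset`` samples."""
    if subset is None:
        cols = np.arange(matrix.n_samples)
    else:
        cols = matrix.sample_indices(subset)
    geno = matrix.genotypes[:, cols]
    stats: list[SiteStats] = []
    for site, row in zip(matrix.sites, geno):
        called = row[row != MISSING]
        n = len(called)
        if n == 0:
            stats.append(
                SiteStats(site.chrom, site.pos, 0, np.nan, np.nan, 0, True)
            )
            continue
        n_hom_ref = int(np.sum(called == 0))
        n_het = int(np.sum(called == 1))
        f = (2 * n_hom_ref + n_het) / (2 * n)
        maf = min(f, 1.0 - f)
        # the minor allele is the rarer of the two; ties resolve to alt
        if f >= 0.5:
            carriers = int(np.sum((called == 1) | (called == 2)))
        else:
            carriers = int(np.sum((called == 1) | (called == 0)))
        stats.append(SiteStats(site.chrom, site.pos, n, f, maf, carriers))
    return stats


def filter_stage1(
    matrix: GenotypeMatrix, repeats: IntervalSet
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop every site located inside a repeat interval."""
    flat = repeats.flatten()
    keep = np.array(
        [not flat.contains(s.chrom, s.pos) for s in matrix.sites], dtype=bool
    )
    out = matrix.subset_sites(keep)
    report = FilterReport(
        stage="stage1_repeats",
        sites_in=matrix.n_sites,
        sites_out=out.n_sites,
        removals={"in_repeat": int((~keep).sum())},
    )
    return out, report


def filter_stage2(
    matrix: GenotypeMatrix,
    cnv_bins: "BinCopyTable",
    min_cnv_varieties: int = 3,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop singleton SNPs and SNPs in recurrently CNV-affected bins."""
    stats = compute_site_stats(matrix)
    singleton = np.array(
        [s.minor_allele_carriers == 1 and s.maf > 0 for s in stats], dtype=bool
    )
    cnv_hit = np.array(
        [
            cnv_bins.n_variant_samples(s.chrom, s.pos) >= min_cnv_varieties
            for s in matrix.sites
        ],
        dtype=bool,
    )
    drop = singleton | cnv_hit
    out = matrix.subset_sites(~drop)
    report = FilterReport(
        stage="stage2_singletons_cnv",
        sites_in=matrix.n_sites,
        sites_out=out.n_sites,
        removals={
            "singleton": int(singleton.sum()),
            f"cnv_ge_{min_cnv_varieties}_varieties": int(cnv_hit.sum()),
        },
    )
    return out, report


def _close_pair_mask(matrix: GenotypeMatrix, min_spacing_bp: int) -> np.ndarray:
    """Mask of sites having another site of the set closer than the spacing.

    Sites are sorted within chromosomes, so only adjacent neighbours need
    checking; both members of a close pair are marked.
    """
    mask = np.zeros(matrix.n_sites, dtype=bool)
    chroms = matrix.site_chroms()
    pos = matrix.positions()
    for i in range(matrix.n_sites - 1):
        if chroms[i] == chroms[i + 1] and pos[i + 1] - pos[i] < min_spacing_bp:
            mask[i] = True
            mask[i + 1] = True
    return mask


def filter_stage3(
    matrix: GenotypeMatrix,
    cnv_bins: "BinCopyTable",
    min_genotyped: int = 80,
    min_spacing_bp: int = 10,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop sites with any CNV evidence, close neighbours, or low call rate."""
    if min_genotyped > matrix.n_samples:
        raise GenomicsIOError(
            f"min_genotyped {min_genotyped} exceeds panel size "
            f"{matrix.n_samples}"
        )
    cnv_hit = np.array(
        [
            cnv_bins.n_variant_samples(s.chrom, s.pos) >= 1
            for s in matrix.sites
        ],
        dtype=bool,
    )
    close = _close_pair_mask(matrix, min_spacing_bp)
    n_genotyped = np.sum(matrix.genotypes != MISSING, axis=1)
    low_calls = n_genotyped < min_genotyped
    drop = cnv_hit | close | low_calls
    out = matrix.subset_sites(~drop)
    report = FilterReport(
        stage="stage3_high_quality",
        sites_in=matrix.n_sites,
        sites_out=out.n_sites,
        removals={
            "cnv_any_variety": int(cnv_hit.sum()),
            f"closer_than_{min_spacing_bp}bp": int(close.sum()),
            f"genotyped_lt_{min_genotyped}": int(low_calls.sum()),
        },
    )
    return out, report


def run_filter_cascade(
    matrix: GenotypeMatrix,
    repeats: IntervalSet,
    cnv_bins: "BinCopyTable",
    min_cnv_varieties: int = 3,
    min_genotyped: int = 80,
    min_spacing_bp: int = 10,
) -> tuple[list[GenotypeMatrix], list[FilterReport]]:
    """Apply all three stages progressively; returns matrices and reports."""
    m1, r1 = filter_stage1(matrix, repeats)
    m2, r2 = filter_stage2(m1, cnv_bins, min_cnv_varieties)
    m3, r3 = filter_stage3(m2, cnv_bins, min_genotyped, min_spacing_bp)
    return [m1, m2, m3], [r1, r2, r3]


def count_private_snps(
    matrix: GenotypeMatrix, popmap: PopulationMap
) -> dict[str, int]:
    """Count SNPs polymorphic in exactly one population.

    A site is private to population P when both alleles are observed
    within P and exactly one allele is observed in every other
    population. Sites monomorphic everywhere, polymorphic in several
    populations, or unobserved in some population count for none.
    """
    for sample in matrix.samples:
        if sample not in popmap:
            raise GenomicsIOError(f"sample {sample!r} not in population map")
    pops = popmap.populations()
    pop_cols = {
        p: matrix.sample_indices(
            [s for s in matrix.samples if popmap[s] == p]
        )
        for p in pops
    }
    counts = {p: 0 for p in pops}
    geno = matrix.genotypes
    for i in range(matrix.n_sites):
        poly_pops: list[str] = []
        mono_everywhere_else = True
        for p in pops:
            row = geno[i, pop_cols[p]]
            called = row[row != MISSING]
            if len(called) == 0:
                n_alleles = 0
            else:
                has_ref = bool(np.any((called == 0) | (called == 1)))
                has_alt = bool(np.any((called == 2) | (called == 1)))
                n_alleles = int(has_ref) + int(has_alt)
            if n_alleles == 2:
                poly_pops.append(p)
            elif n_alleles != 1:
                mono_everywhere_else = False
        if len(poly_pops) == 1 and mono_everywhere_else:
            counts[poly_pops[0]] += 1
    return counts


def maf_spectrum(
    stats: Sequence[SiteStats], bin_edges: Sequence[float]
) -> tuple[np.ndarray, int]:
    """Histogram minor allele frequencies into the given bins.

    Bins are left-closed right-open; the last bin is closed on both
    sides (``numpy.histogram`` semantics). Returns (counts, n_skipped)
    where ``n_skipped`` counts sites with undefined MAF.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    mafs = np.array([s.maf for s in stats if not s.undefined])
    skipped = sum(1 for s in stats if s.undefined)
    counts, _ = np.histogram(mafs, bins=edges)
    return counts, skipped
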