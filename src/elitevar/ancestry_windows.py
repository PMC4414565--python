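"""Window-based local ancestry assignment against population consensus calls.

The procedure has three steps:

1. *Panel selection.* Reference-allele frequencies are computed per
   population and a SNP is retained when two populations differ in
   frequency by at least 0.6 — these SNPs discriminate at least one
   population pair.
2. *Consensus genotypes.* Each population gets a pseudo-sample holding
   the homozygous genotype of its majority allele, or a heterozygous
   call when the within-population minor allele frequency exceeds 0.4.
3. *Window scoring.* Panel SNPs are cut into consecutive non-overlapping
   windows of 50 per chromosome. A sample's window is scored against
   every population consensus: per SNP, +1 if either call is
   heterozygous, +2 if both are homozygous and equal, -2 if both are
   homozygous and different, 0 if either is missing. A window is
   assigned when at least 40 SNPs are genotyped and the best score is at
   least 50; the assignment is unique when the best score beats the
   runner-up by at least 10. The maximum score of 100 is reached exactly
   when the two windows are equal, fully homozygous and fully genotyped.

Self-comparison of the population consensus vectors marks windows where
population pairs are too conserved to be told apart.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomics_io import (
    MISSING,
    GenomicsIOError,
    GenotypeMatrix,
    PopulationMap,
    VariantSite,
)


@dataclass
class DiscriminatingPanel:
    """Discriminating SNPs with per-population frequencies and consensus.

    ``frequencies`` holds the reference-allele frequency per retained
    site and population (NaN where no member is genotyped);
    ``consensus`` the population pseudo-genotypes in the usual codes.
    """

    sites: list[VariantSite]
    populations: list[str]
    frequencies: np.ndarray  # (site, population), NaN where undefined
    consensus: np.ndarray | None = None  # (site, population) codes
    min_freq_diff: float = 0.6

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def _population_frequencies(
    matrix: GenotypeMatrix, popmap: PopulationMap
) -> tuple[list[str], np.ndarray]:
    pops = popmap.populations()
    freqs = np.full((matrix.n_sites, len(pops)), np.nan)
    for k, p in enumerate(pops):
        members = [s for s in matrix.samples if s in popmap and popmap[s] == p]
        if not members:
            raise GenomicsIOError(f"population {p!r} has no samples")
        cols = matrix.sample_indices(members)
        sub = matrix.genotypes[:, cols]
        called = sub != MISSING
        n = called.sum(axis=1)
        ref_alleles = np.where(called, 2 - sub, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[:, k] = np.where(n > 0, ref_alleles / (2 * n), np.nan)
    return pops, freqs


def select_discriminating_snps(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    min_freq_diff: float = 0.6,
) -> tuple[DiscriminatingPanel, GenotypeMatrix]:
    """Retain SNPs where two population frequencies differ by >= threshold.

    Returns the panel (frequencies filled, consensus empty) and the
    genotype matrix restricted to the retained sites.
    """
    pops, freqs = _population_frequencies(matrix, popmap)
    keep = np.zeros(matrix.n_sites, dtype=bool)
    for i in range(matrix.n_sites):
        f = freqs[i]
        defined = f[~np.isnan(f)]
        if defined.size >= 2 and defined.max() - defined.min() >= min_freq_diff:
            keep[i] = True
    sub = matrix.subset_sites(keep)
    panel = DiscriminatingPanel(
        sites=list(sub.sites),
        populations=pops,
        frequencies=freqs[keep],
        min_freq_diff=min_freq_diff,
    )
    return panel, sub


def build_population_consensus(
    panel_matrix: GenotypeMatrix,
    popmap: PopulationMap,
    panel: DiscriminatingPanel,
    het_maf_threshold: float = 0.4,
) -> DiscriminatingPanel:
    """Fill per-population consensus genotypes into the panel.

    The consensus is the homozygous genotype of the majority allele, a
    heterozygous call when the within-population MAF strictly exceeds
    the threshold, and missing when no member is genotyped.
    """
    pops, freqs = _population_frequencies(panel_matrix, popmap)
    if pops != panel.populations:
        raise GenomicsIOError("population map does not match the panel")
    consensus = np.full(freqs.shape, MISSING, dtype=np.int8)
    defined = ~np.isnan(freqs)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freqs, 1.0 - freqs)
        hom = np.where(freqs >= 0.5, 0, 2).astype(np.int8)
    consensus[defined] = np.where(
        maf[defined] > het_maf_threshold, 1, hom[defined]
    ).astype(np.int8)
    panel.consensus = consensus
    panel.frequencies = freqs
    return panel


def score_genotype_window(g_sample: np.ndarray, g_pop: np.ndarray) -> int:
    """Score a pair of genotype vectors under the per-SNP ancestry rule.

    Per SNP, with rule precedence missing > heterozygous > equality:
    0 if either call is missing, +1 if at least one call is
    heterozygous, +2 if both are homozygous and equal, -2 if both are
    homozygous and different.
    """
    g_sample = np.asarray(g_sample)
    g_pop = np.asarray(g_pop)
    if g_sample.shape != g_pop.shape:
        raise ValueError(
            f"length mismatch: {g_sample.shape} vs {g_pop.shape}"
        )
    usable = (g_sample != MISSING) & (g_pop != MISSING)
    any_het = usable & ((g_sample == 1) | (g_pop == 1))
    both_hom = usable & ~any_het
    equal_hom = both_hom & (g_sample == g_pop)
    diff_hom = both_hom & (g_sample != g_pop)
    return int(any_het.sum() + 2 * equal_hom.sum() - 2 * diff_hom.sum())


@dataclass(frozen=True)
class WindowAssignment:
    """Best and runner-up population for one sample in one SNP window."""

    sample: str
    chrom: str
    window_index: int
    first_pos: int
    last_pos: int
    n_genotyped: int
    best: str
    best_score: int
    second: str
    second_score: int
    status: str  # "unique", "ambiguous" or "unassigned"


def _windows_per_chrom(
    sites: Sequence[VariantSite], window_snps: int
) -> list[tuple[str, int, np.ndarray]]:
    """Consecutive non-overlapping full windows of panel sites per chromosome.

    Returns (chrom, window_index, site_row_indices); window numbering
    restarts on each chromosome and trailing partial windows are dropped.
    """
    out: list[tuple[str, int, np.ndarray]] = []
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        by_chrom.setdefault(s.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        idx = np.asarray(idx)
        n_windows = len(idx) // window_snps
        for w in range(n_windows):
            out.append((chrom, w, idx[w * window_snps : (w + 1) * window_snps]))
    return out


def assign_windows(
    panel_matrix: GenotypeMatrix,
    panel: DiscriminatingPanel,
    window_snps: int = 50,
    min_genotyped: int = 40,
    min_score: int = 50,
    unique_margin: int = 10,
) -> list[WindowAssignment]:
    """Assign a population to every sample in every full SNP window.

    A window is unassigned when fewer than ``min_genotyped`` SNPs are
    genotyped in the sample or the best score falls below ``min_score``;
    otherwise it is unique when the best score exceeds the runner-up by
    at least ``unique_margin``, else ambiguous with both populations
    reported. Score ties rank populations in label order.
    """
    if window_snps < 1:
        raise GenomicsIOError("window_snps must be >= 1")
    if panel.consensus is None:
        raise GenomicsIOError("panel has no consensus genotypes")
    if panel.sites != panel_matrix.sites:
        raise GenomicsIOError("panel sites do not match the matrix")
    pops = panel.populations
    assignments: list[WindowAssignment] = []
    for chrom, w, rows in _windows_per_chrom(panel.sites, window_snps):
        cons = panel.consensus[rows]
        first_pos = panel.sites[rows[0]].pos
        last_pos = panel.sites[rows[-1]].pos
        geno = panel_matrix.genotypes[rows]
        for j, sample in enumerate(panel_matrix.samples):
            g = geno[:, j]
            n_geno = int((g != MISSING).sum())
            scores = [score_genotype_window(g, cons[:, k])
                      for k in range(len(pops))]
            order = sorted(range(len(pops)), key=lambda k: (-scores[k], pops[k]))
            b, s = order[0], order[1]
            if n_geno < min_genotyped or scores[b] < min_score:
                status = "unassigned"
            elif scores[b] - scores[s] >= unique_margin:
                status = "unique"
            else:
                status = "ambiguous"
            assignments.append(
                WindowAssignment(
                    sample=sample, chrom=chrom, window_index=w,
                    first_pos=first_pos, last_pos=last_pos,
                    n_genotyped=n_geno,
                    best=pops[b], best_score=scores[b],
                    second=pops[s], second_score=scores[s],
                    status=status,
                )
            )
    return assignments


@dataclass(frozen=True)
class PairDiscriminability:
    """Consensus-vs-consensus score of one population pair in one window."""

    chrom: str
    window_index: int
    pop_a: str
    pop_b: str
    score: int
    non_discriminative: bool


def population_self_discrimination(
    panel: DiscriminatingPanel,
    window_snps: int = 50,
    flag_margin: int = 10,
) -> list[PairDiscriminability]:
    """Score population consensus vectors against each other per window.

    A pair is flagged non-discriminative in a window when its score is
    within ``flag_margin`` of the maximum (2 per SNP) — such windows are
    too conserved between the two populations to separate them.
    """
    if panel.consensus is None:
        raise GenomicsIOError("panel has no consensus genotypes")
    pops = panel.populations
    max_score = 2 * window_snps
    out: list[PairDiscriminability] = []
    for chrom, w, rows in _windows_per_chrom(panel.sites, window_snps):
        cons = panel.consensus[rows]
        for a in range(len(pops)):
            for b in range(a + 1, len(pops)):
                score = score_genotype_window(cons[:, a], cons[:, b])
                out.append(
                    PairDiscriminability(
                        chrom=chrom, window_index=w,
                        pop_a=pops[a], pop_b=pops[b], score=score,
                        non_discriminative=score >= max_score - flag_margin,
                    )
                )
    return out


def assignments_to_frame(assignments: Sequence[WindowAssignment]) -> pd.DataFrame:
    """Tabulate window assignments (sample, chrom, window, spans, scores)."""
    return pd.DataFrame(
        [
            {
                "sample": a.sample, "chrom": a.chrom, "window": a.window_index,
                "start": a.first_pos, "end": a.last_pos,
                "n_genotyped": a.n_genotyped,
                "best": a.best, "score": a.best_score,
                "second": a.second, "second_score": a.second_score,
                "status": a.status,
            }
            for a in assignments
        ]
    )


def write_panel_vcf(
    panel_matrix: GenotypeMatrix, panel: DiscriminatingPanel, path: str | Path
) -> None:
    """Write the panel with one pseudo-sample column per population."""
    from .genomics_io import write_vcf_genotypes

    if panel.consensus is None:
        raise GenomicsIOError("panel has no consensus genotypes")
    combined = GenotypeMatrix(
        panel.sites,
        list(panel_matrix.samples) + [f"POP_{p}" for p in panel.populations],
        np.hstack([panel_matrix.genotypes, panel.consensus]),
    )
    write_vcf_genotypes(combined, path)
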