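"""Pairwise diversity, diversity-ratio Fst, distance matrices and dN/dS.

Diversity between two samples is the number of nucleotide changes over a
region, computed on genotype dosages: at each site genotyped in both
samples, |d1 - d2| / 2 with dosage d in {0, 1, 2}. Opposite homozygotes
contribute one difference, a heterozygote against a homozygote one half.
Windowed and per-gene diversity average this count over sample pairs and
normalise by region length in kilobases. Fst between groups is one minus
the ratio of the mean within-group diversity to the between-group
diversity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .effects import EffectAnnotation
from .genomics_io import MISSING, GenotypeMatrix, PopulationMap


def pairwise_difference_count(g1: np.ndarray, g2: np.ndarray) -> float:
    """Number of nucleotide changes between two genotype vectors.

    Sums |dosage1 - dosage2| / 2 over sites where both calls are
    non-missing.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError(f"length mismatch: {g1.shape} vs {g2.shape}")
    both = (g1 != MISSING) & (g2 != MISSING)
    return float(np.abs(g1[both].astype(float) - g2[both]).sum() / 2)


def _pair_mean_differences(geno: np.ndarray, cols_a: np.ndarray,
                           cols_b: np.ndarray | None = None) -> float:
    """Mean pairwise difference count over sample pairs.

    Within-group when ``cols_b`` is None (unordered pairs from
    ``cols_a``), between-group otherwise (all cross pairs).
    """
    d = geno.astype(float)
    d[geno == MISSING] = np.nan
    if cols_b is None:
        pairs = list(combinations(cols_a, 2))
    else:
        pairs = [(i, j) for i in cols_a for j in cols_b]
    if not pairs:
        return float("nan")
    total = 0.0
    for i, j in pairs:
        diff = np.abs(d[:, i] - d[:, j]) / 2
        total += np.nansum(diff)
    return total / len(pairs)


def windowed_diversity(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    window_bp: int = 100_000,
    groups: Sequence[str] | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Average pairwise differences per kbp in fixed windows.

    Returns one row per window with within-group diversity for every
    group, between-group diversity and Fst for every declared pair, and
    the overall diversity across all listed samples. Groups with fewer
    than two members yield NaN within-diversity.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if groups is None:
        groups = popmap.populations()
    if pairs is None:
        pairs = []
    group_cols = {
        g: matrix.sample_indices(
            [s for s in matrix.samples if s in popmap and popmap[s] == g]
        )
        for g in groups
    }
    for g, cols in group_cols.items():
        if cols.size == 0:
            raise ValueError(f"group {g!r} has no samples in the matrix")
    all_cols = np.unique(np.concatenate(list(group_cols.values())))
    kbp = window_bp / 1000

    chroms = matrix.site_chroms()
    pos = matrix.positions()
    rows = []
    for chrom in matrix.chroms:
        on_chrom = chroms == chrom
        if chrom_lengths is not None:
            length = chrom_lengths[chrom]
        else:
            length = int(pos[on_chrom].max())
        n_windows = -(-length // window_bp)
        for w in range(n_windows):
            start = w * window_bp + 1
            end = min((w + 1) * window_bp, length)
            in_win = on_chrom & (pos >= start) & (pos <= end)
            sub = matrix.genotypes[in_win]
            row: dict[str, object] = {"chrom": chrom, "start": start, "end": end}
            for g in groups:
                row[f"div_{g}"] = (
                    _pair_mean_differences(sub, group_cols[g]) / kbp
                )
            for p1, p2 in pairs:
                between = (
                    _pair_mean_differences(sub, group_cols[p1], group_cols[p2])
                    / kbp
                )
                row[f"div_between_{p1}_{p2}"] = between
                row[f"fst_{p1}_{p2}"] = fst_from_diversity(
                    [row[f"div_{p1}"], row[f"div_{p2}"]], between
                )
            row["div_overall"] = _pair_mean_differences(sub, all_cols) / kbp
            rows.append(row)
    return pd.DataFrame(rows)


def gene_diversity(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    genes: Sequence[tuple[str, str, int, int]],
    groups: Sequence[str] | None = None,
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Pairwise-difference diversity per gene span, per group.

    ``genes`` holds (gene_id, chrom, start, end) with 1-based inclusive
    spans. When ``categories`` maps gene ids to category labels, a
    second frame of per-category unweighted means is attached as the
    ``.attrs['category_means']`` entry.
    """
    if groups is None:
        groups = popmap.populations()
    group_cols = {
        g: matrix.sample_indices(
            [s for s in matrix.samples if s in popmap and popmap[s] == g]
        )
        for g in groups
    }
    chroms = matrix.site_chroms()
    pos = matrix.positions()
    rows = []
    for gene_id, chrom, start, end in genes:
        if end < start:
            raise ValueError(f"gene {gene_id}: end < start")
        length_kbp = (end - start + 1) / 1000
        if length_kbp == 0:
            raise ValueError(f"gene {gene_id} has zero length")
        in_gene = (chroms == chrom) & (pos >= start) & (pos <= end)
        sub = matrix.genotypes[in_gene]
        row: dict[str, object] = {"gene": gene_id, "chrom": chrom,
                                  "start": start, "end": end}
        for g in groups:
            row[f"div_{g}"] = _pair_mean_differences(sub, group_cols[g]) / length_kbp
        rows.append(row)
    out = pd.DataFrame(rows)
    if categories is not None and not out.empty:
        out["category"] = out["gene"].map(categories)
        means = out.groupby("category")[
            [f"div_{g}" for g in groups]
        ].mean()
        out.attrs["category_means"] = means
    return out


def fst_from_diversity(
    within: Sequence[float],
    between: float,
    weights: Sequence[float] | None = None,
) -> float:
    """Fst as one minus mean within-group over between-group diversity.

    The default is the unweighted mean of the within-group diversities;
    ``weights`` (e.g. sample sizes or pair counts) selects a weighted
    mean instead. Returns NaN when the between-group diversity is zero
    or any input is undefined.
    """
    within = np.asarray(within, dtype=float)
    if np.any(within < 0):
        raise ValueError("within-group diversities must be >= 0")
    if between == 0 or np.isnan(between) or np.any(np.isnan(within)):
        return float("nan")
    mean_within = np.average(within, weights=weights)
    return 1.0 - mean_within / between


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a zero diagonal."""

    ids: list[str]
    values: np.ndarray
    #: (i, j) pairs that shared no genotyped site (distance reported as 0)
    no_overlap_pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.values.shape == (n, n)
        assert np.allclose(self.values, self.values.T)
        assert np.allclose(np.diag(self.values), 0)

    def to_phylip(self, path: str | Path) -> None:
        """Write in square PHYLIP distance-matrix format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{name:<10s} {row}\n")

    def to_nexus(self, path: str | Path) -> None:
        """Write as a NEXUS DISTANCES block."""
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\n")
            fh.write("BEGIN TAXA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(self.ids)};\n")
            fh.write("  TAXLABELS " + " ".join(self.ids) + ";\nEND;\n\n")
            fh.write("BEGIN DISTANCES;\n")
            fh.write("  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\n  MATRIX\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"    {name} {row}\n")
            fh.write("  ;\nEND;\n")


def pairwise_distance_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Proportion-of-differences distance between every pair of samples.

    d(i, j) is the pairwise difference count divided by the number of
    sites genotyped in both samples; pairs sharing no genotyped site get
    distance 0 and are flagged.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    geno = matrix.genotypes
    d = geno.astype(float)
    d[geno == MISSING] = np.nan
    n = matrix.n_samples
    values = np.zeros((n, n))
    flagged: list[tuple[str, str]] = []
    for i, j in combinations(range(n), 2):
        both = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
        n_shared = int(both.sum())
        if n_shared == 0:
            flagged.append((matrix.samples[i], matrix.samples[j]))
            continue
        diff = np.abs(d[both, i] - d[both, j]).sum() / 2
        values[i, j] = values[j, i] = diff / n_shared
    return DistanceMatrix(list(matrix.samples), values, flagged)


def dnds_summary(
    effects_per_site: Sequence[Sequence[EffectAnnotation]],
    polymorphic_mask: Sequence[bool] | None = None,
) -> tuple[float, int]:
    """Average per-transcript dN/dS over the polymorphic site set.

    For every transcript, the ratio of non-synonymous (missense plus
    nonsense) to synonymous polymorphic sites is computed as a raw count
    ratio; transcripts without a synonymous site are excluded. Returns
    the unweighted mean of per-transcript ratios and the number of
    qualifying transcripts ((NaN, 0) when none qualifies).
    """
    if polymorphic_mask is None:
        polymorphic_mask = [True] * len(effects_per_site)
    syn: dict[str, int] = {}
    nonsyn: dict[str, int] = {}
    for anns, poly in zip(effects_per_site, polymorphic_mask):
        if not poly:
            continue
        for a in anns:
            if a.transcript_id is None:
                continue
            if a.effect == "synonymous":
                syn[a.transcript_id] = syn.get(a.transcript_id, 0) + 1
                nonsyn.setdefault(a.transcript_id, 0)
            elif a.effect in ("missense", "nonsense"):
                nonsyn[a.transcript_id] = nonsyn.get(a.transcript_id, 0) + 1
                syn.setdefault(a.transcript_id, 0)
    ratios = [
        nonsyn[t] / syn[t] for t in syn if syn[t] > 0
    ]
    if not ratios:
        return float("nan"), 0
    return float(np.mean(ratios)), len(ratios)
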