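"""Copy-number variation on fixed-width genomic bins.

Per-sample CNV calls of arbitrary length are projected onto non-overlapping
bins (100 bp by default) tiling each chromosome: a bin takes a sample's
event copy number when the event covers the bin's midpoint, and the normal
diploid copy number of two otherwise. Recurrence within populations, the
copy-number class histogram, and the characteristic-CNV rule between two
populations all operate on this table.

A CNV on a bin is *characteristic* for population P1 relative to P2 when,
with x the fraction of samples reporting the event and n the mean copy
number, either x1 - x2 > 0.5, or x1 > 0.5 and n1 - n2 > 2 (all strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genomics_io import (
    CnvCall,
    GenomicsIOError,
    Interval,
    IntervalSet,
    PopulationMap,
)

NORMAL_COPY = 2.0


class BinCopyTable:
    """Per-bin, per-sample copy numbers over a tiled genome.

    Bins tile each chromosome without overlap; the last bin of a
    chromosome may be shorter than ``bin_width``. Copy numbers default
    to the diploid normal of 2.
    """

    def __init__(
        self,
        genome: Mapping[str, int],
        samples: Sequence[str],
        bin_width: int = 100,
    ) -> None:
        if bin_width <= 0:
            raise GenomicsIOError("bin width must be positive")
        self.genome = dict(genome)
        self.samples = list(samples)
        self.bin_width = bin_width
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}
        self._offsets: dict[str, int] = {}
        self._n_bins: dict[str, int] = {}
        total = 0
        for chrom in self.genome:
            n = -(-self.genome[chrom] // bin_width)  # ceil division
            self._offsets[chrom] = total
            self._n_bins[chrom] = n
            total += n
        self.total_bins = total
        self.copy = np.full((total, len(self.samples)), NORMAL_COPY)

    # -- bin geometry -------------------------------------------------------

    def n_bins(self, chrom: str) -> int:
        return self._n_bins[chrom]

    def bin_span(self, chrom: str, bin_index: int) -> tuple[int, int]:
        """1-based inclusive (start, end) of a bin, clipped to the chromosome."""
        start = bin_index * self.bin_width + 1
        end = min((bin_index + 1) * self.bin_width, self.genome[chrom])
        return start, end

    def bin_midpoint(self, chrom: str, bin_index: int) -> float:
        start, end = self.bin_span(chrom, bin_index)
        return (start + end) / 2

    def bin_of(self, chrom: str, pos: int) -> int:
        if not 1 <= pos <= self.genome[chrom]:
            raise GenomicsIOError(f"position {chrom}:{pos} outside chromosome")
        return (pos - 1) // self.bin_width

    def row(self, chrom: str, bin_index: int) -> np.ndarray:
        return self.copy[self._offsets[chrom] + bin_index]

    def iter_bins(self):
        for chrom in self.genome:
            for b in range(self._n_bins[chrom]):
                yield chrom, b

    # -- queries used by the SNP filter cascade -----------------------------

    def n_variant_samples(self, chrom: str, pos: int) -> int:
        """Number of samples whose copy number differs from 2 in the bin at pos."""
        if chrom not in self.genome or not 1 <= pos <= self.genome[chrom]:
            return 0
        row = self.row(chrom, self.bin_of(chrom, pos))
        return int(np.sum(row != NORMAL_COPY))


def bin_copy_numbers(
    cnv_calls: IntervalSet,
    genome: Mapping[str, int],
    samples: Sequence[str] | None = None,
    bin_width: int = 100,
) -> BinCopyTable:
    """Project CNV call intervals onto fixed-width bins.

    A bin takes a sample's event copy number iff the event covers the
    bin's midpoint. When several events of one sample cover the same
    midpoint, the copy number furthest from 2 wins; ties resolve to the
    lower copy number.
    """
    if samples is None:
        samples = sorted({iv.payload.sample for iv in cnv_calls})
    table = BinCopyTable(genome, samples, bin_width)
    for iv in cnv_calls:
        call = iv.payload
        if not isinstance(call, CnvCall):
            raise GenomicsIOError("CNV intervals must carry CnvCall payloads")
        if iv.chrom not in table.genome:
            raise GenomicsIOError(f"unknown chromosome {iv.chrom!r} in CNV call")
        if iv.end > table.genome[iv.chrom]:
            raise GenomicsIOError(
                f"CNV event {iv.chrom}:{iv.start}-{iv.end} beyond chromosome "
                f"end {table.genome[iv.chrom]}"
            )
        j = table._sample_idx[call.sample]
        first_bin = table.bin_of(iv.chrom, iv.start)
        last_bin = table.bin_of(iv.chrom, iv.end)
        for b in range(first_bin, last_bin + 1):
            mid = table.bin_midpoint(iv.chrom, b)
            if not iv.start <= mid <= iv.end:
                continue
            row = table.row(iv.chrom, b)
            current = row[j]
            new = call.copy_number
            d_cur = abs(current - NORMAL_COPY)
            d_new = abs(new - NORMAL_COPY)
            if d_new > d_cur or (d_new == d_cur and new < current):
                row[j] = new
    return table


@dataclass
class RecurrenceTable:
    """Per-bin, per-population CNV recurrence.

    For every bin and population: the fraction of members with copy > 2
    (``dup_fraction``), the fraction with copy < 2 (``del_fraction``),
    and the mean copy number over all members (non-carriers count as 2).
    Arrays are indexed (bin, population).
    """

    bins: BinCopyTable
    populations: list[str]
    dup_fraction: np.ndarray
    del_fraction: np.ndarray
    mean_copy: np.ndarray
    keep_mask: np.ndarray | None = None  # (bin, population) after filtering

    def pop_index(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise GenomicsIOError(f"unknown population {population!r}") from None


def population_recurrence(
    bins: BinCopyTable, popmap: PopulationMap
) -> RecurrenceTable:
    """Summarise bin copy numbers per population."""
    for sample in bins.samples:
        if sample not in popmap:
            raise GenomicsIOError(f"sample {sample!r} not in population map")
    pops = popmap.populations()
    cols = {}
    for p in pops:
        members = [s for s in bins.samples if popmap[s] == p]
        if not members:
            raise GenomicsIOError(f"population {p!r} has no samples")
        cols[p] = np.array([bins._sample_idx[s] for s in members])
    dup = np.empty((bins.total_bins, len(pops)))
    dele = np.empty_like(dup)
    mean = np.empty_like(dup)
    for k, p in enumerate(pops):
        sub = bins.copy[:, cols[p]]
        dup[:, k] = np.mean(sub > NORMAL_COPY, axis=1)
        dele[:, k] = np.mean(sub < NORMAL_COPY, axis=1)
        mean[:, k] = np.mean(sub, axis=1)
    return RecurrenceTable(bins, pops, dup, dele, mean)


def filter_common_nonrepeat_bins(
    rec: RecurrenceTable,
    repeats: IntervalSet,
    min_fraction: float = 0.5,
) -> RecurrenceTable:
    """Keep, per population, common CNV bins outside repeats.

    A bin is kept for a population when its midpoint lies outside every
    repeat interval and at least ``min_fraction`` of the population's
    members report a duplication, or at least that fraction report a
    deletion (bins reported "in less than half of the samples" are
    removed, so exactly half is kept).
    """
    flat = repeats.flatten()
    bins = rec.bins
    in_repeat = np.zeros(bins.total_bins, dtype=bool)
    for i, (chrom, b) in enumerate(bins.iter_bins()):
        in_repeat[i] = flat.contains(chrom, bins.bin_midpoint(chrom, b))
    common = (rec.dup_fraction >= min_fraction) | (
        rec.del_fraction >= min_fraction
    )
    keep = common & ~in_repeat[:, None]
    return RecurrenceTable(
        bins=bins,
        populations=rec.populations,
        dup_fraction=rec.dup_fraction,
        del_fraction=rec.del_fraction,
        mean_copy=rec.mean_copy,
        keep_mask=keep,
    )


def copy_number_histogram(
    rec: RecurrenceTable,
    classes: Sequence[int] = (0, 1, 3, 4),
) -> dict[str, dict[str, int]]:
    """Count retained bins per population by rounded mean copy number.

    The last class is open-ended ("4+" by default); the normal copy
    number of two is excluded. Mean copies are rounded half away from
    zero. Uses ``keep_mask`` when present, else all bins with a
    non-normal rounded mean.
    """
    classes = sorted(classes)
    top = classes[-1]
    labels = [str(c) for c in classes[:-1]] + [f"{top}+"]
    out: dict[str, dict[str, int]] = {}
    rounded = np.floor(rec.mean_copy + 0.5).astype(int)
    for k, p in enumerate(rec.populations):
        counts = {lab: 0 for lab in labels}
        if rec.keep_mask is not None:
            idx = np.nonzero(rec.keep_mask[:, k])[0]
        else:
            idx = np.nonzero(rounded[:, k] != int(NORMAL_COPY))[0]
        for i in idx:
            c = rounded[i, k]
            if c == int(NORMAL_COPY):
                continue
            if c >= top:
                counts[f"{top}+"] += 1
            elif c in classes:
                counts[str(c)] += 1
        out[p] = counts
    return out


@dataclass(frozen=True)
class CharacteristicCall:
    """One bin called characteristic for P1 relative to P2."""

    chrom: str
    bin_index: int
    start: int
    end: int
    direction: str
    p1: str
    p2: str
    x1: float
    x2: float
    n1: float
    n2: float
    rule: str  # "frequency", "copy-number" or "both"


def characteristic_cnv_bins(
    rec: RecurrenceTable,
    p1: str,
    p2: str,
    direction: str,
    freq_gap: float = 0.5,
    freq_floor: float = 0.5,
    copy_gap: float = 2.0,
) -> list[CharacteristicCall]:
    """Call bins whose CNV is characteristic for ``p1`` relative to ``p2``.

    With x the event fraction (duplications or deletions per
    ``direction``) and n the mean copy number, a bin fires when
    x1 - x2 > freq_gap, or x1 > freq_floor and n1 - n2 > copy_gap.
    All comparisons are strict, so boundary values do not fire.
    """
    if p1 == p2:
        raise GenomicsIOError("p1 and p2 must differ")
    if direction not in ("dup", "del"):
        raise GenomicsIOError(f"direction must be 'dup' or 'del', got {direction!r}")
    k1, k2 = rec.pop_index(p1), rec.pop_index(p2)
    frac = rec.dup_fraction if direction == "dup" else rec.del_fraction
    x1s, x2s = frac[:, k1], frac[:, k2]
    n1s, n2s = rec.mean_copy[:, k1], rec.mean_copy[:, k2]
    freq_rule = (x1s - x2s) > freq_gap
    # n1 - n2 as printed; in practice this branch only fires for duplications
    copy_rule = (x1s > freq_floor) & ((n1s - n2s) > copy_gap)
    calls: list[CharacteristicCall] = []
    fired = np.nonzero(freq_rule | copy_rule)[0]
    flat_index = {
        i: (chrom, b) for i, (chrom, b) in enumerate(rec.bins.iter_bins())
    }
    for i in fired:
        chrom, b = flat_index[int(i)]
        start, end = rec.bins.bin_span(chrom, b)
        if freq_rule[i] and copy_rule[i]:
            rule = "both"
        elif freq_rule[i]:
            rule = "frequency"
        else:
            rule = "copy-number"
        calls.append(
            CharacteristicCall(
                chrom=chrom, bin_index=b, start=start, end=end,
                direction=direction, p1=p1, p2=p2,
                x1=float(x1s[i]), x2=float(x2s[i]),
                n1=float(n1s[i]), n2=float(n2s[i]), rule=rule,
            )
        )
    return calls
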