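"""Readers, writers and the in-memory data model for the pipeline.

All internal coordinates are 1-based inclusive (the VCF/GFF convention).
BED input, which is 0-based half-open, is converted at the boundary and
never kept in its native convention. Chromosome names are matched by exact
string equality; no ``chr`` prefix aliasing is performed.

Genotypes are encoded per sample as small integers:

====  ==========================
code  meaning
====  ==========================
0     homozygous reference
1     heterozygous
2     homozygous alternative
-1    missing (``MISSING``)
====  ==========================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from cyvcf2 import VCF
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Genotype code for a missing call.
MISSING: int = -1

_VALID_BASES = frozenset("ACGT")


class GenomicsIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True, order=True)
class VariantSite:
    """A biallelic SNP site: one reference and one alternative nucleotide."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise GenomicsIOError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele not in _VALID_BASES or self.alt_allele not in _VALID_BASES:
            raise GenomicsIOError(
                f"alleles must be single nucleotides in ACGT: "
                f"{self.ref_allele!r}/{self.alt_allele!r} at {self.chrom}:{self.pos}"
            )
        if self.ref_allele == self.alt_allele:
            raise GenomicsIOError(
                f"ref and alt alleles identical at {self.chrom}:{self.pos}"
            )


class GenotypeMatrix:
    """Sites x samples matrix of biallelic SNP genotype codes.

    Parameters
    ----------
    sites
        Ordered :class:`VariantSite` records, strictly sorted by position
        within each chromosome (chromosome blocks are contiguous).
    samples
        Ordered unique sample identifiers.
    genotypes
        Integer array of shape ``(len(sites), len(samples))`` with values
        in ``{0, 1, 2, MISSING}``.
    """

    def __init__(
        self,
        sites: Sequence[VariantSite],
        samples: Sequence[str],
        genotypes: np.ndarray,
    ) -> None:
        self.sites: list[VariantSite] = list(sites)
        self.samples: list[str] = list(samples)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        if self.genotypes.size == 0:
            self.genotypes = self.genotypes.reshape(len(self.sites), len(self.samples))
        self._validate()
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}

    def _validate(self) -> None:
        n_sites, n_samples = len(self.sites), len(self.samples)
        if self.genotypes.shape != (n_sites, n_samples):
            raise GenomicsIOError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{n_sites} sites x {n_samples} samples"
            )
        if len(set(self.samples)) != n_samples:
            raise GenomicsIOError("sample ids are not unique")
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.genotypes[~valid][0]
            raise GenomicsIOError(f"invalid genotype code {bad}")
        seen_chroms: set[str] = set()
        prev_chrom: str | None = None
        prev_pos = 0
        for s in self.sites:
            if s.chrom != prev_chrom:
                if s.chrom in seen_chroms:
                    raise GenomicsIOError(
                        f"chromosome {s.chrom} split into non-contiguous blocks"
                    )
                seen_chroms.add(s.chrom)
                prev_chrom, prev_pos = s.chrom, 0
            if s.pos <= prev_pos:
                raise GenomicsIOError(
                    f"sites not strictly sorted at {s.chrom}:{s.pos}"
                )
            prev_pos = s.pos

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chroms(self) -> list[str]:
        """Chromosomes in order of first appearance."""
        out: list[str] = []
        for s in self.sites:
            if not out or out[-1] != s.chrom:
                out.append(s.chrom)
        return out

    def sample_indices(self, subset: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._sample_idx[s] for s in subset], dtype=int)
        except KeyError as exc:
            raise GenomicsIOError(f"unknown sample {exc.args[0]!r}") from None

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Return a matrix restricted to sites where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        sites = [s for s, keep in zip(self.sites, mask) if keep]
        return GenotypeMatrix(sites, self.samples, self.genotypes[mask])

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def site_chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites], dtype=object)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.samples == other.samples
            and np.array_equal(self.genotypes, other.genotypes)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_sites} sites x {self.n_samples} samples)"


class PopulationMap:
    """Assignment of sample ids to population labels."""

    def __init__(self, assignments: Mapping[str, str]) -> None:
        for sample in assignments:
            if not sample:
                raise GenomicsIOError("empty sample id in population map")
        self.assignments: dict[str, str] = dict(assignments)

    def populations(self) -> list[str]:
        """Distinct labels in sorted order."""
        return sorted(set(self.assignments.values()))

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def __getitem__(self, sample: str) -> str:
        return self.assignments[sample]

    def __contains__(self, sample: str) -> bool:
        return sample in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 1-based inclusive, with an optional payload."""

    chrom: str
    start: int
    end: int
    payload: object = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomicsIOError(
                f"interval start > end: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


class IntervalSet:
    """A collection of genomic intervals supporting overlap queries.

    Intervals may overlap; :meth:`flatten` merges them into disjoint sorted
    intervals with identical per-base coverage. Queries are backed by one
    interval tree per chromosome.
    """

    def __init__(self, intervals: Iterable[Interval] = ()) -> None:
        self.intervals: list[Interval] = list(intervals)
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            # intervaltree is half-open; store [start, end+1)
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end + 1, iv
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def contains(self, chrom: str, pos: float) -> bool:
        """True if the 1-based position (possibly fractional) is covered."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return any(
            iv.data.start <= pos <= iv.data.end
            for iv in tree.overlap(pos - 1, pos + 1)
        )

    def overlapping(self, chrom: str, start: int, end: int) -> list[Interval]:
        """Intervals overlapping [start, end] (1-based inclusive)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(start, end + 1)),
            key=lambda i: (i.start, i.end),
        )

    def flatten(self) -> "IntervalSet":
        """Merge into disjoint sorted intervals covering the same bases."""
        merged: list[Interval] = []
        by_chrom: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
            cur_start, cur_end = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start <= cur_end + 1:
                    cur_end = max(cur_end, iv.end)
                else:
                    merged.append(Interval(chrom, cur_start, cur_end))
                    cur_start, cur_end = iv.start, iv.end
            merged.append(Interval(chrom, cur_start, cur_end))
        return IntervalSet(merged)

    def total_bases(self) -> int:
        return sum(iv.length for iv in self.flatten())


@dataclass
class TranscriptModel:
    """A protein-coding transcript: ordered CDS segments on one strand.

    ``cds_segments`` are (start, end) pairs, 1-based inclusive, ordered in
    transcription order (5' to 3' of the transcript): ascending genomic
    coordinates on the plus strand, descending on the minus strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    cds_segments: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomicsIOError(f"invalid strand {self.strand!r}")
        genomic = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise GenomicsIOError(
                    f"overlapping CDS segments in {self.transcript_id}"
                )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and any(
            s <= pos <= e for s, e in self.cds_segments
        )

    def cds_offset(self, pos: int) -> int:
        """0-based offset of a genomic position within the spliced CDS."""
        offset = 0
        for s, e in self.cds_segments:
            if s <= pos <= e:
                if self.strand == "+":
                    return offset + (pos - s)
                return offset + (e - pos)
            offset += e - s + 1
        raise GenomicsIOError(
            f"position {pos} not in CDS of {self.transcript_id}"
        )


class SequenceSet(dict):
    """Mapping of chromosome id to an uppercase nucleotide string."""

    def base_at(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        seq = self[chrom]
        if not 1 <= pos <= len(seq):
            raise GenomicsIOError(f"position {chrom}:{pos} outside sequence")
        return seq[pos - 1]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_vcf_genotypes(path: str | Path, keep_only_biallelic_snps: bool = True) -> GenotypeMatrix:
    """Read genotype codes from a VCF file.

    Only biallelic SNP records are retained; indels and multi-allelic
    records are skipped with a logged count. Phased separators are
    collapsed to unphased codes.
    """
    path = Path(path)
    if not path.exists():
        raise GenomicsIOError(f"cannot read VCF: {path} does not exist")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise GenomicsIOError("duplicate sample names in VCF header")

    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    skipped = 0
    last_pos: dict[str, int] = {}
    for rec in vcf:
        is_snp = (
            len(rec.ALT) == 1
            and len(rec.REF) == 1
            and rec.REF in _VALID_BASES
            and len(rec.ALT[0]) == 1
            and rec.ALT[0] in _VALID_BASES
        )
        if not is_snp:
            if keep_only_biallelic_snps:
                skipped += 1
                continue
            raise GenomicsIOError(
                f"non-biallelic-SNP record at {rec.CHROM}:{rec.POS} "
                "with keep_only_biallelic_snps disabled"
            )
        if samples and "GT" not in (rec.FORMAT or ""):
            raise GenomicsIOError(f"record {rec.CHROM}:{rec.POS} lacks GT field")
        if rec.POS <= last_pos.get(rec.CHROM, 0):
            raise GenomicsIOError(
                f"VCF not sorted: record {rec.CHROM}:{rec.POS} follows "
                f"{rec.CHROM}:{last_pos[rec.CHROM]}"
            )
        last_pos[rec.CHROM] = rec.POS
        sites.append(
            VariantSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                id=rec.ID,
            )
        )
        row = np.empty(len(samples), dtype=np.int8)
        for j, gt in enumerate(rec.genotypes):
            alleles = [a for a in gt[:-1] if isinstance(a, (int, np.integer))]
            if any(a < 0 for a in alleles) or not alleles:
                row[j] = MISSING
            elif len(alleles) == 1:
                row[j] = 2 * alleles[0]
            else:
                row[j] = alleles[0] + alleles[1]
        rows.append(row)
    if skipped:
        logger.info("skipped %d non-biallelic-SNP records in %s", skipped, path)
    genotypes = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    matrix = GenotypeMatrix(sites, samples, genotypes)
    matrix.skipped_records = skipped  # type: ignore[attr-defined]
    return matrix


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a matrix as minimal VCF v4.2 with a GT-only FORMAT."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in matrix.chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if matrix.samples:
            cols += ["FORMAT"] + matrix.samples
        fh.write("\t".join(cols) + "\n")
        for i, site in enumerate(matrix.sites):
            fields = [
                site.chrom,
                str(site.pos),
                site.id or ".",
                site.ref_allele,
                site.alt_allele,
                ".",
                ".",
                ".",
            ]
            if matrix.samples:
                fields.append("GT")
                fields.extend(_GT_STRINGS[int(g)] for g in matrix.genotypes[i])
            fh.write("\t".join(fields) + "\n")


def read_bed_intervals(path: str | Path) -> IntervalSet:
    """Read a BED3+ file, converting 0-based half-open to 1-based inclusive."""
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise GenomicsIOError(f"line {lineno}: fewer than 3 BED columns")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if end0 <= start0:
                raise GenomicsIOError(
                    f"line {lineno}: BED end {end0} <= start {start0}"
                )
            intervals.append(Interval(chrom, start0 + 1, end0))
    return IntervalSet(intervals)


def write_bed_intervals(intervals: IntervalSet, path: str | Path) -> None:
    """Write intervals as BED3, converting back to 0-based half-open."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


@dataclass(frozen=True)
class CnvCall:
    """Payload of one CNV call row: the sample and its copy number."""

    sample: str
    copy_number: float


def read_cnv_calls(path: str | Path) -> IntervalSet:
    """Read a per-sample CNV call table.

    The expected layout is a header row followed by tab-separated columns
    ``sample, chrom, first, last, copy_number`` with 1-based inclusive
    coordinates, the layout this package itself emits; the read-depth
    caller's native output should be reshaped to it.
    """
    intervals: list[Interval] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["sample", "chrom", "first", "last", "copy_number"]
        if [h.strip().lower() for h in header[:5]] != required:
            raise GenomicsIOError(
                f"CNV table header must be {required}, got {header[:5]}"
            )
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise GenomicsIOError(f"line {lineno}: expected 5 columns")
            try:
                sample, chrom = parts[0], parts[1]
                first, last = int(parts[2]), int(parts[3])
                copy_number = float(parts[4])
            except ValueError as exc:
                raise GenomicsIOError(f"line {lineno}: {exc}") from None
            if copy_number < 0:
                raise GenomicsIOError(
                    f"line {lineno}: negative copy number {copy_number}"
                )
            intervals.append(
                Interval(chrom, first, last, CnvCall(sample, copy_number))
            )
    return IntervalSet(intervals)


def write_cnv_calls(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tfirst\tlast\tcopy_number\n")
        for iv in intervals:
            call = iv.payload
            cn = call.copy_number
            cn_str = str(int(cn)) if float(cn).is_integer() else f"{cn:g}"
            fh.write(f"{call.sample}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{cn_str}\n")


def read_gff_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Build transcript models from a GFF3 file.

    One model is produced per mRNA feature with at least one CDS child.
    Transcripts whose total CDS length is not divisible by three are
    excluded with a warning, as are CDS features lacking a Parent.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    for feat in db.features_of_type("CDS"):
        if "Parent" not in feat.attributes:
            logger.warning("CDS at %s:%d-%d has no Parent; skipped",
                           feat.seqid, feat.start, feat.end)

    models: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        cds = list(db.children(mrna, featuretype="CDS"))
        if not cds:
            continue
        segments = sorted((c.start, c.end) for c in cds)
        strand = mrna.strand
        if strand == "-":
            segments = segments[::-1]
        gene_ids = mrna.attributes.get("Parent", [mrna.id])
        model = TranscriptModel(
            transcript_id=mrna.id,
            gene_id=gene_ids[0],
            chrom=mrna.seqid,
            strand=strand,
            cds_segments=segments,
        )
        if model.cds_length % 3 != 0:
            logger.warning(
                "transcript %s CDS length %d not divisible by 3; excluded",
                model.transcript_id, model.cds_length,
            )
            continue
        models.append(model)
    return models


def read_fasta_sequences(path: str | Path) -> SequenceSet:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    seqs = SequenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise GenomicsIOError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a two-column TSV (header ``sample``, ``population``)."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header[:2]] != ["sample", "population"]:
            raise GenomicsIOError(
                "population map header must be 'sample<TAB>population'"
            )
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GenomicsIOError(f"line {lineno}: expected 2 columns")
            sample, pop = parts[0], parts[1]
            if sample in assignments and assignments[sample] != pop:
                raise GenomicsIOError(
                    f"line {lineno}: sample {sample!r} mapped to both "
                    f"{assignments[sample]!r} and {pop!r}"
                )
            assignments[sample] = pop
    return PopulationMap(assignments)


def write_population_map(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\n")
        for sample, pop in popmap.assignments.items():
            fh.write(f"{sample}\t{pop}\n")
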