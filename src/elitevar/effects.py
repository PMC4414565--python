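"""SNP effect annotation against transcript models.

Each SNP falling inside the CDS of a transcript is classified as
synonymous, missense or nonsense by substituting the alternative allele
into the affected codon and translating with the standard genetic code.
Minus-strand codons are read on the reverse complement. Sites outside
every CDS are non-coding. Loss of the start codon is reported as missense
(there is no separate start-lost class) and a stop codon replaced by a
stop codon is synonymous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .genomics_io import (
    GenotypeMatrix,
    SequenceSet,
    TranscriptModel,
    VariantSite,
)

SEVERITY_ORDER = ("nonsense", "missense", "synonymous", "noncoding")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _translate_codon(codon: str) -> str:
    """One-letter amino acid, '*' for a stop codon."""
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


class ReferenceMismatchError(ValueError):
    """The VCF reference allele disagrees with the reference sequence."""


@dataclass(frozen=True)
class EffectAnnotation:
    """Effect of one SNP on one transcript (or 'noncoding' on none)."""

    chrom: str
    pos: int
    transcript_id: str | None
    effect: str
    codon_index: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None


def _spliced_cds(transcript: TranscriptModel, seqs: SequenceSet) -> str:
    """CDS sequence in transcription order (reverse-complemented on minus)."""
    chrom_seq = seqs[transcript.chrom]
    parts = []
    for start, end in transcript.cds_segments:
        segment = chrom_seq[start - 1 : end]
        if transcript.strand == "-":
            segment = segment.translate(_COMPLEMENT)[::-1]
        parts.append(segment)
    return "".join(parts)


def annotate_variant_effect(
    site: VariantSite,
    transcripts: Sequence[TranscriptModel],
    seqs: SequenceSet,
) -> list[EffectAnnotation]:
    """Classify a SNP against every transcript whose CDS contains it.

    Returns one annotation per overlapping transcript; a single
    ``noncoding`` annotation if no CDS covers the site.

    Raises
    ------
    ReferenceMismatchError
        If the reference sequence base at the site differs from the
        site's reference allele.
    """
    ref_base = seqs.base_at(site.chrom, site.pos)
    if ref_base != site.ref_allele:
        raise ReferenceMismatchError(
            f"reference base {ref_base} at {site.chrom}:{site.pos} "
            f"does not match ref allele {site.ref_allele}"
        )
    annotations: list[EffectAnnotation] = []
    for tx in transcripts:
        if not tx.contains(site.chrom, site.pos):
            continue
        offset = tx.cds_offset(site.pos)
        codon_index = offset // 3
        within = offset % 3
        cds = _spliced_cds(tx, seqs)
        codon = cds[3 * codon_index : 3 * codon_index + 3]
        ref_allele, alt_allele = site.ref_allele, site.alt_allele
        if tx.strand == "-":
            ref_allele = ref_allele.translate(_COMPLEMENT)
            alt_allele = alt_allele.translate(_COMPLEMENT)
        assert codon[within] == ref_allele
        alt_codon = codon[:within] + alt_allele + codon[within + 1 :]
        ref_aa = _translate_codon(codon)
        alt_aa = _translate_codon(alt_codon)
        if alt_aa == ref_aa:
            effect = "synonymous"
        elif alt_aa == "*":
            effect = "nonsense"
        else:
            effect = "missense"
        annotations.append(
            EffectAnnotation(
                chrom=site.chrom,
                pos=site.pos,
                transcript_id=tx.transcript_id,
                effect=effect,
                codon_index=codon_index,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
            )
        )
    if not annotations:
        annotations.append(
            EffectAnnotation(
                chrom=site.chrom, pos=site.pos, transcript_id=None,
                effect="noncoding",
            )
        )
    return annotations


def classify_site_severity(annotations: Iterable[EffectAnnotation]) -> str:
    """Collapse per-transcript effects to the most severe one.

    Severity order: nonsense > missense > synonymous > noncoding.
    """
    effects = {a.effect for a in annotations}
    if not effects:
        raise ValueError("cannot classify an empty annotation list")
    for effect in SEVERITY_ORDER:
        if effect in effects:
            return effect
    raise ValueError(f"unknown effects {effects}")


def annotate_matrix(
    matrix: GenotypeMatrix,
    transcripts: Sequence[TranscriptModel],
    seqs: SequenceSet,
) -> list[list[EffectAnnotation]]:
    """Annotate every site of a matrix; one annotation list per site."""
    return [
        annotate_variant_effect(site, transcripts, seqs)
        for site in matrix.sites
    ]


def effect_class_counts(
    annotations_per_site: Sequence[Sequence[EffectAnnotation]],
    collapse: str = "most_severe",
) -> dict[str, int]:
    """Count sites per effect class.

    ``collapse='most_severe'`` counts each site once under its most severe
    per-transcript effect; ``collapse='per_transcript'`` counts every
    (site, transcript) annotation.
    """
    counts = {e: 0 for e in SEVERITY_ORDER}
    if collapse == "most_severe":
        for anns in annotations_per_site:
            counts[classify_site_severity(anns)] += 1
    elif collapse == "per_transcript":
        for anns in annotations_per_site:
            for a in anns:
                counts[a.effect] += 1
    else:
        raise ValueError(f"unknown collapse mode {collapse!r}")
    return counts


def coding_fraction(class_counts: dict[str, int]) -> float:
    """Share of sites in coding (non-intronic) sequence.

    Computed as (synonymous + missense + nonsense) / total classified.
    """
    coding = sum(class_counts.get(e, 0) for e in ("synonymous", "missense", "nonsense"))
    total = coding + class_counts.get("noncoding", 0)
    if total == 0:
        return float("nan")
    return coding / total
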