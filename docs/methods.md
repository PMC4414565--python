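# Methods

This note documents the statistical models, algorithmic rules and
numerical choices behind `elitevar`, and what the synthetic panels used
for validation do and do not demonstrate about real data.

## Data model and conventions

All coordinates are 1-based inclusive internally (the VCF/GFF
convention); BED input is converted at the boundary (`start0+1, end0`)
and the conversion is a bijection on valid intervals. Chromosome names
match by exact string equality — no `chr` aliasing — so wrong-genome
joins fail loudly rather than silently. Genotypes are biallelic dosage
codes (0 hom-ref, 1 het, 2 hom-alt, −1 missing). Multi-allelic and indel
VCF records are skipped, not split: every downstream statistic is
defined on biallelic SNPs. Phased genotype separators are collapsed to
unphased codes; the intended panels are inbred lines in which phase
carries no extra information.

## SNP filter cascade

Three progressive stages, each consuming the previous stage's output, so
surviving site sets are provably nested:

1. drop SNPs inside annotated repetitive regions (flattened intervals,
   point-in-interval test);
2. drop singleton SNPs — minor allele carried by exactly one variety,
   counting carrier samples rather than allele copies — and SNPs whose
   100 bp bin has ≥ 3 samples with copy number ≠ 2;
3. drop SNPs whose bin has ≥ 1 sample with copy number ≠ 2, SNPs with
   another SNP of the input set closer than 10 bp (both members of a
   close pair are removed; the rule is applied within the loaded SNP
   universe, a documented narrowing from "any variant"), and SNPs
   genotyped in fewer than `min_genotyped` samples (default 80, a CLI
   parameter because panel sizes differ).

Allele frequency at a site is f = (2·hom-ref + het)/(2·n_genotyped) over
non-missing calls; MAF = min(f, 1−f); at f = 0.5 the alternative allele
is treated as minor. A site is *private* to a population when both
alleles are observed inside it and exactly one allele is observed in
every other population; populations with no genotyped member at a site
therefore disqualify it, which is the strict reading of "polymorphic in
only one population".

## Diversity, Fst, distances

Diversity between two samples over a region is the dosage difference
Σ |d₁ − d₂| / 2 across sites genotyped in both: opposite homozygotes
count 1, het-vs-hom counts ½. For fully inbred panels this equals the
plain count of nucleotide changes; for residual heterozygosity it is the
expected count under random allele draws. Windowed (default 100 kbp) and
per-gene diversity average this over all unordered sample pairs in a
group (or all cross pairs between two groups) and divide by region
length in kbp — length-normalised, not genotyped-site-normalised, so
lower call rates depress measured diversity rather than inflate it,
matching the behaviour of read-depth-limited panels. Gene diversity uses
the gene span as denominator (CDS length would be an alternative; span
is what the windowed statistic generalises).

Fst between groups is 1 − mean(within)/between. The default mean over
within-group diversities is unweighted; a `weights` argument supports
sample-size or pair-count weighting, because for unequal group sizes the
weighting convention changes the value at the second decimal and
published values do not always state it.

The distance matrix is the proportion of differences per
jointly-genotyped site, d(i,j) ∈ [0,1], symmetric with a zero diagonal;
pairs with no shared genotyped site get distance 0 and are listed in
`no_overlap_pairs`. Writers for square PHYLIP and a NEXUS DISTANCES
block serve neighbour-joining tools; tree building itself is out of
scope.

dN/dS is a raw count ratio per transcript — (missense + nonsense) /
synonymous over the polymorphic sites of the chosen subset — averaged
without weighting over transcripts having at least one synonymous site.
It is not a substitution-model dN/dS: no site-count normalisation is
applied, so values are comparable across filters of one dataset but not
across genomes with different codon composition.

## Effect annotation

A SNP inside the CDS of a transcript is classified by substituting the
alternative allele into its codon (reverse-complemented on minus-strand
transcripts) and translating with the standard genetic code: synonymous
(equal amino acid, including stop→stop), nonsense (stop gained),
missense otherwise; start-codon loss is reported as missense rather than
as a separate class. Sites outside every CDS are noncoding. Per-site
counting collapses per-transcript effects by severity
(nonsense > missense > synonymous > noncoding); per-transcript counting
is available. Transcripts whose CDS length is not divisible by three are
excluded with a warning. Splice-site, UTR and regulatory annotation are
out of scope.

## Window-based ancestry assignment

Discriminating SNPs are those where two populations' reference-allele
frequencies differ by ≥ 0.6 (boundary included). Each population gets a
consensus pseudo-genotype per site: the homozygote of its majority
allele, or a het call when its within-population MAF strictly exceeds
0.4, or missing when no member is genotyped.

Panel SNPs are cut into consecutive non-overlapping 50-SNP windows per
chromosome; trailing partial windows are dropped (a partial window
cannot reach the full-score threshold and the assignment cut-offs
presume 50 SNPs). A sample window is scored against each consensus
window with, per SNP and in this precedence order: 0 if either call is
missing, +1 if either call is heterozygous, +2 if both are homozygous
and equal, −2 if both are homozygous and different. The precedence is
forced by the max-score characterisation: 100 is attained iff the two
windows are equal, fully homozygous and fully genotyped — a property the
test suite checks by exhaustive enumeration of per-SNP categories.

A window is assigned when ≥ 40 SNPs are genotyped in the sample and the
best score is ≥ 50; the assignment is *unique* when the best score beats
the runner-up by ≥ 10, otherwise both candidates are reported
(ambiguous). Ties rank populations in label order, deterministically.
Consensus self-comparison flags window × pair combinations scoring
within 10 points of the maximum as non-discriminative; the flag margin
mirrors the uniqueness margin and is configurable, since conservation
between sister populations is the main cause of ambiguous calls.

## CNV bins and the characteristic-CNV rule

Per-sample CNV calls are projected onto non-overlapping 100 bp bins
tiling each chromosome (last bin may be short): a bin takes an event's
copy number iff the event covers the bin midpoint ((start+end)/2);
otherwise it keeps the diploid normal of 2. When several events of one
sample cover a midpoint, the copy number furthest from 2 wins, ties
resolving to the lower value (a homozygous deletion outranks a
duplication of equal distance). The midpoint rule is parameter-free, but
an event must span more than one bin width to be guaranteed to cover
some midpoint; integer events up to one bin width long can fall between
two midpoints and change no bin. This is the known edge of the rule.

Recurrence per bin and population: dup_fraction (copy > 2),
del_fraction (copy < 2), and mean copy over *all* members with
non-carriers at 2 — the all-members convention keeps the mean defined
when the comparison population has no carriers; a carriers-only mean is
the natural alternative but is undefined at zero carriers. Common-CNV
filtering keeps bins whose midpoint is outside every repeat and where at
least half of a population's members report an event (exactly half is
kept). The copy-number class histogram rounds the population mean half
away from zero and buckets into {0, 1, 3, 4+}, excluding the normal 2.

A bin's CNV is *characteristic* for P1 relative to P2 when
x₁ − x₂ > 0.5, or x₁ > 0.5 and n₁ − n₂ > 2, with x the event fraction
and n the mean copy number; all comparisons strict, so boundary values
do not fire. The copy-number branch uses n₁ − n₂ in both directions,
which means it can only fire for duplications; for deletions the
frequency branch is the operative rule. The frequency rule is inherently
asymmetric: x₁ − x₂ and x₂ − x₁ cannot both exceed 0.5.

## Synthetic panels

The generator emulates the structure of a resequenced inbred rice panel,
not its content. Defaults: 7 populations (aromatic, aus, indica, nivara,
rufipogon, temperate and tropical japonica) × 15 samples over two 1 Mbp
chromosomes at 10 SNPs/kbp; Balding–Nichols frequency divergence with
F = 0.15; inbreeding coefficient 0.95 (elite lines are effectively
homozygous); 5% missing calls; ~45% of each chromosome marked
repetitive. Population frequencies are Beta(p(1−F)/F, (1−p)(1−F)/F)
draws around a Uniform(0.05, 0.95) ancestral frequency — chosen because
F gives an analytic handle on expected differentiation for the recovery
tests. Genotypes are two allele draws forced identical with probability
equal to the inbreeding coefficient, so the expected het fraction at
frequency p is 2p(1−p)(1−i). Introgression tracts re-draw the
recipient's genotypes from the donor's true frequencies; CNV specs make
each population member a carrier with a stated probability. All
randomness flows from a single seed with per-chromosome substreams;
identical configurations produce byte-identical outputs.

What passing the recovery tests shows: the assignment algorithm
correctly identifies donor tracts when populations are differentiated at
the Balding–Nichols level and SNP ascertainment follows the frequency
rule. What it does not show: robustness to linkage disequilibrium
(sites are drawn independently), recombination-graded tract edges,
ascertainment bias of real SNP discovery, or sequencing-depth-dependent
genotyping error — real panels have all four. Misassigned windows in the
synthetic runs are almost exclusively tract-boundary windows whose SNPs
mix two ancestries.

## Problem sizes and numerical choices

Validation runs use the default 20,000-site, 105-sample panel
(~6,000–6,600 discriminating SNPs, ~130 windows), a 100-window
two-population panel for Fst recovery, and toy fixtures small enough for
brute-force oracles (double-loop diversity, per-SNP score evaluation,
dense characteristic-rule grids, per-base interval membership). The
Fst-recovery oracle computes expected dosage-difference diversity
directly from the generating frequencies and the inbred genotype
distribution; observed minus oracle stays within ±0.05 and is typically
below 0.01. NaN is used for flagged undefined values (no genotyped
member, zero between-group diversity) rather than exceptions, so
windowed tables keep their shape; histogram binning is left-closed
right-open with the final bin closed.
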