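"""Self-contained synthetic panels with known truth.

The generator emulates the structure of a resequenced inbred rice panel:
around a hundred mostly-homozygous samples from seven populations with
divergent allele frequencies, missing genotype calls, repeat-rich
chromosomes, population-recurrent CNVs, and introgression tracts of known
donor origin.

Population allele frequencies follow a Balding-Nichols model: at a site
with ancestral frequency p, each population draws its frequency from
Beta(p(1-F)/F, (1-p)(1-F)/F), so F controls the expected differentiation
between populations. Genotypes are two allele draws forced identical with
probability equal to the inbreeding coefficient, giving the homozygote
excess typical of elite inbred lines. Everything is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .genomics_io import (
    MISSING,
    CnvCall,
    GenomicsIOError,
    GenotypeMatrix,
    Interval,
    IntervalSet,
    PopulationMap,
    VariantSite,
    write_bed_intervals,
    write_cnv_calls,
)

#: Population labels of the default seven-group panel.
SEVEN_POPULATIONS = (
    "aromatic",
    "aus",
    "indica",
    "nivara",
    "rufipogon",
    "temperate_japonica",
    "tropical_japonica",
)


@dataclass(frozen=True)
class IntrogressionSpec:
    """One donor tract to implant into a recipient sample."""

    sample: str
    donor: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class CnvSpec:
    """One population-recurrent CNV region."""

    population: str
    chrom: str
    start: int
    end: int
    copy_number: float
    carrier_fraction: float


@dataclass
class SimulationConfig:
    """Parameters of a synthetic panel.

    Defaults describe a panel of 7 populations x 15 inbred samples over
    two 1 Mbp chromosomes at 10 SNPs per kbp, with moderate population
    differentiation (F = 0.15), strong inbreeding (0.95) and 5% missing
    genotype calls; roughly 45% of each chromosome is marked repetitive.
    """

    seed: int
    n_chromosomes: int = 2
    chromosome_length_bp: int = 1_000_000
    n_populations: int = 7
    samples_per_population: int = 15
    divergence_f: float = 0.15
    inbreeding: float = 0.95
    missing_rate: float = 0.05
    snp_density_per_kbp: float = 10.0
    repeat_fraction: float = 0.45
    population_labels: tuple[str, ...] | None = None
    introgressions: tuple[IntrogressionSpec, ...] = ()
    cnvs: tuple[CnvSpec, ...] = ()

    def __post_init__(self) -> None:
        for name in ("inbreeding", "missing_rate", "repeat_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise GenomicsIOError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.divergence_f < 1:
            raise GenomicsIOError("divergence_f must be in (0, 1)")
        if self.chromosome_length_bp <= 0 or self.n_chromosomes <= 0:
            raise GenomicsIOError("genome dimensions must be positive")
        if self.population_labels is None:
            if self.n_populations == 7:
                self.population_labels = SEVEN_POPULATIONS
            else:
                self.population_labels = tuple(
                    f"pop{i + 1}" for i in range(self.n_populations)
                )
        if len(self.population_labels) != self.n_populations:
            raise GenomicsIOError("population_labels length mismatch")

    @property
    def chromosomes(self) -> dict[str, int]:
        return {
            f"chr{i + 1}": self.chromosome_length_bp
            for i in range(self.n_chromosomes)
        }


@dataclass
class TruthSet:
    """Ground truth emitted alongside a synthetic panel."""

    config: SimulationConfig
    sites: list[VariantSite] = field(default_factory=list)
    #: (site, population) true reference-allele frequencies
    population_freqs: np.ndarray | None = None
    populations: list[str] = field(default_factory=list)
    tracts: list[IntrogressionSpec] = field(default_factory=list)
    cnv_events: IntervalSet = field(default_factory=IntervalSet)
    repeats: IntervalSet = field(default_factory=IntervalSet)

    def donor_at(self, sample: str, chrom: str, pos: float) -> str | None:
        """Donor population of the tract covering a position, if any."""
        for t in self.tracts:
            if t.sample == sample and t.chrom == chrom and t.start <= pos <= t.end:
                return t.donor
        return None


_BASES = np.array(list("ACGT"))


def _draw_inbred_genotypes(
    rng: np.random.Generator,
    ref_freqs: np.ndarray,
    inbreeding: float,
) -> np.ndarray:
    """Dosage codes for one sample given per-site ref-allele frequencies.

    With probability ``inbreeding`` the two allele draws are forced
    identical (a single draw is doubled); otherwise the draws are
    independent.
    """
    n = len(ref_freqs)
    p_alt = 1.0 - ref_freqs
    forced = rng.random(n) < inbreeding
    a1 = (rng.random(n) < p_alt).astype(np.int8)
    a2 = (rng.random(n) < p_alt).astype(np.int8)
    a2 = np.where(forced, a1, a2)
    return (a1 + a2).astype(np.int8)


def simulate_panel(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PopulationMap, TruthSet]:
    """Generate a structured, inbred, partially missing genotype panel."""
    labels = config.population_labels
    assert labels is not None
    samples = [
        f"{p}_{i + 1:02d}"
        for p in labels
        for i in range(config.samples_per_population)
    ]
    popmap = PopulationMap(
        {s: s.rsplit("_", 1)[0] for s in samples}
    )

    f = config.divergence_f
    sites: list[VariantSite] = []
    freq_blocks: list[np.ndarray] = []
    geno_blocks: list[np.ndarray] = []
    for ci, (chrom, length) in enumerate(config.chromosomes.items()):
        rng = np.random.default_rng([config.seed % (2**31), ci])
        n_sites = int(round(length / 1000 * config.snp_density_per_kbp))
        if n_sites == 0:
            raise GenomicsIOError("configuration yields zero SNP sites")
        positions = np.sort(
            rng.choice(np.arange(1, length + 1), size=n_sites, replace=False)
        )
        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_shift = rng.integers(1, 4, size=n_sites)
        alt_idx = (ref_idx + alt_shift) % 4
        for pos, r, a in zip(positions, ref_idx, alt_idx):
            sites.append(
                VariantSite(chrom, int(pos), str(_BASES[r]), str(_BASES[a]))
            )
        ancestral = rng.uniform(0.05, 0.95, size=n_sites)
        pop_freqs = np.empty((n_sites, len(labels)))
        scale = (1.0 - f) / f
        for k in range(len(labels)):
            pop_freqs[:, k] = rng.beta(ancestral * scale, (1 - ancestral) * scale)
        freq_blocks.append(pop_freqs)
        geno = np.empty((n_sites, len(samples)), dtype=np.int8)
        for j, s in enumerate(samples):
            k = labels.index(popmap[s])
            geno[:, j] = _draw_inbred_genotypes(
                rng, pop_freqs[:, k], config.inbreeding
            )
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = MISSING
        geno_blocks.append(geno)

    matrix = GenotypeMatrix(sites, samples, np.vstack(geno_blocks))
    truth = TruthSet(
        config=config,
        sites=sites,
        population_freqs=np.vstack(freq_blocks),
        populations=list(labels),
    )
    if config.introgressions:
        matrix, truth = inject_introgressions(
            matrix, truth, config.introgressions
        )
    return matrix, popmap, truth


def inject_introgressions(
    matrix: GenotypeMatrix,
    truth: TruthSet,
    specs: Sequence[IntrogressionSpec],
) -> tuple[GenotypeMatrix, TruthSet]:
    """Re-draw recipient genotypes inside tracts from donor frequencies.

    Tracts of one sample must not overlap. The re-draw uses the donor
    population's true per-site frequencies and the panel's inbreeding
    coefficient; every tract is recorded in the truth set.
    """
    by_sample: dict[str, list[IntrogressionSpec]] = {}
    for spec in specs:
        if spec.start > spec.end:
            continue  # zero-length specification: no effect
        for prev in by_sample.get(spec.sample, []):
            if prev.chrom == spec.chrom and not (
                spec.end < prev.start or spec.start > prev.end
            ):
                raise GenomicsIOError(
                    f"overlapping tracts for sample {spec.sample!r}"
                )
        by_sample.setdefault(spec.sample, []).append(spec)

    geno = matrix.genotypes.copy()
    config = truth.config
    chroms = matrix.site_chroms()
    pos = matrix.positions()
    rng = np.random.default_rng([config.seed % (2**31), 9001])
    new_tracts = list(truth.tracts)
    for sample, tracts in by_sample.items():
        j = matrix.sample_indices([sample])[0]
        for t in tracts:
            donor_k = truth.populations.index(t.donor)
            in_tract = (chroms == t.chrom) & (pos >= t.start) & (pos <= t.end)
            idx = np.nonzero(in_tract)[0]
            if idx.size:
                donor_freqs = truth.population_freqs[idx, donor_k]
                drawn = _draw_inbred_genotypes(
                    rng, donor_freqs, config.inbreeding
                )
                miss = rng.random(idx.size) < config.missing_rate
                drawn[miss] = MISSING
                geno[idx, j] = drawn
            new_tracts.append(t)
    new_truth = replace(truth, tracts=new_tracts)
    return GenotypeMatrix(matrix.sites, matrix.samples, geno), new_truth


def simulate_cnv_landscape(
    config: SimulationConfig,
    popmap: PopulationMap,
) -> tuple[IntervalSet, IntervalSet, TruthSet]:
    """Generate per-sample CNV calls and a repeat annotation.

    For every :class:`CnvSpec`, each member of the target population
    carries the event with the stated probability; carriers receive the
    stated copy number over the whole region. Repeat intervals are
    placed uniformly until the configured fraction of each chromosome is
    covered. Returns (cnv_calls, repeats, truth).
    """
    rng = np.random.default_rng([config.seed % (2**31), 7001])
    events: list[Interval] = []
    for spec in config.cnvs:
        if not 0 <= spec.carrier_fraction <= 1:
            raise GenomicsIOError(
                f"carrier fraction {spec.carrier_fraction} outside [0, 1]"
            )
        if spec.end > config.chromosomes.get(spec.chrom, 0):
            raise GenomicsIOError(
                f"CNV region {spec.chrom}:{spec.start}-{spec.end} "
                "outside the simulated genome"
            )
        members = sorted(popmap.samples_in(spec.population))
        carrier = rng.random(len(members)) < spec.carrier_fraction
        for s, is_carrier in zip(members, carrier):
            if is_carrier:
                events.append(
                    Interval(
                        spec.chrom, spec.start, spec.end,
                        CnvCall(s, spec.copy_number),
                    )
                )
    cnv_calls = IntervalSet(events)

    repeat_ivs: list[Interval] = []
    for chrom, length in config.chromosomes.items():
        target = config.repeat_fraction * length
        covered = 0
        tries = 0
        chrom_ivs: list[Interval] = []
        while covered < target and tries < 100_000:
            tries += 1
            size = int(rng.integers(200, 5001))
            start = int(rng.integers(1, max(2, length - size)))
            chrom_ivs.append(Interval(chrom, start, start + size - 1))
            covered = IntervalSet(chrom_ivs).total_bases()
        repeat_ivs.extend(chrom_ivs)
    repeats = IntervalSet(repeat_ivs).flatten()

    truth = TruthSet(
        config=config,
        cnv_events=cnv_calls,
        repeats=repeats,
    )
    return cnv_calls, repeats, truth


def write_truth_files(truth: TruthSet, out_dir: str | Path) -> None:
    """Write truth tables (1-based inclusive TSV / standard BED)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "tracts.tsv", "w") as fh:
        fh.write("sample\tchrom\tfirst\tlast\tdonor\n")
        for t in truth.tracts:
            fh.write(f"{t.sample}\t{t.chrom}\t{t.start}\t{t.end}\t{t.donor}\n")
    write_cnv_calls(truth.cnv_events, out_dir / "cnv_truth.tsv")
    write_bed_intervals(truth.repeats, out_dir / "repeats_truth.bed")
    if truth.population_freqs is not None:
        with open(out_dir / "population_freqs.tsv", "w") as fh:
            fh.write("chrom\tpos\t" + "\t".join(truth.populations) + "\n")
            for site, freqs in zip(truth.sites, truth.population_freqs):
                vals = "\t".join(f"{v:.6f}" for v in freqs)
                fh.write(f"{site.chrom}\t{site.pos}\t{vals}\n")


def write_genome_table(config: SimulationConfig, path: str | Path) -> None:
    """Write chromosome lengths as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom, length in config.chromosomes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_genome_table(path: str | Path) -> dict[str, int]:
    """Read chromosome lengths from a two-column TSV."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header[:2]] != ["chrom", "length"]:
            raise GenomicsIOError("genome table header must be 'chrom<TAB>length'")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, length = line.split("\t")[:2]
            genome[chrom] = int(length)
    return genome


def study_scenario(
    seed: int,
    n_admixed: int = 5,
    tracts_per_sample: int = 10,
    tract_length_bp: int = 60_000,
) -> SimulationConfig:
    """A ready-made admixture scenario over the default panel.

    Selected indica samples receive ``tracts_per_sample`` donor tracts
    each, with donors rotating over the other six populations and tract
    starts spread evenly over the two chromosomes.
    """
    base = SimulationConfig(seed=seed)
    labels = base.population_labels
    assert labels is not None
    recipients = [f"indica_{i + 1:02d}" for i in range(n_admixed)]
    donors = [p for p in labels if p != "indica"]
    tracts: list[IntrogressionSpec] = []
    rng = np.random.default_rng([seed % (2**31), 5001])
    chrom_names = list(base.chromosomes)
    per_chrom = tracts_per_sample // len(chrom_names) + 1
    for r_i, sample in enumerate(recipients):
        placed = 0
        for chrom in chrom_names:
            length = base.chromosomes[chrom]
            slots = np.linspace(
                1, length - tract_length_bp, per_chrom, dtype=int
            )
            jitter = rng.integers(0, tract_length_bp // 4, size=len(slots))
            for s, j in zip(slots, jitter):
                if placed >= tracts_per_sample:
                    break
                donor = donors[(r_i + placed) % len(donors)]
                start = int(s + j)
                tracts.append(
                    IntrogressionSpec(
                        sample=sample, donor=donor, chrom=chrom,
                        start=start, end=start + tract_length_bp - 1,
                    )
                )
                placed += 1
    return replace(base, introgressions=tuple(tracts))
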