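"""In-silico SPET experiment generator.

Produces everything the downstream stages need without any real data: a
random reference with gene models, a structured multi-species germplasm set
(a low-diversity selfing crop plus progressively diverged outcrossing wild
relatives), and probe readout reads whose capture success decays with the
number of probe-footprint mismatches — the mechanism behind the
divergence-dependent missing-data gradient seen in real SPET assays.

Model summary
-------------
* Species backbone: Poisson(divergence x genome length) substitutions fixed
  in every accession of the species (homozygous).
* Within-species polymorphism: a pool of Poisson(diversity x genome length)
  sites with allele frequencies drawn from Beta(0.5, 0.5); each accession
  haplotype samples the alternative allele by frequency.
* Selfing: after g generations each heterozygous site has been fixed (to a
  random allele) with probability 1 - 2^-g.
* Coverage: reads per probe x accession ~ Negative Binomial(mean, k); a
  read from a haplotype with m probe-footprint mismatches survives capture
  with probability (1 - lambda)^m; surviving reads copy the haplotype
  readout window with a uniform per-base error rate.

Infinite sites holds genome-wide: no position is ever reused, across
species and haplotypes, so every variant site has a single alternative
allele.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig
from .formats_io import Annotation, GenomeRef, write_panel
from .panel import DesignReport, PilotCoverage, Probe, design_panel

BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSpec:
    """One species in the germplasm ladder."""

    name: str
    divergence: float  # expected substitutions/site from the reference lineage
    selfing_generations: int
    n_accessions: int
    diversity: float  # within-species polymorphic sites per bp

    def __post_init__(self) -> None:
        if self.divergence < 0 or self.diversity < 0:
            raise ValueError("divergence and diversity must be >= 0")
        if self.selfing_generations < 0 or self.n_accessions < 0:
            raise ValueError("selfing_generations and n_accessions must be >= 0")


def default_species_ladder() -> list[SpeciesSpec]:
    """The default 4-species study design: an autogamous crop panel plus
    three outcrossing wild relatives of increasing divergence."""
    return [
        SpeciesSpec("crop", divergence=0.0, selfing_generations=20,
                    n_accessions=12, diversity=0.002),
        SpeciesSpec("wild_close", divergence=0.01, selfing_generations=0,
                    n_accessions=4, diversity=0.008),
        SpeciesSpec("wild_mid", divergence=0.03, selfing_generations=0,
                    n_accessions=4, diversity=0.010),
        SpeciesSpec("wild_far", divergence=0.06, selfing_generations=0,
                    n_accessions=4, diversity=0.012),
    ]


@dataclass
class SimulationConfig:
    """Geometry and noise parameters of the simulated experiment."""

    n_contigs: int = 2
    contig_length: int = 500_000
    genes_per_contig: int = 120
    utr_length: int = 100
    cds_exon_length: int = 300
    intron_length: int = 200
    n_cds_exons: int = 3
    species: list[SpeciesSpec] = field(default_factory=default_species_ladder)
    #: accession prefix(es) whose species enter the candidate-SNP cohort
    #: (panel ascertainment); None means all species.
    ascertainment_species: tuple[str, ...] | None = ("crop",)
    depth_mean: float = 60.0
    #: negative-binomial dispersion k (smaller = more overdispersed);
    #: None gives a constant depth of round(depth_mean).
    depth_dispersion: float | None = 5.0
    hyb_lambda: float = 0.3  # per-mismatch capture failure rate
    error_rate: float = 2e-4  # per-base sequencing error

    @property
    def gene_length(self) -> int:
        return (2 * self.utr_length + self.n_cds_exons * self.cds_exon_length
                + (self.n_cds_exons - 1) * self.intron_length)

    @property
    def genome_length(self) -> int:
        return self.n_contigs * self.contig_length


# ---------------------------------------------------------------------------
# reference + annotation
# ---------------------------------------------------------------------------

def generate_reference(
    config: SimulationConfig, seed: int
) -> tuple[GenomeRef, Annotation]:
    """Random reference genome with non-overlapping gene models.

    Gene model: 5'UTR, then alternating CDS exons and introns, then 3'UTR.
    Genes are placed by distributing the spare intergenic space uniformly
    at random between them; deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    glen = config.gene_length
    total = config.genes_per_contig * glen
    if config.genes_per_contig and total > config.contig_length:
        raise ValueError(
            f"{config.genes_per_contig} genes x {glen} bp exceed contig "
            f"length {config.contig_length}"
        )
    contigs: dict[str, str] = {}
    features: list[tuple[str, int, int, str, str]] = []
    for c in range(config.n_contigs):
        cid = f"chr{c + 1}"
        seq = rng.integers(0, 4, size=config.contig_length)
        contigs[cid] = BASES[seq].tobytes().decode()
        n = config.genes_per_contig
        if n == 0:
            continue
        spare = config.contig_length - n * glen
        gaps = rng.multinomial(spare, np.full(n + 1, 1.0 / (n + 1)))
        cursor = 0
        for g in range(n):
            cursor += gaps[g]
            start = cursor + 1  # 1-based gene start
            gene_id = f"{cid}_g{g + 1:04d}"
            p = start
            features.append((cid, p, p + config.utr_length - 1, "UTR", gene_id))
            p += config.utr_length
            for e in range(config.n_cds_exons):
                features.append(
                    (cid, p, p + config.cds_exon_length - 1, "CDS", gene_id))
                p += config.cds_exon_length
                if e < config.n_cds_exons - 1:
                    features.append(
                        (cid, p, p + config.intron_length - 1, "intron", gene_id))
                    p += config.intron_length
            features.append((cid, p, p + config.utr_length - 1, "UTR", gene_id))
            cursor += glen
    return GenomeRef(contigs=contigs, anchored={c: True for c in contigs}), \
        Annotation(features=features)


def write_gff3(annotation: Annotation, genome: GenomeRef, path: str | Path) -> Path:
    """Emit the annotation as GFF3 with reconstructed gene/mRNA/exon rows."""
    path = Path(path)
    by_gene: dict[str, list[tuple[str, int, int, str]]] = {}
    for contig, start, end, cls, gene in annotation.features:
        by_gene.setdefault(gene, []).append((contig, start, end, cls))
    lines = ["##gff-version 3"]
    for cid in genome.contigs:
        lines.append(f"##sequence-region {cid} 1 {genome.length(cid)}")
    for gene in sorted(by_gene):
        ivals = sorted(by_gene[gene], key=lambda t: t[1])
        contig = ivals[0][0]
        gstart, gend = ivals[0][1], max(e for _, _, e, _ in ivals)
        introns = sorted((s, e) for _, s, e, cls in ivals if cls == "intron")
        lines.append(f"{contig}\tspetkit\tgene\t{gstart}\t{gend}\t.\t+\t.\tID={gene}_g")
        lines.append(
            f"{contig}\tspetkit\tmRNA\t{gstart}\t{gend}\t.\t+\t.\t"
            f"ID={gene};Parent={gene}_g"
        )
        # exons = gene span minus introns
        exon_start = gstart
        exons = []
        for s, e in introns:
            exons.append((exon_start, s - 1))
            exon_start = e + 1
        exons.append((exon_start, gend))
        for i, (s, e) in enumerate(exons, 1):
            lines.append(
                f"{contig}\tspetkit\texon\t{s}\t{e}\t.\t+\t.\t"
                f"ID={gene}.exon{i};Parent={gene}"
            )
        for _, s, e, cls in ivals:
            if cls == "CDS":
                lines.append(
                    f"{contig}\tspetkit\tCDS\t{s}\t{e}\t.\t+\t0\tParent={gene}")
            elif cls == "UTR":
                ftype = "five_prime_UTR" if s < (gstart + gend) / 2 else "three_prime_UTR"
                lines.append(
                    f"{contig}\tspetkit\t{ftype}\t{s}\t{e}\t.\t+\t.\tParent={gene}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_fasta(genome: GenomeRef, path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# germplasm
# ---------------------------------------------------------------------------

@dataclass
class AccessionGenome:
    """Two haplotypes as sparse substitution maps over the reference."""

    accession_id: str
    species: str
    hap1: dict[tuple[str, int], str]
    hap2: dict[tuple[str, int], str]

    def dosage(self, contig: str, pos: int, alt: str) -> int:
        """Alt-allele dosage (0/1/2) at a known variant site."""
        return int(self.hap1.get((contig, pos)) == alt) + \
            int(self.hap2.get((contig, pos)) == alt)

    def heterozygosity(self) -> float:
        """Fraction of this accession's variant sites that are heterozygous."""
        keys = set(self.hap1) | set(self.hap2)
        if not keys:
            return 0.0
        het = sum(1 for k in keys if self.hap1.get(k) != self.hap2.get(k))
        return het / len(keys)


@dataclass
class GermplasmSet:
    """Simulated accessions plus the registry of all true variant sites."""

    accessions: list[AccessionGenome]
    #: (contig, pos) -> (ref base, alt base), every simulated variant
    sites: dict[tuple[str, int], tuple[str, str]]
    species: list[SpeciesSpec]

    def truth_genotype(self, contig: str, pos: int, accession: AccessionGenome) -> int:
        _ref, alt = self.sites[(contig, pos)]
        return accession.dosage(contig, pos, alt)

    def by_species(self, name: str) -> list[AccessionGenome]:
        return [a for a in self.accessions if a.species == name]


class _SiteSampler:
    """Genome-wide infinite-sites position sampler."""

    def __init__(self, genome: GenomeRef, rng: np.random.Generator):
        self.genome = genome
        self.rng = rng
        self.contig_ids = list(genome.contigs)
        lengths = np.array([genome.length(c) for c in self.contig_ids], dtype=float)
        self.weights = lengths / lengths.sum()
        self.lengths = lengths.astype(int)
        self.used: set[tuple[str, int]] = set()

    def draw(self, k: int) -> list[tuple[str, int]]:
        out: list[tuple[str, int]] = []
        while len(out) < k:
            ci = self.rng.choice(len(self.contig_ids), p=self.weights)
            pos = int(self.rng.integers(1, self.lengths[ci] + 1))
            key = (self.contig_ids[ci], pos)
            if key in self.used:
                continue
            self.used.add(key)
            out.append(key)
        return out

    def alt_base(self, contig: str, pos: int) -> str:
        ref = self.genome.contigs[contig][pos - 1]
        choices = [b for b in "ACGT" if b != ref]
        return choices[int(self.rng.integers(0, len(choices)))]


def simulate_germplasm(
    genome: GenomeRef, species: list[SpeciesSpec], seed: int
) -> GermplasmSet:
    """Draw accession genomes for every species in the ladder."""
    rng = np.random.default_rng(seed)
    sampler = _SiteSampler(genome, rng)
    L = sum(genome.length(c) for c in genome.contigs)
    sites: dict[tuple[str, int], tuple[str, str]] = {}
    accessions: list[AccessionGenome] = []

    def register(key: tuple[str, int]) -> str:
        alt = sampler.alt_base(*key)
        sites[key] = (genome.contigs[key[0]][key[1] - 1], alt)
        return alt

    for spec in species:
        # fixed species backbone
        n_back = rng.poisson(spec.divergence * L)
        backbone = {key: register(key) for key in sampler.draw(n_back)}
        # shared within-species polymorphism pool
        n_poly = rng.poisson(spec.diversity * L)
        pool_keys = sampler.draw(n_poly)
        pool = [(key, register(key), rng.beta(0.5, 0.5)) for key in pool_keys]
        p_fix = 1.0 - 0.5 ** spec.selfing_generations
        for i in range(spec.n_accessions):
            hap1 = dict(backbone)
            hap2 = dict(backbone)
            for key, alt, freq in pool:
                c1 = rng.random() < freq
                c2 = rng.random() < freq
                if c1 != c2 and rng.random() < p_fix:  # selfing fixes hets
                    c1 = c2 = rng.random() < 0.5
                if c1:
                    hap1[key] = alt
                if c2:
                    hap2[key] = alt
            accessions.append(
                AccessionGenome(
                    accession_id=f"{spec.name}_{i + 1:02d}",
                    species=spec.name,
                    hap1=hap1,
                    hap2=hap2,
                )
            )
    return GermplasmSet(accessions=accessions, sites=sites, species=list(species))


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_truth_vcf(germplasm: GermplasmSet, path: str | Path, seed: int | None = None) -> Path:
    """All simulated variants with per-accession true genotypes."""
    path = Path(path)
    names = [a.accession_id for a in germplasm.accessions]
    lines = ["##fileformat=VCFv4.2"]
    if seed is not None:
        lines.append(f"##spetkit_seed={seed}")
    contigs = sorted({c for c, _ in germplasm.sites})
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names))
    for (contig, pos) in sorted(germplasm.sites):
        ref, alt = germplasm.sites[(contig, pos)]
        gts = [
            _GT_STR[acc.dosage(contig, pos, alt)] for acc in germplasm.accessions
        ]
        lines.append(
            f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_candidate_vcf(
    germplasm: GermplasmSet,
    path: str | Path,
    cohort_species: tuple[str, ...] | None = None,
    seed: int | None = None,
) -> Path:
    """Candidate-SNP VCF ascertained from a species subset of the cohort.

    Mirrors real panel design, where candidates come from whoever happened
    to be resequenced; sites monomorphic-reference in the cohort are
    invisible and omitted.
    """
    path = Path(path)
    cohort = [
        a for a in germplasm.accessions
        if cohort_species is None or a.species in cohort_species
    ]
    if not cohort:
        raise ValueError(f"no accessions in cohort species {cohort_species}")
    an = 2 * len(cohort)
    lines = ["##fileformat=VCFv4.2"]
    if seed is not None:
        lines.append(f"##spetkit_seed={seed}")
    lines += [f"##contig=<ID={c}>" for c in sorted({c for c, _ in germplasm.sites})]
    lines += [
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele count">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for (contig, pos) in sorted(germplasm.sites):
        ref, alt = germplasm.sites[(contig, pos)]
        ac = sum(a.dosage(contig, pos, alt) for a in cohort)
        if ac == 0:
            continue
        lines.append(
            f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tAC={ac};AN={an}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class Read:
    """One surviving SPET readout, in reference-forward orientation."""

    probe_id: str
    accession_id: str
    haplotype: int  # 1 or 2
    sequence: str  # bases over [readout_start, readout_end]
    error_offsets: tuple[int, ...] = ()


@dataclass
class ReadBatch:
    reads: list[Read]

    def __len__(self) -> int:
        return len(self.reads)

    def by_group(self) -> dict[tuple[str, str], list[Read]]:
        groups: dict[tuple[str, str], list[Read]] = {}
        for r in self.reads:
            groups.setdefault((r.probe_id, r.accession_id), []).append(r)
        return groups


def _haplotype_window(
    genome: GenomeRef, hap: dict[tuple[str, int], str], contig: str,
    start: int, end: int,
) -> str:
    seq = list(genome.fetch(contig, start, end))
    for pos in range(start, end + 1):
        alt = hap.get((contig, pos))
        if alt is not None:
            seq[pos - start] = alt
    return "".join(seq)


def _footprint_mismatches(
    hap: dict[tuple[str, int], str], probe: Probe
) -> int:
    return sum(
        1 for pos in range(probe.start, probe.end + 1)
        if (probe.contig, pos) in hap
    )


def simulate_reads(
    panel: list[Probe],
    accessions: list[AccessionGenome],
    genome: GenomeRef,
    config: SimulationConfig,
    seed: int,
) -> ReadBatch:
    """Simulate capture + sequencing for every probe x accession.

    Reads are emitted in reference-forward orientation over the probe's
    readout window, regardless of probe orientation.
    """
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    base_list = "ACGT"
    for probe in panel:
        win_len = probe.readout_end - probe.readout_start + 1
        for acc in accessions:
            if config.depth_dispersion is None:
                n = int(round(config.depth_mean))
            else:
                k = config.depth_dispersion
                p = k / (k + config.depth_mean)
                n = int(rng.negative_binomial(k, p))
            if n == 0:
                continue
            n1 = int(rng.binomial(n, 0.5))
            for hap_idx, hap, n_h in ((1, acc.hap1, n1), (2, acc.hap2, n - n1)):
                if n_h == 0:
                    continue
                m = _footprint_mismatches(hap, probe)
                surv_p = (1.0 - config.hyb_lambda) ** m
                n_surv = int(rng.binomial(n_h, surv_p)) if surv_p < 1.0 else n_h
                if n_surv == 0:
                    continue
                window = _haplotype_window(
                    genome, hap, probe.contig, probe.readout_start, probe.readout_end
                )
                n_err = rng.binomial(win_len, config.error_rate, size=n_surv)
                for e in n_err:
                    if e == 0:
                        reads.append(Read(probe.id, acc.accession_id, hap_idx, window))
                        continue
                    offs = rng.choice(win_len, size=int(e), replace=False)
                    chars = list(window)
                    for off in offs:
                        wrong = [b for b in base_list if b != chars[off]]
                        chars[off] = wrong[int(rng.integers(0, 3))]
                    reads.append(
                        Read(probe.id, acc.accession_id, hap_idx,
                             "".join(chars), tuple(int(o) for o in offs))
                    )
    return ReadBatch(reads=reads)


def write_reads_tsv(batch: ReadBatch, path: str | Path, seed: int | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"#spetkit_seed={seed}\n")
        fh.write("probe_id\taccession_id\thaplotype\tsequence\n")
        for r in batch.reads:
            fh.write(f"{r.probe_id}\t{r.accession_id}\t{r.haplotype}\t{r.sequence}\n")
    return path


def pilot_coverage(
    batch: ReadBatch, panel: list[Probe], samples: list[str] | None = None
) -> PilotCoverage:
    """Per-probe read-depth table from a pilot read batch."""
    if samples is None:
        samples = sorted({r.accession_id for r in batch.reads})
    idx = {s: i for i, s in enumerate(samples)}
    depths = {p.id: [0.0] * len(samples) for p in panel}
    for r in batch.reads:
        depths[r.probe_id][idx[r.accession_id]] += 1
    return PilotCoverage(per_sample_depths=depths)


def read_reads_tsv(path: str | Path) -> ReadBatch:
    reads = []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts
                continue
            reads.append(Read(parts[0], parts[1], int(parts[2]), parts[3]))
    return ReadBatch(reads=reads)


def write_reads_fastq(batch: ReadBatch, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for i, r in enumerate(batch.reads):
            fh.write(f"@{r.probe_id}|{r.accession_id}|hap{r.haplotype}|{i}\n")
            fh.write(r.sequence + "\n+\n" + "I" * len(r.sequence) + "\n")
    return path


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """Everything one simulated SPET experiment produced, in memory."""

    genome: GenomeRef
    annotation: Annotation
    germplasm: GermplasmSet
    panel: list[Probe]
    report: DesignReport
    reads: ReadBatch
    run_config: RunConfig
    sim_config: SimulationConfig


def build_fixture(
    sim_config: SimulationConfig | None = None,
    run_config: RunConfig | None = None,
    seed: int = 0,
    simulate_reads_for: list[str] | None = None,
) -> Fixture:
    """Run the whole simulation in memory: reference, germplasm, candidate
    ascertainment, panel design, reads."""
    sim_config = sim_config or SimulationConfig()
    run_config = run_config or RunConfig.for_mode("tomato-like", seed=seed)
    genome, annotation = generate_reference(sim_config, seed)
    germplasm = simulate_germplasm(genome, sim_config.species, seed + 1)
    snps = _ascertain_candidates(germplasm, sim_config.ascertainment_species)
    panel, report = design_panel(snps, genome, annotation, run_config)
    accessions = germplasm.accessions
    if simulate_reads_for is not None:
        accessions = [a for a in accessions if a.accession_id in simulate_reads_for]
    reads = simulate_reads(panel, accessions, genome, sim_config, seed + 2)
    return Fixture(genome, annotation, germplasm, panel, report, reads,
                   run_config, sim_config)


def _ascertain_candidates(germplasm, cohort_species):
    from .panel import CandidateSNP

    cohort = [
        a for a in germplasm.accessions
        if cohort_species is None or a.species in cohort_species
    ]
    an = 2 * len(cohort)
    snps = []
    for (contig, pos) in sorted(germplasm.sites):
        ref, alt = germplasm.sites[(contig, pos)]
        ac = sum(a.dosage(contig, pos, alt) for a in cohort)
        if ac == 0:
            continue
        maf = min(ac, an - ac) / an
        snps.append(CandidateSNP(contig=contig, pos=pos, ref=ref, alt=alt,
                                 alt_count=ac, maf=maf))
    return snps


def make_fixture(
    out_dir: str | Path,
    sim_config: SimulationConfig | None = None,
    run_config: RunConfig | None = None,
    seed: int = 0,
    fastq: bool = False,
) -> Path:
    """Materialise a fixture directory with a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = build_fixture(sim_config, run_config, seed)
    paths = [
        write_fasta(fx.genome, out / "reference.fasta"),
        write_gff3(fx.annotation, fx.genome, out / "genes.gff3"),
        write_candidate_vcf(fx.germplasm, out / "candidates.vcf",
                            fx.sim_config.ascertainment_species, seed=seed),
        write_truth_vcf(fx.germplasm, out / "truth.vcf", seed=seed),
        write_reads_tsv(fx.reads, out / "reads.tsv", seed=seed),
    ]
    paths += list(write_panel(fx.panel, out / "panel", fx.run_config).values())
    (out / "design_report.tsv").write_text(fx.report.to_tsv())
    paths.append(out / "design_report.tsv")
    if fastq:
        paths.append(write_reads_fastq(fx.reads, out / "reads.fastq"))
    manifest = ["file\tsha256"]
    for p in sorted(paths):
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        manifest.append(f"{p.name}\t{digest}")
    (out / "manifest.tsv").write_text("\n".join(manifest) + "\n")
    return out


def verify_manifest(fixture_dir: str | Path) -> bool:
    """Re-hash every manifest entry; True iff all checksums match."""
    out = Path(fixture_dir)
    for line in (out / "manifest.tsv").read_text().splitlines()[1:]:
        name, digest = line.split("\t")
        if hashlib.sha256((out / name).read_bytes()).hexdigest() != digest:
            return False
    return True
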