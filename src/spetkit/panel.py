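"""SPET probe panel design.

Turns candidate SNPs into a final probe panel through the assay's rules:
cohort-count/MAF eligibility, genomic spacing between selected SNPs
(5 kbp between CDS SNPs, 15 kbp whenever an intron/UTR SNP is involved),
40-base probe placement adjacent to the target, the target-within-25-bp
probe window check, and an optional pilot-coverage selection step.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace

import numpy as np

from .config import RunConfig
from .formats_io import Annotation, GenomeRef

logger = logging.getLogger("spetkit")


@dataclass
class CandidateSNP:
    """One biallelic candidate site with cohort allele information."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_count: int
    maf: float
    feature_class: str | None = None  # CDS / UTR / intron / intergenic
    anchored: bool = True

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.contig}:{self.pos}: ref == alt ({self.ref})")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.contig}:{self.pos}: maf {self.maf} outside [0, 0.5]")
        if self.alt_count < 0:
            raise ValueError(f"{self.contig}:{self.pos}: negative alt_count")


@dataclass
class Probe:
    """A single ~40-base primer adjacent to its target SNP.

    ``start``/``end`` are the probe's 1-based inclusive reference interval;
    the probe sequence is always the forward-strand reference subsequence.
    With orientation ``readout-right`` the 3' end is ``end`` and sequencing
    proceeds to higher coordinates; ``readout-left`` mirrors this.
    """

    id: str
    contig: str
    start: int
    end: int
    orientation: str  # readout-right | readout-left
    target_pos: int
    sequence: str
    readout_start: int
    readout_end: int
    feature_class: str | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("readout-right", "readout-left"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(f"probe {self.id}: sequence length != interval length")
        if self.start <= self.target_pos <= self.end:
            raise ValueError(f"probe {self.id}: target inside probe interval")

    @property
    def three_prime(self) -> int:
        return self.end if self.orientation == "readout-right" else self.start

    @property
    def target_offset(self) -> int:
        """Distance (bp) from the 3' end to the target SNP, >= 1."""
        if self.orientation == "readout-right":
            return self.target_pos - self.end
        return self.start - self.target_pos


@dataclass
class PilotCoverage:
    """Per-probe pilot sequencing depths (one value per pilot sample)."""

    per_sample_depths: dict[str, list[float]]

    def mean_depth(self, probe_id: str) -> float:
        return float(np.mean(self.per_sample_depths[probe_id]))


@dataclass
class DesignReport:
    """Counts surviving each design stage, plus probe-design failures."""

    stage_counts: list[tuple[str, int]] = field(default_factory=list)
    failed_probe_snps: list[CandidateSNP] = field(default_factory=list)

    def add(self, stage: str, count: int) -> None:
        self.stage_counts.append((stage, count))

    def to_tsv(self) -> str:
        lines = ["stage\tcount"]
        lines += [f"{s}\t{c}" for s, c in self.stage_counts]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def classify_feature(
    contig: str,
    pos: int,
    annotation: Annotation,
    contigs: set[str] | None = None,
) -> str:
    """Feature class at a position: CDS beats UTR beats intron; else intergenic."""
    if contigs is not None and contig not in contigs:
        raise KeyError(f"unknown contig {contig!r}")
    for cls in ("CDS", "UTR", "intron"):
        if annotation.overlaps(contig, pos, cls):
            return cls
    return "intergenic"


def filter_eligible(
    snps: list[CandidateSNP], config: RunConfig
) -> list[CandidateSNP]:
    """Apply cohort-count / MAF / anchoring / genic eligibility rules.

    Order of the input is preserved.  Unclassified SNPs count as intergenic.
    """
    out = []
    for s in snps:
        if not s.anchored:
            continue
        if (s.feature_class or "intergenic") == "intergenic":
            continue
        if config.alt_count_strict:
            if not s.alt_count > config.min_alt_count:
                continue
        elif not s.alt_count >= config.min_alt_count:
            continue
        if config.min_maf is not None and not s.maf > config.min_maf:
            continue
        out.append(s)
    if not out:
        logger.warning("filter_eligible: no SNPs passed eligibility")
    return out


def required_spacing(class_a: str, class_b: str, config: RunConfig) -> int:
    """Minimum distance between two selected SNPs, by feature class."""
    if class_a in ("intron", "UTR") or class_b in ("intron", "UTR"):
        return config.spacing_intron_utr
    return config.spacing_cds


class _SpacingTracker:
    """Sorted per-class position lists supporting nearest-neighbour checks."""

    def __init__(self) -> None:
        self.cds: list[int] = []
        self.other: list[int] = []

    @staticmethod
    def _min_gap(positions: list[int], pos: int) -> int:
        if not positions:
            return 1 << 60
        i = bisect_left(positions, pos)
        gap = 1 << 60
        if i > 0:
            gap = min(gap, pos - positions[i - 1])
        if i < len(positions):
            gap = min(gap, positions[i] - pos)
        return gap

    def compatible(self, snp: CandidateSNP, config: RunConfig) -> bool:
        if snp.feature_class == "CDS":
            return (
                self._min_gap(self.cds, snp.pos) >= config.spacing_cds
                and self._min_gap(self.other, snp.pos) >= config.spacing_intron_utr
            )
        gap = min(self._min_gap(self.cds, snp.pos), self._min_gap(self.other, snp.pos))
        return gap >= config.spacing_intron_utr

    def add(self, snp: CandidateSNP) -> None:
        insort(self.cds if snp.feature_class == "CDS" else self.other, snp.pos)


def enforce_spacing(
    eligible: list[CandidateSNP],
    config: RunConfig,
    order: str = "position",
) -> list[CandidateSNP]:
    """Greedy selection of a spacing-valid SNP subset, per contig.

    ``order='position'`` scans left to right (CDS first at equal positions);
    ``order='random'`` offers SNPs in a seed-determined shuffle.  Either way
    a SNP is kept iff it violates no spacing constraint against already
    selected SNPs, so the result is maximal w.r.t. the offer order.
    """
    cls_rank = {"CDS": 0, "UTR": 1, "intron": 2}
    if order == "position":
        offered = sorted(
            eligible, key=lambda s: (s.contig, s.pos, cls_rank.get(s.feature_class, 3))
        )
    elif order == "random":
        rng = np.random.default_rng(config.seed)
        offered = [eligible[i] for i in rng.permutation(len(eligible))]
    else:
        raise ValueError(f"unknown order {order!r}")

    trackers: dict[str, _SpacingTracker] = {}
    chosen: list[CandidateSNP] = []
    for snp in offered:
        tracker = trackers.setdefault(snp.contig, _SpacingTracker())
        if tracker.compatible(snp, config):
            tracker.add(snp)
            chosen.append(snp)
    chosen.sort(key=lambda s: (s.contig, s.pos))
    return chosen


def design_probe(
    snp: CandidateSNP, genome: GenomeRef, config: RunConfig, probe_id: str | None = None
) -> Probe:
    """Place a probe immediately adjacent to the target SNP.

    Both flanks are considered; the probe must lie on-contig and contain no
    N.  A side whose full readout window stays on-contig is preferred, then
    readout-right.  Raises ``ProbeDesignError`` when neither side fits.
    """
    L = config.probe_length
    R = config.readout_length
    clen = genome.length(snp.contig)
    candidates = []
    # readout-right: probe occupies the L bases immediately left of the SNP
    if snp.pos - L >= 1:
        start, end = snp.pos - L, snp.pos - 1
        ro_end = min(end + R, clen)
        candidates.append(("readout-right", start, end, end + 1, ro_end,
                           end + R <= clen))
    # readout-left: probe occupies the L bases immediately right of the SNP
    if snp.pos + L <= clen:
        start, end = snp.pos + 1, snp.pos + L
        ro_start = max(start - R, 1)
        candidates.append(("readout-left", start, end, ro_start, start - 1,
                           start - R >= 1))
    viable = []
    for orient, start, end, ro_s, ro_e, full in candidates:
        seq = genome.fetch(snp.contig, start, end)
        if "N" in seq:
            continue
        viable.append((not full, 0 if orient == "readout-right" else 1,
                       orient, start, end, ro_s, ro_e, seq))
    if not viable:
        raise ProbeDesignError(
            f"no feasible probe side for {snp.contig}:{snp.pos}"
        )
    viable.sort(key=lambda t: t[:2])
    _, _, orient, start, end, ro_s, ro_e, seq = viable[0]
    return Probe(
        id=probe_id or f"probe_{snp.contig}_{snp.pos}",
        contig=snp.contig,
        start=start,
        end=end,
        orientation=orient,
        target_pos=snp.pos,
        sequence=seq,
        readout_start=ro_s,
        readout_end=ro_e,
        feature_class=snp.feature_class,
    )


class ProbeDesignError(ValueError):
    """No feasible probe placement for a SNP."""


def validate_probe_window(probe: Probe, config: RunConfig) -> bool:
    """True iff the target SNP falls in the first ``target_window`` bp
    past the probe 3' end (inclusive)."""
    return 1 <= probe.target_offset <= config.target_window


def pilot_coverage_filter(
    probes: list[Probe], cov: PilotCoverage, config: RunConfig
) -> list[Probe]:
    """Keep probes within the pilot mean-coverage band with few low samples."""
    kept = []
    for p in probes:
        if p.id not in cov.per_sample_depths:
            raise KeyError(f"no pilot coverage for probe {p.id}")
        depths = np.asarray(cov.per_sample_depths[p.id], dtype=float)
        mean = float(depths.mean())
        if not config.cov_mean_min <= mean <= config.cov_mean_max:
            continue
        if config.cov_low_inclusive:
            n_low = int((depths <= config.cov_low_depth).sum())
        else:
            n_low = int((depths < config.cov_low_depth).sum())
        if n_low >= config.cov_max_low_samples:
            continue
        kept.append(p)
    return kept


def design_panel(
    snps: list[CandidateSNP],
    genome: GenomeRef,
    annotation: Annotation,
    config: RunConfig,
    cov: PilotCoverage | None = None,
    target_size: int | None = None,
    order: str = "position",
) -> tuple[list[Probe], DesignReport]:
    """Full design pipeline: classify, filter, space, place, select.

    Returns the final panel and a per-stage count report.  With
    ``target_size`` the surviving probes are down-sampled uniformly at
    random under the config seed.
    """
    report = DesignReport()
    report.add("candidates", len(snps))

    contigs = set(genome.contigs)
    classified = [
        replace(s, feature_class=classify_feature(s.contig, s.pos, annotation, contigs))
        for s in snps
    ]
    report.add("classified", len(classified))

    eligible = filter_eligible(classified, config)
    report.add("eligible", len(eligible))

    spaced = enforce_spacing(eligible, config, order=order)
    report.add("spaced", len(spaced))

    probes: list[Probe] = []
    for i, snp in enumerate(spaced):
        try:
            probe = design_probe(snp, genome, config, probe_id=f"probe_{i:05d}")
        except ProbeDesignError:
            report.failed_probe_snps.append(snp)
            continue
        if validate_probe_window(probe, config):
            probes.append(probe)
    report.add("probes_designed", len(probes))

    if cov is not None:
        probes = pilot_coverage_filter(probes, cov, config)
        report.add("coverage_selected", len(probes))

    if target_size is not None and target_size < len(probes):
        rng = np.random.default_rng(config.seed)
        idx = sorted(rng.choice(len(probes), size=target_size, replace=False))
        probes = [probes[i] for i in idx]
        report.add("downsampled", len(probes))

    for stage, count in report.stage_counts:
        logger.info("design_panel: %s = %d", stage, count)
    return probes, report
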