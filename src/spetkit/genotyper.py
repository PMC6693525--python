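"""Alignment-free targeted genotyping of SPET readouts.

Reads carry their probe of origin, so allele tallying is a direct mapping
from readout offset to reference coordinate — no alignment step.  Calling
follows the assay's re-call thresholds: a genotype needs at least 10 reads;
it is homozygous when the minor-read fraction is at most 0.04, heterozygous
when that fraction lies in [0.25, 0.5], and missing (ambiguous) in between.
Site-level filters reproduce the vcftools-style high-confidence selection
(mean depth, call completeness, at least one non-reference allele) and the
80% genotyping-ratio re-call rule.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .formats_io import GenomeRef
from .panel import Probe
from .simulate import ReadBatch

logger = logging.getLogger("spetkit")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"
_B2I = np.full(128, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _B2I[ord(_b)] = _i

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass
class AlleleDepthTable:
    """Per (site, sample) base counts over all covered readout positions."""

    samples: list[str]
    positions: list[tuple[str, int]]  # (contig, 1-based pos)
    counts: np.ndarray  # (n_positions, n_samples, 4) int32, base order ACGT
    _pos_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.positions), len(self.samples), 4):
            raise ValueError("counts shape does not match axes")
        if not self._pos_index:
            self._pos_index = {p: i for i, p in enumerate(self.positions)}

    def row(self, contig: str, pos: int) -> int:
        return self._pos_index[(contig, pos)]

    def depth(self, contig: str, pos: int, sample_idx: int) -> int:
        i = self._pos_index.get((contig, pos))
        if i is None:
            return 0
        return int(self.counts[i, sample_idx].sum())

    def mean_depth(self, contig: str, pos: int) -> float:
        """Mean total depth across all samples (zero-depth included)."""
        i = self._pos_index.get((contig, pos))
        if i is None:
            return 0.0
        return float(self.counts[i].sum(axis=1).mean())


@dataclass
class Site:
    contig: str
    pos: int
    ref: str
    alt: str
    target: bool


@dataclass
class GenotypeMatrix:
    """Sites x samples genotype calls with target/non-target labels.

    Call codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing.
    """

    sites: list[Site]
    samples: list[str]
    calls: np.ndarray  # (n_sites, n_samples) int8

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError("calls shape does not match axes")

    def subset_sites(self, indices) -> "GenotypeMatrix":
        indices = list(indices)
        return GenotypeMatrix(
            sites=[self.sites[i] for i in indices],
            samples=list(self.samples),
            calls=self.calls[indices].copy() if indices else
            np.zeros((0, len(self.samples)), np.int8),
        )

    def target_mask(self) -> np.ndarray:
        return np.array([s.target for s in self.sites], dtype=bool)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


# ---------------------------------------------------------------------------
# tallying
# ---------------------------------------------------------------------------

def tally_alleles(
    reads: ReadBatch,
    panel: list[Probe],
    genome: GenomeRef,
    samples: list[str] | None = None,
) -> AlleleDepthTable:
    """Count bases per (reference position, sample) from probe readouts.

    Every read contributes one count per covered position; offsets map to
    reference coordinates through the probe's readout window (reads are
    stored reference-forward).
    """
    probes = {p.id: p for p in panel}
    if samples is None:
        samples = sorted({r.accession_id for r in reads.reads})
    sample_index = {s: i for i, s in enumerate(samples)}

    positions: list[tuple[str, int]] = []
    pos_index: dict[tuple[str, int], int] = {}

    def window_rows(probe: Probe) -> np.ndarray:
        rows = np.empty(probe.readout_end - probe.readout_start + 1, dtype=np.int64)
        for k, pos in enumerate(range(probe.readout_start, probe.readout_end + 1)):
            key = (probe.contig, pos)
            i = pos_index.get(key)
            if i is None:
                i = len(positions)
                pos_index[key] = i
                positions.append(key)
            rows[k] = i
        return rows

    # group identical sequences to amortise per-base work
    grouped: dict[tuple[str, str], Counter] = {}
    for r in reads.reads:
        if r.probe_id not in probes:
            raise KeyError(f"read references unknown probe {r.probe_id!r}")
        grouped.setdefault((r.probe_id, r.accession_id), Counter())[r.sequence] += 1

    rows_cache: dict[str, np.ndarray] = {}
    tallies: list[tuple[np.ndarray, int, np.ndarray, int]] = []
    for (probe_id, acc_id), seq_counts in grouped.items():
        probe = probes[probe_id]
        rows = rows_cache.get(probe_id)
        if rows is None:
            rows = rows_cache[probe_id] = window_rows(probe)
        si = sample_index[acc_id]
        for seq, n in seq_counts.items():
            codes = _B2I[np.frombuffer(seq.encode(), dtype=np.uint8)]
            tallies.append((rows[: len(codes)], si, codes, n))

    counts = np.zeros((len(positions), len(samples), 4), dtype=np.int32)
    for rows, si, codes, n in tallies:
        valid = codes >= 0
        np.add.at(counts, (rows[valid], si, codes[valid]), n)
    return AlleleDepthTable(samples=list(samples), positions=positions, counts=counts)


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Call:
    """A raw per-cell call before ref/alt orientation."""

    state: str  # 'hom' | 'het' | 'missing'
    major: str | None = None
    minor: str | None = None


def call_genotype(base_counts, config: RunConfig) -> Call:
    """Call one site x sample cell from its four base counts.

    depth < min -> missing; minor fraction <= hom threshold -> homozygous
    for the major base; minor fraction in the het band -> heterozygous;
    anything between the two bands is ambiguous and stays missing.
    """
    c = np.asarray(base_counts, dtype=np.int64)
    d = int(c.sum())
    if d < config.min_call_depth:
        return Call("missing")
    order = np.argsort(-c, kind="stable")
    major, minor = _BASES[order[0]], _BASES[order[1]]
    f = c[order[1]] / d
    if f <= config.hom_max_minor_fraction:
        return Call("hom", major)
    if config.het_min_minor_fraction <= f <= config.het_max_minor_fraction:
        return Call("het", major, minor)
    return Call("missing")


def discover_sites(
    depths: AlleleDepthTable, panel: list[Probe], config: RunConfig
) -> GenotypeMatrix:
    """Find variant sites in the readout windows and genotype every sample.

    A position becomes a site when at least one sample's call carries a
    non-reference base; the site's alternative allele is the most frequent
    non-reference base over all samples.  Sites at probe target positions
    are flagged target; carriers of a third allele are set missing.
    """
    counts = depths.counts
    n_pos, n_samp, _ = counts.shape
    if n_pos == 0:
        return GenotypeMatrix(sites=[], samples=list(depths.samples),
                              calls=np.zeros((0, n_samp), np.int8))

    ref_idx = np.array(
        [_BASE_INDEX.get(_ref_base_of(depths, panel, i), -1) for i in range(n_pos)],
        dtype=np.int64,
    )
    d = counts.sum(axis=2)
    i1 = counts.argmax(axis=2)
    c1 = np.take_along_axis(counts, i1[:, :, None], axis=2)[:, :, 0]
    masked = counts.copy()
    np.put_along_axis(masked, i1[:, :, None], -1, axis=2)
    i2 = masked.argmax(axis=2)
    c2 = np.take_along_axis(counts, i2[:, :, None], axis=2)[:, :, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(d > 0, c2 / np.maximum(d, 1), 0.0)
    callable_ = d >= config.min_call_depth
    hom = callable_ & (f <= config.hom_max_minor_fraction)
    het = callable_ & (f >= config.het_min_minor_fraction) \
        & (f <= config.het_max_minor_fraction)

    ref_col = ref_idx[:, None]
    nonref_cell = (hom & (i1 != ref_col)) | (het & ((i1 != ref_col) | (i2 != ref_col)))
    site_rows = np.flatnonzero(nonref_cell.any(axis=1))
    if site_rows.size == 0:
        return GenotypeMatrix(sites=[], samples=list(depths.samples),
                              calls=np.zeros((0, n_samp), np.int8))

    target_positions = {(p.contig, p.target_pos) for p in panel}
    totals = counts.sum(axis=1)  # (n_pos, 4)
    sites: list[Site] = []
    calls = np.full((site_rows.size, n_samp), MISSING, dtype=np.int8)
    third_allele_cells = 0
    for out_i, row in enumerate(site_rows):
        contig, pos = depths.positions[row]
        ref_b = ref_idx[row]
        tot = totals[row].copy()
        if ref_b >= 0:
            tot[ref_b] = -1
        alt_b = int(np.argmax(tot))
        sites.append(
            Site(contig=contig, pos=pos, ref=_BASES[ref_b], alt=_BASES[alt_b],
                 target=(contig, pos) in target_positions)
        )
        for j in range(n_samp):
            if hom[row, j]:
                if i1[row, j] == ref_b:
                    calls[out_i, j] = HOM_REF
                elif i1[row, j] == alt_b:
                    calls[out_i, j] = HOM_ALT
                else:
                    third_allele_cells += 1
            elif het[row, j]:
                pair = {int(i1[row, j]), int(i2[row, j])}
                if pair == {int(ref_b), alt_b}:
                    calls[out_i, j] = HET
                else:
                    third_allele_cells += 1
    if third_allele_cells:
        logger.info("discover_sites: %d third-allele genotype cells set missing",
                    third_allele_cells)
    return GenotypeMatrix(sites=sites, samples=list(depths.samples), calls=calls)


def _ref_base_of(depths: AlleleDepthTable, panel: list[Probe], row: int) -> str:
    # lazily attach a genome lookup: the reference base is cached on the
    # table the first time discover_sites runs
    cache = getattr(depths, "_ref_cache", None)
    if cache is None:
        raise RuntimeError(
            "AlleleDepthTable lacks reference bases; call attach_reference() first"
        )
    return cache[row]


def attach_reference(depths: AlleleDepthTable, genome: GenomeRef) -> AlleleDepthTable:
    """Record the reference base for every tallied position."""
    cache = [genome.contigs[c][p - 1] for c, p in depths.positions]
    depths._ref_cache = cache  # type: ignore[attr-defined]
    return depths


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

def filter_high_confidence(
    matrix: GenotypeMatrix, depths: AlleleDepthTable, config: RunConfig
) -> GenotypeMatrix:
    """vcftools-style site selection: mean depth >= min-meanDP, call
    completeness >= max-missing, and at least one non-reference call."""
    keep = []
    for i, site in enumerate(matrix.sites):
        if depths.mean_depth(site.contig, site.pos) < config.min_mean_depth:
            continue
        row = matrix.calls[i]
        called = row != MISSING
        if called.mean() < config.max_missing:
            continue
        if not np.any((row == HET) | (row == HOM_ALT)):
            continue
        keep.append(i)
    return matrix.subset_sites(keep)


@dataclass
class RecallReport:
    retained: int
    total: int

    @property
    def fraction(self) -> float:
        return self.retained / self.total if self.total else 0.0


def recall_filter(
    matrix: GenotypeMatrix, depths: AlleleDepthTable, config: RunConfig
) -> tuple[GenotypeMatrix, RecallReport]:
    """Drop sites genotyped in fewer than the required fraction of samples
    (the 80% genotyping-ratio rule, boundary inclusive)."""
    keep = [
        i for i in range(matrix.n_sites)
        if (matrix.calls[i] != MISSING).mean() >= config.genotyping_ratio
    ]
    report = RecallReport(retained=len(keep), total=matrix.n_sites)
    return matrix.subset_sites(keep), report


def genotype_pipeline(
    reads: ReadBatch,
    panel: list[Probe],
    genome: GenomeRef,
    config: RunConfig,
    samples: list[str] | None = None,
) -> tuple[GenotypeMatrix, AlleleDepthTable, RecallReport]:
    """tally -> discover -> high-confidence filter -> re-call filter."""
    depths = tally_alleles(reads, panel, genome, samples=samples)
    attach_reference(depths, genome)
    matrix = discover_sites(depths, panel, config)
    matrix = filter_high_confidence(matrix, depths, config)
    matrix, report = recall_filter(matrix, depths, config)
    return matrix, depths, report
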