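"""Reading and writing the standard formats the toolkit touches.

Conventions, stated once: internal coordinates and everything in the public
API are 1-based inclusive (the VCF/GFF3 dialect); BED output is 0-based
half-open.  Candidate SNPs and probes live on the forward strand of the
reference; probe orientation is an attribute, never a stored
reverse-complement.
"""

from __future__ import annotations

import logging
import re
import tempfile
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import pysam
from Bio import SeqIO

from .config import RunConfig

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .genotyper import AlleleDepthTable, GenotypeMatrix
    from .panel import CandidateSNP, Probe
    from .relationships import Tree

logger = logging.getLogger("spetkit")

DNA_ALPHABET = set("ACGTN")
#: default pattern distinguishing anchored chromosomes from scaffolds:
#: '|'-separated regexes where a bare '*' is shorthand for '.*'.
DEFAULT_ANCHORED_PATTERN = "chr*|[0-9]+"


def _compile_anchored_pattern(pattern: str) -> re.Pattern:
    parts = [re.sub(r"(?<![.\\])\*", ".*", p) for p in pattern.split("|") if p]
    return re.compile("|".join(f"(?:{p})" for p in parts))


def is_anchored(contig: str, pattern: str = DEFAULT_ANCHORED_PATTERN) -> bool:
    return _compile_anchored_pattern(pattern).fullmatch(contig) is not None


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeRef:
    """A reference genome held in memory.

    contigs maps contig id to an uppercase DNA string; anchored marks
    chromosome-level sequences (as opposed to unplaced scaffolds).
    """

    contigs: dict[str, str]
    anchored: dict[str, bool]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {cid!r} has empty sequence")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"contig {cid!r} contains non-DNA characters {sorted(bad)}"
                )
        missing = set(self.contigs) - set(self.anchored)
        if missing:
            raise ValueError(f"anchored flags missing for contigs {sorted(missing)}")

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Subsequence on 1-based inclusive [start, end]."""
        seq = self.contigs[contig]
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(f"[{start}, {end}] outside {contig} (len {len(seq)})")
        return seq[start - 1 : end]

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])


FEATURE_CLASSES = ("CDS", "UTR", "intron")


@dataclass
class Annotation:
    """Classified genic intervals: (contig, start, end, class, gene_id).

    Coordinates are 1-based inclusive.  Anything not covered by a CDS, UTR
    or intron interval is intergenic by omission.
    """

    features: list[tuple[str, int, int, str, str]]
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for contig, start, end, cls, gene in self.features:
            if start > end:
                raise ValueError(f"feature {gene} on {contig}: start {start} > end {end}")
            if cls not in FEATURE_CLASSES:
                raise ValueError(f"unknown feature class {cls!r}")

    def _build_index(self) -> None:
        # per (contig, class): starts sorted, with a prefix running max of
        # ends -> O(log n) interval-stabbing existence query
        by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for contig, start, end, cls, _gene in self.features:
            by_key.setdefault((contig, cls), []).append((start, end))
        for key, ivals in by_key.items():
            ivals.sort()
            starts = [s for s, _ in ivals]
            maxend = []
            running = 0
            for _, e in ivals:
                running = max(running, e)
                maxend.append(running)
            self._index[key] = (starts, maxend)

    def overlaps(self, contig: str, pos: int, cls: str) -> bool:
        """True iff 1-based position ``pos`` lies in any ``cls`` interval."""
        if not self._index and self.features:
            self._build_index()
        entry = self._index.get((contig, cls))
        if entry is None:
            return False
        starts, maxend = entry
        i = bisect_right(starts, pos)
        return i > 0 and maxend[i - 1] >= pos

    def contigs(self) -> set[str]:
        return {f[0] for f in self.features}


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genome(
    path: str | Path, anchored_pattern: str = DEFAULT_ANCHORED_PATTERN
) -> GenomeRef:
    """Load a FASTA reference; flag anchored chromosomes by id pattern."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains non-DNA characters {sorted(bad)}"
            )
        contigs[rec.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    anchored = {cid: is_anchored(cid, anchored_pattern) for cid in contigs}
    return GenomeRef(contigs=contigs, anchored=anchored)


def read_candidate_vcf(
    path: str | Path,
    anchored_pattern: str = DEFAULT_ANCHORED_PATTERN,
) -> "list[CandidateSNP]":
    """Parse a candidate VCF into biallelic SNP records.

    Multiallelic rows and indels are dropped (count logged).  Alternative
    allele counts come from INFO AC/AN when present, otherwise from the
    genotype columns.
    """
    from .panel import CandidateSNP

    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    out: list[CandidateSNP] = []
    dropped = 0
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1 \
                or rec.ref not in "ACGT" or alts[0] not in "ACGT":
            dropped += 1
            continue
        ac, an = _allele_counts(rec, path)
        maf = min(ac, an - ac) / an if an else 0.0
        out.append(
            CandidateSNP(
                contig=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alts[0],
                alt_count=ac,
                maf=maf,
                anchored=is_anchored(rec.chrom, anchored_pattern),
            )
        )
    if dropped:
        logger.info("read_candidate_vcf: dropped %d non-biallelic/indel rows", dropped)
    if not out:
        logger.warning("read_candidate_vcf: no biallelic SNPs found in %s", path)
    return out


def _allele_counts(rec, path) -> tuple[int, int]:
    info = rec.info
    if "AC" in info and "AN" in info:
        ac = info["AC"]
        if isinstance(ac, tuple):
            ac = ac[0]
        return int(ac), int(info["AN"])
    ac = an = 0
    found = False
    for sample in rec.samples.values():
        gt = sample.get("GT")
        if gt is None:
            continue
        for allele in gt:
            if allele is None:
                continue
            found = True
            an += 1
            if allele > 0:
                ac += 1
    if not found:
        raise ValueError(
            f"{path} row {rec.chrom}:{rec.pos}: no AC/AN INFO and no genotype "
            "columns; provide genotypes so allele counts can be computed"
        )
    return ac, an


def read_annotation(
    path: str | Path, contigs: Iterable[str] | None = None
) -> Annotation:
    """Load GFF3 gene models into classified CDS/UTR/intron intervals.

    Introns are derived per mRNA as the gaps between consecutive exons;
    overlapping exons within one mRNA are an error.  If ``contigs`` is
    given, features on unknown contigs are an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    known = set(contigs) if contigs is not None else None
    features: list[tuple[str, int, int, str, str]] = []

    def gene_of(feat) -> str:
        parents = feat.attributes.get("Parent")
        return parents[0] if parents else feat.id

    for ftype, cls in (
        ("CDS", "CDS"),
        ("five_prime_UTR", "UTR"),
        ("three_prime_UTR", "UTR"),
        ("UTR", "UTR"),
    ):
        for feat in db.features_of_type(ftype):
            if known is not None and feat.seqid not in known:
                raise ValueError(f"feature on unknown contig {feat.seqid!r}")
            features.append((feat.seqid, feat.start, feat.end, cls, gene_of(feat)))

    for mrna in db.features_of_type("mRNA"):
        if known is not None and mrna.seqid not in known:
            raise ValueError(f"mRNA on unknown contig {mrna.seqid!r}")
        exons = sorted(
            (e.start, e.end) for e in db.children(mrna, featuretype="exon")
        )
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping exons [{s1},{e1}] and [{s2},{e2}] in mRNA {mrna.id}"
                )
            if s2 > e1 + 1:
                features.append((mrna.seqid, e1 + 1, s2 - 1, "intron", mrna.id))
    return Annotation(features=features)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _header_comment(config: RunConfig | None) -> list[str]:
    if config is None:
        return []
    return [f"#{k}={v}" for k, v in config.header_items()[:2]]


def write_panel(
    panel: "list[Probe]", out_prefix: str | Path, config: RunConfig | None = None
) -> dict[str, Path]:
    """Write a probe panel as BED + FASTA + TSV under ``out_prefix``.

    BED intervals are 0-based half-open; the TSV carries probe id, target
    SNP position, orientation and feature class.  Returns the paths.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "bed": prefix.with_suffix(".bed"),
        "fasta": prefix.with_suffix(".fasta"),
        "tsv": prefix.with_suffix(".tsv"),
    }
    head = _header_comment(config)
    with open(paths["bed"], "w") as bed:
        for line in head:
            bed.write(line + "\n")
        for p in panel:
            bed.write(f"{p.contig}\t{p.start - 1}\t{p.end}\t{p.id}\n")
    with open(paths["fasta"], "w") as fa:
        for p in panel:
            fa.write(f">{p.id}\n{p.sequence}\n")
    with open(paths["tsv"], "w") as tsv:
        for line in head:
            tsv.write(line + "\n")
        tsv.write(
            "probe_id\tcontig\tstart\tend\torientation\ttarget_pos\t"
            "feature_class\treadout_start\treadout_end\n"
        )
        for p in panel:
            tsv.write(
                f"{p.id}\t{p.contig}\t{p.start}\t{p.end}\t{p.orientation}\t"
                f"{p.target_pos}\t{p.feature_class}\t{p.readout_start}\t"
                f"{p.readout_end}\n"
            )
    return paths


def read_panel(prefix: str | Path) -> "list[Probe]":
    """Load a probe panel back from its TSV + FASTA pair."""
    from .panel import Probe

    prefix = Path(prefix)
    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(prefix.with_suffix(".fasta")), "fasta")
    }
    probes = []
    with open(prefix.with_suffix(".tsv")) as fh:
        header = None
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts
                continue
            row = dict(zip(header, parts))
            probes.append(
                Probe(
                    id=row["probe_id"],
                    contig=row["contig"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    orientation=row["orientation"],
                    target_pos=int(row["target_pos"]),
                    sequence=seqs[row["probe_id"]],
                    readout_start=int(row["readout_start"]),
                    readout_end=int(row["readout_end"]),
                    feature_class=row["feature_class"] or None,
                )
            )
    return probes


_CALL_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_genotype_vcf(
    matrix: "GenotypeMatrix",
    depths: "AlleleDepthTable | None",
    path: str | Path,
    config: RunConfig | None = None,
) -> Path:
    """Write calls (and per-sample depths) as a VCF 4.2 text file.

    Sites designed into the panel carry the INFO flag ``TARGET``; the
    header records the run seed and mode.
    """
    path = Path(path)
    if depths is not None and list(depths.samples) != list(matrix.samples):
        raise ValueError("matrix and depth table have different sample axes")
    lines = ["##fileformat=VCFv4.2"]
    if config is not None:
        for k, v in config.header_items()[:2]:
            lines.append(f"##{k}={v}")
    lines += [
        '##INFO=<ID=TARGET,Number=0,Type=Flag,Description="Panel target SNP">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for contig in sorted({s.contig for s in matrix.sites}):
        lines.append(f"##contig=<ID={contig}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
    )
    order = sorted(range(len(matrix.sites)),
                   key=lambda i: (matrix.sites[i].contig, matrix.sites[i].pos))
    for i in order:
        site = matrix.sites[i]
        info = "TARGET" if site.target else "."
        fields = [site.contig, str(site.pos), ".", site.ref, site.alt,
                  ".", "PASS", info, "GT:DP"]
        for j in range(len(matrix.samples)):
            gt = _CALL_TO_GT[int(matrix.calls[i, j])]
            dp = depths.depth(site.contig, site.pos, j) if depths is not None else 0
            fields.append(f"{gt}:{dp}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_genotype_vcf(path: str | Path) -> "GenotypeMatrix":
    """Read a (possibly spetkit-written) VCF back into a genotype matrix."""
    import numpy as np

    from .genotyper import GenotypeMatrix, Site

    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    sites: list[Site] = []
    rows: list[list[int]] = []
    gt_code = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}
    for rec in vcf:
        alts = rec.alts or (".",)
        sites.append(
            Site(contig=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alts[0],
                 target="TARGET" in rec.info)
        )
        row = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or None in gt:
                row.append(-1)
            else:
                row.append(gt_code.get(tuple(gt), -1))
        rows.append(row)
    calls = np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(samples)), np.int8)
    return GenotypeMatrix(sites=sites, samples=samples, calls=calls)


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

_NEWICK_RESERVED = re.compile(r"[\s()\[\]{}:;,']")


def _quote_label(label: str) -> str:
    if _NEWICK_RESERVED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: "Tree") -> str:
    """Serialise a tree with branch lengths and integer supports."""

    def fmt_len(x: float) -> str:
        return format(x, ".10g")

    def render(node) -> str:
        if not node.children:
            return _quote_label(node.label)
        inner = ",".join(
            render(c) + ":" + fmt_len(c.length) for c in node.children
        )
        sup = "" if node.support is None else str(int(round(node.support)))
        return f"({inner}){sup}"

    return render(tree.root) + ";"


def write_newick(
    tree: "Tree", path: str | Path, config: RunConfig | None = None
) -> Path:
    path = Path(path)
    lines = []
    if config is not None:
        lines.append(
            "[" + " ".join(f"{k}={v}" for k, v in config.header_items()[:2]) + "]"
        )
    lines.append(to_newick(tree))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_newick(path_or_string: str | Path) -> "Tree":
    """Parse newick (via dendropy) into a spetkit tree."""
    import dendropy

    from .relationships import Tree, TreeNode

    s = str(path_or_string)
    if "(" not in s:
        s = Path(s).read_text()
    # strip comment blocks written by write_newick
    s = re.sub(r"\[[^\]]*\]", "", s).strip()
    dtree = dendropy.Tree.get(data=s, schema="newick",
                              suppress_internal_node_taxa=True,
                              preserve_underscores=True)

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            node = TreeNode(label=dnode.taxon.label)
        else:
            sup = None
            if dnode.label is not None:
                try:
                    sup = float(dnode.label)
                except ValueError:
                    sup = None
            node = TreeNode(label="", support=sup)
            for child in dnode.child_nodes():
                cn = convert(child)
                cn.length = child.edge.length if child.edge.length is not None else 0.0
                node.children.append(cn)
        return node

    return Tree(root=convert(dtree.seed_node))
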