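"""Per-site and per-accession diversity statistics.

Covers the fingerprinting side of a SPET assay: polymorphic information
content (PIC = 1 - sum p_j^2), per-accession missing-data / heterozygosity /
reference-identity percentages, pairwise genotype discordance, duplicate
grouping, and passport-mislabel flagging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .genotyper import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING, AlleleDepthTable

logger = logging.getLogger("spetkit")


def pic(frequencies) -> float:
    """Polymorphic information content of one site: 1 - sum(p_j^2).

    ``frequencies`` are the called-allele frequencies and must sum to 1.
    For a biallelic site the maximum is 0.5 at p = q = 0.5.
    """
    p = np.asarray(frequencies, dtype=float)
    if p.size == 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies must sum to 1, got {p.tolist()}")
    if np.any(p < 0):
        raise ValueError("negative allele frequency")
    return float(1.0 - np.sum(p**2))


@dataclass
class SiteStats:
    contig: str
    pos: int
    alt_frequency: float
    pic: float
    mean_depth: float
    missing_fraction: float
    target: bool


def site_stats(
    matrix: GenotypeMatrix, depths: AlleleDepthTable | None = None
) -> list[SiteStats]:
    """Allele frequency, PIC, depth and missingness per site.

    Frequencies use called genotypes only (missing excluded), so they sum
    to 1 by construction; monomorphic-after-missing sites get PIC 0.
    """
    out = []
    for i, site in enumerate(matrix.sites):
        row = matrix.calls[i]
        called = row != MISSING
        n = int(called.sum())
        if n == 0:
            p_alt = 0.0
        else:
            p_alt = float((2 * (row == HOM_ALT).sum() + (row == HET).sum()) / (2 * n))
        out.append(
            SiteStats(
                contig=site.contig,
                pos=site.pos,
                alt_frequency=p_alt,
                pic=pic([1 - p_alt, p_alt]) if 0 < p_alt < 1 else 0.0,
                mean_depth=depths.mean_depth(site.contig, site.pos) if depths else 0.0,
                missing_fraction=1.0 - n / len(row),
                target=site.target,
            )
        )
    return out


@dataclass
class AccessionStats:
    accession: str
    missing_pct: float
    het_pct: float | None  # None when no sites were called
    ref_identity_pct: float | None


def accession_stats(matrix: GenotypeMatrix) -> list[AccessionStats]:
    """Missing %, heterozygosity % and reference-identity % per accession.

    Missing is over all sites; het and identity are over non-missing calls.
    Identity counts hom-ref calls only (a het is not identical to the
    reference).
    """
    out = []
    for j, name in enumerate(matrix.samples):
        col = matrix.calls[:, j]
        total = len(col)
        called = col != MISSING
        n = int(called.sum())
        missing_pct = 100.0 * (1 - n / total) if total else 0.0
        if n == 0:
            warnings.warn(f"accession {name}: no called sites; het/identity undefined")
            out.append(AccessionStats(name, missing_pct, None, None))
            continue
        het_pct = 100.0 * (col == HET).sum() / n
        ident_pct = 100.0 * (col == HOM_REF).sum() / n
        out.append(AccessionStats(name, missing_pct, float(het_pct), float(ident_pct)))
    return out


def pairwise_discordance(matrix: GenotypeMatrix) -> np.ndarray:
    """Fraction of co-called sites with differing genotype calls, per pair.

    Returns a symmetric matrix with zero diagonal; pairs with no co-called
    sites get NaN with a warning.
    """
    calls = matrix.calls
    n = calls.shape[1]
    if n < 2:
        raise ValueError("need at least 2 accessions")
    out = np.zeros((n, n), dtype=float)
    called = calls != MISSING
    for a in range(n):
        for b in range(a + 1, n):
            both = called[:, a] & called[:, b]
            m = int(both.sum())
            if m == 0:
                warnings.warn(
                    f"accessions {matrix.samples[a]} / {matrix.samples[b]}: "
                    "no co-called sites; discordance undefined"
                )
                out[a, b] = out[b, a] = np.nan
                continue
            diff = (calls[both, a] != calls[both, b]).sum()
            out[a, b] = out[b, a] = diff / m
    return out


def flag_duplicates(
    discordance: np.ndarray,
    samples: list[str],
    threshold: float = 0.002,
) -> list[list[str]]:
    """Group accessions whose pairwise discordance is below ``threshold``.

    Pairs under the threshold form edges; duplicate groups are the
    connected components with at least two members.
    """
    n = len(samples)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(n):
        for b in range(a + 1, n):
            d = discordance[a, b]
            if np.isfinite(d) and d < threshold:
                parent[find(a)] = find(b)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(samples[i])
    return sorted((sorted(g) for g in groups.values() if len(g) > 1),
                  key=lambda g: g[0])


@dataclass
class MislabelFlag:
    accession: str
    passport_group: str
    nearest_group: str
    nearest_discordance: float
    passport_discordance: float


def flag_mislabels(
    matrix: GenotypeMatrix,
    passport: dict[str, str],
    margin: float = 0.5,
) -> list[MislabelFlag]:
    """Flag accessions genetically nearer a foreign passport group.

    An accession is flagged when its nearest group (by mean discordance,
    self excluded) differs from its passport group and the nearest-group
    mean discordance is below ``margin`` times the passport-group mean.
    Accessions in singleton groups are skipped with a warning.
    """
    disc = pairwise_discordance(matrix)
    samples = matrix.samples
    groups: dict[str, list[int]] = {}
    for j, s in enumerate(samples):
        groups.setdefault(passport[s], []).append(j)
    if len(groups) < 2:
        warnings.warn("flag_mislabels: need at least two passport groups")
        return []
    flags = []
    for j, s in enumerate(samples):
        own = passport[s]
        if len(groups[own]) < 2:
            warnings.warn(f"accession {s}: singleton passport group {own!r}; skipped")
            continue
        means = {}
        for gname, members in groups.items():
            others = [m for m in members if m != j]
            if not others:
                continue
            vals = disc[j, others]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                means[gname] = float(vals.mean())
        if own not in means:
            continue
        nearest = min(means, key=means.get)
        if nearest != own and means[nearest] < margin * means[own]:
            flags.append(
                MislabelFlag(
                    accession=s,
                    passport_group=own,
                    nearest_group=nearest,
                    nearest_discordance=means[nearest],
                    passport_discordance=means[own],
                )
            )
    return flags
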