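"""Genetic relationships: distances, neighbor-joining trees with
SNP-resampling bootstrap, Robinson-Foulds tree comparison, and genotype PCA.

The tree machinery is implemented here rather than delegated: NJ follows
the Saitou-Nei Q-criterion agglomeration with deterministic tie-breaking,
and Robinson-Foulds is the symmetric difference of non-trivial bipartition
sets, normalised by 2(n-3) for binary unrooted trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotyper import GenotypeMatrix, MISSING


# ---------------------------------------------------------------------------
# tree structures
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    label: str = ""
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0  # edge length to parent
    support: float | None = None

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree stored as a rooted structure with a basal multifurcation."""

    root: TreeNode

    def taxa(self) -> set[str]:
        return {leaf.label for leaf in self.root.leaves()}

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalised as the side that does not
        contain the lexicographically smallest taxon."""
        all_taxa = self.taxa()
        ref = min(all_taxa)
        splits: set[frozenset] = set()

        def walk(node: TreeNode) -> set[str]:
            if not node.children:
                return {node.label}
            below = set()
            for c in node.children:
                below |= walk(c)
            if node is not self.root and 2 <= len(below) <= len(all_taxa) - 2:
                side = below if ref not in below else all_taxa - below
                splits.add(frozenset(side))
            return below

        walk(self.root)
        return splits

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode) -> None:
            if node.children:
                if node is not self.root:
                    out.append(node)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if m.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(m < -1e-12):
            raise ValueError("negative distances")
        self.matrix = m


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def genetic_distance(
    matrix: GenotypeMatrix, method: str = "allele-sharing"
) -> DistanceMatrix:
    """Allele-sharing distance over pairwise co-called sites.

    Per site a pair shares 1 for identical genotypes, 0.5 for het vs hom,
    0 for opposite homozygotes; the distance is one minus the mean share.
    """
    if method != "allele-sharing":
        raise ValueError(f"unknown distance method {method!r}")
    calls = matrix.calls
    n = calls.shape[1]
    if n < 2:
        raise ValueError("need at least 2 accessions")
    dosage = calls.astype(float)
    dosage[calls == MISSING] = np.nan
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            diff = np.abs(dosage[:, a] - dosage[:, b])
            ok = ~np.isnan(diff)
            if not ok.any():
                raise ValueError(
                    f"no co-called sites for pair "
                    f"({matrix.samples[a]}, {matrix.samples[b]})"
                )
            d = float(np.mean(diff[ok]) / 2.0)
            out[a, b] = out[b, a] = d
    return DistanceMatrix(taxa=list(matrix.samples), matrix=out)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dist: DistanceMatrix) -> Tree:
    """Neighbor joining on the Q-criterion.

    Ties in Q break toward the lowest (i, j) node-index pair; negative
    branch-length estimates are clamped to zero with the deficit moved to
    the sister branch.
    """
    n = len(dist.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=t) for t in dist.taxa]
    D = dist.matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin over the row-major flattened matrix: ties resolve to the
        # lexicographically smallest (i, j)
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = float(li), float(lj)
        new = TreeNode(children=[child_i, child_j])
        nodes.append(new)
        u = len(nodes) - 1
        newD = np.zeros((u + 1, u + 1))
        newD[:u, :u] = D
        for ak in active:
            if ak in (i, j):
                continue
            duk = 0.5 * (D[i, ak] + D[j, ak] - dij)
            newD[u, ak] = newD[ak, u] = max(duk, 0.0)
        D = newD
        active = [a for a in active if a not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = TreeNode()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = float(max(ln, 0.0))
        root.children.append(nodes[idx])
    return Tree(root=root)


def bootstrap_support(
    matrix: GenotypeMatrix,
    replicates: int = 100,
    seed: int = 0,
    method: str = "allele-sharing",
) -> Tree:
    """Main NJ tree with SNP-resampling bootstrap supports.

    Each replicate resamples sites with replacement, rebuilds the distance
    matrix and NJ tree, and each internal edge of the main tree gets the
    percentage of replicates containing its bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    main = nj_tree(genetic_distance(matrix, method=method))
    all_taxa = main.taxa()
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    n_sites = matrix.n_sites
    for _ in range(replicates):
        idx = rng.integers(0, n_sites, size=n_sites)
        resampled = matrix.subset_sites(idx)
        try:
            rep = nj_tree(genetic_distance(resampled, method=method))
        except ValueError:
            continue
        for bp in rep.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1

    ref = min(all_taxa)

    def walk(node: TreeNode) -> set[str]:
        if not node.children:
            return {node.label}
        below = set()
        for c in node.children:
            below |= walk(c)
        if node is not main.root and 2 <= len(below) <= len(all_taxa) - 2:
            side = below if ref not in below else all_taxa - below
            node.support = 100.0 * counts.get(frozenset(side), 0) / replicates
        return below

    walk(main.root)
    return main


def robinson_foulds(t1: Tree, t2: Tree) -> tuple[int, float]:
    """Robinson-Foulds distance and its normalised form.

    rf is the size of the symmetric difference of the non-trivial
    bipartition sets; normalised by the total number of internal edges in
    both trees (2(n-3) when both are binary).
    """
    tax1, tax2 = t1.taxa(), t2.taxa()
    if tax1 != tax2:
        raise ValueError(
            f"taxon sets differ: only-in-first={sorted(tax1 - tax2)}, "
            f"only-in-second={sorted(tax2 - tax1)}"
        )
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    rf = len(b1 ^ b2)
    denom = len(b1) + len(b2)
    return rf, (rf / denom if denom else 0.0)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    samples: list[str]
    loadings: np.ndarray  # (n_samples, k), orthonormal columns
    variance_fractions: np.ndarray  # (k,)


def pca(matrix: GenotypeMatrix, k: int = 2) -> PCAResult:
    """PCA of the alt-allele dosage matrix.

    Genotypes are encoded 0/1/2, missing values imputed with the site
    mean, each site centred and scaled by sqrt(p(1-p)) with p the alt
    frequency; sites monomorphic after imputation contribute nothing.
    Eigenvectors of the accession covariance are returned (orthonormal),
    with variance fractions over all components.
    """
    calls = matrix.calls
    n_sites, n_samp = calls.shape
    if n_samp < 2:
        raise ValueError("need at least 2 accessions")
    dosage = calls.astype(float)
    dosage[calls == MISSING] = np.nan
    site_mean = np.nanmean(np.where(np.isnan(dosage), np.nan, dosage), axis=1)
    site_mean = np.where(np.isnan(site_mean), 0.0, site_mean)
    filled = np.where(np.isnan(dosage), site_mean[:, None], dosage)
    p = site_mean / 2.0
    scale = np.sqrt(p * (1 - p))
    ok = scale > 1e-12
    if not ok.any():
        raise ValueError("no polymorphic sites after imputation")
    X = (filled[ok] - site_mean[ok, None]) / scale[ok, None]  # sites x samples
    cov = X.T @ X / X.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    fractions = eigvals / total if total > 0 else eigvals
    rank = int((eigvals > 1e-12 * max(total, 1.0)).sum())
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; truncating")
        k = rank
    return PCAResult(
        samples=list(matrix.samples),
        loadings=eigvecs[:, :k],
        variance_fractions=fractions[:k],
    )
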