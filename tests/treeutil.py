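"""Tree-generation helpers and independent oracles for the tree tests."""

import dendropy
import numpy as np

from spetkit.relationships import DistanceMatrix, Tree, TreeNode


def random_binary_tree(taxa: list[str], rng: np.random.Generator,
                       min_len: float = 0.1, max_len: float = 1.0) -> Tree:
    """Random unrooted binary tree via sequential random edge attachment."""
    assert len(taxa) >= 3

    def elen() -> float:
        return float(rng.uniform(min_len, max_len))

    nodes = [TreeNode(label=t, length=elen()) for t in taxa[:3]]
    root = TreeNode(children=nodes)
    edges = list(nodes)  # nodes whose parent edge can be split
    parents = {id(n): root for n in nodes}
    for label in taxa[3:]:
        target = edges[int(rng.integers(0, len(edges)))]
        parent = parents[id(target)]
        mid = TreeNode(length=target.length * 0.5)
        target.length *= 0.5
        leaf = TreeNode(label=label, length=elen())
        parent.children[parent.children.index(target)] = mid
        mid.children = [target, leaf]
        parents[id(mid)] = parent
        parents[id(target)] = mid
        parents[id(leaf)] = mid
        edges += [mid, leaf]
    return Tree(root=root)


def additive_distances(tree: Tree) -> DistanceMatrix:
    """Exact leaf-to-leaf path-length matrix of a tree (graph search)."""
    leaves = [l.label for l in tree.root.leaves()]
    adj: dict[int, list[tuple[int, float]]] = {}
    labels: dict[int, str] = {}

    def build(node):
        labels[id(node)] = node.label
        for c in node.children:
            adj.setdefault(id(node), []).append((id(c), c.length))
            adj.setdefault(id(c), []).append((id(node), c.length))
            build(c)

    build(tree.root)

    def leaf_dists(start_label):
        start = next(k for k, v in labels.items() if v == start_label)
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adj.get(u, []):
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        return {labels[k]: d for k, d in dist.items() if labels[k]}

    n = len(leaves)
    m = np.zeros((n, n))
    for i, a in enumerate(leaves):
        d = leaf_dists(a)
        for j, b in enumerate(leaves):
            if i != j:
                m[i, j] = d[b]
    m = (m + m.T) / 2
    return DistanceMatrix(taxa=leaves, matrix=m)


def dendropy_rf(t1: Tree, t2: Tree) -> int:
    """Independent Robinson-Foulds oracle via dendropy."""
    from spetkit.formats_io import to_newick

    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=to_newick(t1), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    d2 = dendropy.Tree.get(data=to_newick(t2), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)
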