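import numpy as np
import pytest

import spetkit as sk
from spetkit.genotyper import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING, Site
from spetkit.relationships import DistanceMatrix, Tree, TreeNode

from treeutil import additive_distances, dendropy_rf, random_binary_tree


def matrix_from(calls):
    calls = np.asarray(calls, dtype=np.int8)
    sites = [Site("chr1", i + 1, "A", "G", True) for i in range(calls.shape[0])]
    samples = [f"s{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(sites=sites, samples=samples, calls=calls)


class TestGeneticDistance:
    def test_identical_accessions(self):
        col = np.tile([HOM_REF, HET, HOM_ALT], 10)
        d = sk.genetic_distance(matrix_from(np.column_stack([col, col])))
        assert d.matrix[0, 1] == 0.0

    def test_opposite_homozygotes(self):
        a = np.full(20, HOM_REF, dtype=np.int8)
        b = np.full(20, HOM_ALT, dtype=np.int8)
        d = sk.genetic_distance(matrix_from(np.column_stack([a, b])))
        assert d.matrix[0, 1] == 1.0

    def test_het_vs_hom_half_distance(self):
        d = sk.genetic_distance(matrix_from([[HET, HOM_REF]]))
        assert d.matrix[0, 1] == 0.5

    def test_no_co_called_sites_is_an_error(self):
        a = np.array([HOM_REF, MISSING], dtype=np.int8)
        b = np.array([MISSING, HOM_REF], dtype=np.int8)
        with pytest.raises(ValueError, match="no co-called"):
            sk.genetic_distance(matrix_from(np.column_stack([a, b])))


class TestNjTree:
    def test_three_taxa_three_point_formula(self):
        d = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = sk.nj_tree(d)
        lengths = {leaf.label: leaf.length for leaf in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_quartet_topology_recovered(self):
        # tree ((A,B),(C,D)) with internal edge 2: enumerate all three
        # quartet splits and check NJ picks the only additive-consistent one
        d = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array([
                [0, 2, 7, 7],
                [2, 0, 7, 7],
                [7, 7, 0, 2],
                [7, 7, 2, 0],
            ], float),
        )
        tree = sk.nj_tree(d)
        assert tree.bipartitions() == {frozenset({"C", "D"})}

    def test_additive_matrices_recover_generating_topology(self, rng):
        for n in (5, 7, 10):
            for _ in range(5):
                taxa = [f"t{i}" for i in range(n)]
                true = random_binary_tree(taxa, rng)
                rec = sk.nj_tree(additive_distances(true))
                rf, norm = sk.robinson_foulds(true, rec)
                assert rf == 0 and norm == 0.0

    def test_agrees_with_scikit_bio_on_additive_input(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        taxa = [f"t{i}" for i in range(8)]
        true = random_binary_tree(taxa, rng)
        dm = additive_distances(true)
        mine = sk.nj_tree(dm)
        theirs = skbio_nj(SkbioDM(dm.matrix, ids=dm.taxa))
        their_splits = set()
        n = len(taxa)
        for node in theirs.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 2 <= len(below) <= n - 2:
                side = below if "t0" not in below else frozenset(set(taxa) - below)
                their_splits.add(side)
        assert mine.bipartitions() == their_splits

    def test_branch_lengths_never_negative(self, rng):
        m = rng.random((8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        tree = sk.nj_tree(DistanceMatrix([f"t{i}" for i in range(8)], m))

        def walk(node):
            assert node.length >= 0
            for c in node.children:
                walk(c)

        for c in tree.root.children:
            walk(c)

    def test_non_symmetric_input_is_an_error(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], m)

    def test_fewer_than_three_taxa_is_an_error(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError, match="at least 3"):
            sk.nj_tree(d)


class TestRobinsonFoulds:
    def test_identical_trees(self, rng):
        t = random_binary_tree([f"t{i}" for i in range(5)], rng)
        assert sk.robinson_foulds(t, t) == (0, 0.0)

    def test_conflicting_quartets(self):
        t1 = sk.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = sk.read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert sk.robinson_foulds(t1, t2) == (2, 1.0)

    def test_caterpillar_nni_neighbor(self):
        t1 = sk.read_newick("(A:1,(B:1,(C:1,(D:1,(E:1,F:1):1):1):1):1);")
        t2 = sk.read_newick("(A:1,(C:1,(B:1,(D:1,(E:1,F:1):1):1):1):1);")
        rf, norm = sk.robinson_foulds(t1, t2)
        assert rf == 2
        assert norm == pytest.approx(2 / 6)

    def test_taxon_mismatch_lists_difference(self, rng):
        t1 = random_binary_tree(["a", "b", "c", "d"], rng)
        t2 = random_binary_tree(["a", "b", "c", "e"], rng)
        with pytest.raises(ValueError, match="only-in-first=\\['d'\\]"):
            sk.robinson_foulds(t1, t2)

    def test_matches_dendropy_on_random_pairs(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 9))
            taxa = [f"t{i}" for i in range(n)]
            t1 = random_binary_tree(taxa, rng)
            t2 = random_binary_tree(taxa, rng)
            rf, norm = sk.robinson_foulds(t1, t2)
            assert rf == dendropy_rf(t1, t2)
            assert 0.0 <= norm <= 1.0

    def test_is_a_metric_on_random_trees(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        trees = [random_binary_tree(taxa, rng) for _ in range(6)]
        for a in trees:
            for b in trees:
                rab = sk.robinson_foulds(a, b)[0]
                assert rab == sk.robinson_foulds(b, a)[0]
                for c in trees:
                    assert rab <= sk.robinson_foulds(a, c)[0] + \
                        sk.robinson_foulds(c, b)[0]


class TestBootstrap:
    def _two_clade_matrix(self, rng):
        n_sites = 300
        base_a = rng.choice([HOM_REF, HOM_ALT], size=n_sites, p=[0.8, 0.2])
        base_b = rng.choice([HOM_REF, HOM_ALT], size=n_sites, p=[0.2, 0.8])
        cols = []
        for base in (base_a, base_a, base_a, base_b, base_b, base_b):
            col = base.copy()
            flip = rng.choice(n_sites, size=8, replace=False)
            col[flip] = 2 - col[flip]
            cols.append(col)
        return matrix_from(np.column_stack(cols))

    def test_clade_separation_gets_high_support(self, rng):
        m = self._two_clade_matrix(rng)
        tree = sk.bootstrap_support(m, replicates=100, seed=1)
        split = frozenset({"s3", "s4", "s5"})
        supports = {
            frozenset(l.label for l in n.leaves())
            if "s0" not in {l.label for l in n.leaves()}
            else frozenset(tree.taxa() - {l.label for l in n.leaves()}): n.support
            for n in tree.internal_nodes()
        }
        assert supports[split] >= 95

    def test_single_replicate_supports_are_zero_or_hundred(self, rng):
        m = self._two_clade_matrix(rng)
        tree = sk.bootstrap_support(m, replicates=1, seed=2)
        sups = [n.support for n in tree.internal_nodes() if n.support is not None]
        assert sups and set(sups) <= {0.0, 100.0}

    def test_same_seed_same_supports(self, rng):
        m = self._two_clade_matrix(rng)
        t1 = sk.bootstrap_support(m, replicates=20, seed=3)
        t2 = sk.bootstrap_support(m, replicates=20, seed=3)
        assert sk.to_newick(t1) == sk.to_newick(t2)

    def test_zero_replicates_is_an_error(self, rng):
        with pytest.raises(ValueError, match="replicates"):
            sk.bootstrap_support(self._two_clade_matrix(rng), replicates=0)


class TestPca:
    def _two_group_matrix(self, rng, n_sites=200):
        base_a = rng.choice([HOM_REF, HOM_ALT], size=n_sites, p=[0.7, 0.3])
        base_b = rng.choice([HOM_REF, HOM_ALT], size=n_sites, p=[0.3, 0.7])
        cols = []
        for base in (base_a,) * 4 + (base_b,) * 4:
            col = base.copy()
            flip = rng.choice(n_sites, size=6, replace=False)
            col[flip] = 2 - col[flip]
            cols.append(col)
        return matrix_from(np.column_stack(cols))

    def test_pc1_separates_the_groups(self, rng):
        res = sk.pca(self._two_group_matrix(rng), k=2)
        pc1 = res.loadings[:, 0]
        assert len({np.sign(x) for x in pc1[:4]}) == 1
        assert len({np.sign(x) for x in pc1[4:]}) == 1
        assert np.sign(pc1[0]) != np.sign(pc1[4])

    def test_loadings_orthonormal(self, rng):
        res = sk.pca(self._two_group_matrix(rng), k=4)
        gram = res.loadings.T @ res.loadings
        assert np.allclose(gram, np.eye(res.loadings.shape[1]), atol=1e-9)

    def test_variance_fractions_sum_to_one(self, rng):
        m = self._two_group_matrix(rng)
        res = sk.pca(m, k=len(m.samples))
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.variance_fractions) <= 1e-12)

    def test_order_invariance_up_to_sign(self, rng):
        m = self._two_group_matrix(rng)
        res1 = sk.pca(m, k=2)
        perm = list(reversed(range(len(m.samples))))
        m2 = GenotypeMatrix(sites=m.sites,
                            samples=[m.samples[j] for j in perm],
                            calls=m.calls[:, perm])
        res2 = sk.pca(m2, k=2)
        for c in range(2):
            v1 = res1.loadings[perm, c]
            v2 = res2.loadings[:, c]
            assert np.allclose(np.abs(v1), np.abs(v2), atol=1e-9)

    def test_missing_values_are_mean_imputed(self, rng):
        m = self._two_group_matrix(rng)
        calls = m.calls.copy()
        mask = rng.random(calls.shape) < 0.05
        calls[mask] = MISSING
        res = sk.pca(matrix_from(calls), k=1)
        pc1 = res.loadings[:, 0]
        assert np.sign(pc1[0]) != np.sign(pc1[4])

    def test_k_exceeding_rank_truncates_with_warning(self):
        calls = np.array([[0, 2], [0, 2], [2, 0]], dtype=np.int8)
        with pytest.warns(UserWarning, match="rank"):
            res = sk.pca(matrix_from(calls), k=5)
        assert res.loadings.shape[1] <= 2


class TestAscertainmentContrast:
    def test_target_sites_inflate_crop_discrimination(self, demo_fixture,
                                                      demo_genotypes):
        """Panel (target) SNPs were ascertained in the crop, so crop-vs-crop
        distances relative to the wild spread are larger with target-only
        sites than with all sites."""
        fx = demo_fixture
        matrix, _, _ = demo_genotypes
        species_of = {a.accession_id: a.species for a in fx.germplasm.accessions}
        tmask = matrix.target_mask()
        target_only = matrix.subset_sites(np.flatnonzero(tmask))
        for label, m in (("target", target_only), ("all", matrix)):
            d = sk.genetic_distance(m)
            crop_idx = [i for i, s in enumerate(m.samples)
                        if species_of[s] == "crop"]
            wild_idx = [i for i, s in enumerate(m.samples)
                        if species_of[s] != "crop"]
            crop_d = np.mean([d.matrix[i, j] for i in crop_idx for j in crop_idx
                              if i < j])
            cross_d = np.mean([d.matrix[i, j] for i in crop_idx for j in wild_idx])
            if label == "target":
                ratio_target = crop_d / cross_d
            else:
                ratio_all = crop_d / cross_d
        assert ratio_target > ratio_all
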