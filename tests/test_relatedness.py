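import numpy as np
import pytest

import dendropy

from panelkit import (
    ValidationError,
    code_and_pca,
    nj_tree,
    normalized_distance,
    pairwise_diff,
)

from conftest import gm


def random_additive_tree(rng, n_leaves):
    """A random binary tree with positive branch lengths, its leaf labels
    and the implied additive (patristic) distance matrix."""
    labels = [f"t{i}" for i in range(n_leaves)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_leaves,
        taxon_namespace=taxa, rng=rng,
    )
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = rng.uniform(0.05, 1.0)
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n_leaves, n_leaves))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            d[i, j] = pdm.patristic_distance(ti, tj)
    return tree, labels, d


def rf_distance(newick, reference, taxa):
    mine = dendropy.Tree.get(
        data=newick, schema="newick", taxon_namespace=taxa
    )
    mine.is_rooted = False
    reference.is_rooted = False
    mine.update_bipartitions()
    reference.update_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(
        reference, mine
    )


class TestPairwiseDiff:
    def test_hand_count_with_missing(self):
        m = gm({"s1": ["AA", "AA", "AG"], "s2": ["AA", "GG", "--"]})
        diff = pairwise_diff(m)
        assert diff.n_diff[0, 1] == 1
        assert diff.n_comparable[0, 1] == 2

    def test_identical_samples(self):
        m = gm({"s1": ["AA", "AG"], "s2": ["AA", "AG"]})
        assert pairwise_diff(m).n_diff[0, 1] == 0

    def test_symmetry_and_diagonal(self, truth_matrix):
        diff = pairwise_diff(truth_matrix.subset_samples(
            truth_matrix.samples[:20]))
        assert (diff.n_diff == diff.n_diff.T).all()
        assert (np.diag(diff.n_diff) == 0).all()
        assert (diff.n_diff <= diff.n_comparable).all()

    def test_locus_permutation_invariance(self, truth_matrix):
        sub = truth_matrix.subset_samples(truth_matrix.samples[:10])
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(sub.loci))
        d1 = pairwise_diff(sub)
        d2 = pairwise_diff(sub.subset_loci(perm))
        assert (d1.n_diff == d2.n_diff).all()


class TestNormalizedDistance:
    def test_values(self):
        m = gm({"s1": ["AA", "AA", "AG"], "s2": ["AA", "GG", "--"]})
        d = normalized_distance(pairwise_diff(m))
        assert d[0, 1] == pytest.approx(0.5)
        m2 = gm({"s1": ["AA"], "s2": ["AA"]})
        assert normalized_distance(pairwise_diff(m2))[0, 1] == 0.0
        m3 = gm({"s1": ["AA", "CC"], "s2": ["GG", "TT"]})
        assert normalized_distance(pairwise_diff(m3))[0, 1] == 1.0

    def test_zero_comparable_pair_named(self):
        m = gm({"s1": ["AA", "--"], "s2": ["--", "GG"]})
        with pytest.raises(ValidationError, match="s1.*s2"):
            normalized_distance(pairwise_diff(m))


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> pairwise path lengths
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            dtype=float,
        )
        res = nj_tree(d, ["A", "B", "C", "D"])
        assert res.newick == "((A:1,B:2):1,C:3,D:4);"

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        res = nj_tree(d, ["A", "B", "C"])
        # three-point formulas: a=(3+4-5)/2=1, b=(3+5-4)/2=2, c=(4+5-3)/2=3
        assert res.newick == "(A:1,B:2,C:3);"

    def test_degenerate_equidistant_is_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        labels = ["A", "B", "C", "D"]
        assert nj_tree(d, labels).newick == nj_tree(d, labels).newick

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            nj_tree(np.zeros((2, 2)), ["A", "B"])
        bad = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], dtype=float)
        with pytest.raises(ValidationError):
            nj_tree(bad, ["A", "B", "C"])

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_topology_recovery(self, seed):
        """NJ inverts distances from a random additive tree exactly."""
        import random

        rng = random.Random(seed)
        n = rng.randint(5, 12)
        ref, labels, d = random_additive_tree(rng, n)
        res = nj_tree(d, labels)
        assert rf_distance(res.newick, ref, ref.taxon_namespace) == 0


class TestPca:
    def test_two_clusters_separate_on_pc1(self):
        rows = {}
        for i in range(5):
            rows[f"a{i}"] = ["AA", "AA", "GG"]
            rows[f"b{i}"] = ["GG", "GG", "AA"]
        res = code_and_pca(gm(rows), 2)
        a = [res.coordinates[res.sample_ids.index(f"a{i}"), 0]
             for i in range(5)]
        b = [res.coordinates[res.sample_ids.index(f"b{i}"), 0]
             for i in range(5)]
        assert max(a) < min(b) or max(b) < min(a)
        assert res.explained_variance[0] == pytest.approx(1.0)

    def test_identical_samples_zero_variance(self):
        rows = {f"s{i}": ["AA", "AG"] for i in range(4)}
        res = code_and_pca(gm(rows), 2)
        assert np.allclose(res.explained_variance, 0.0)
        assert np.allclose(res.coordinates, 0.0)

    def test_pairwise_distances_invariant_to_sample_order(self, truth_matrix):
        sub = truth_matrix.subset_samples(truth_matrix.samples[:30])
        rng = np.random.default_rng(1)
        perm = list(rng.permutation(sub.samples))
        r1 = code_and_pca(sub, 3)
        r2 = code_and_pca(sub.subset_samples(perm), 3)
        def pdist(res):
            ids = np.argsort(res.sample_ids)
            x = res.coordinates[ids]
            return np.linalg.norm(x[:, None] - x[None, :], axis=2)
        assert np.allclose(pdist(r1), pdist(r2), atol=1e-8)

    def test_fixture_subpopulations_recovered_by_kmeans(
        self, truth_matrix, fixture_meta
    ):
        """k-means on PC1-3 recovers the four simulated subpopulations."""
        from sklearn.cluster import KMeans
        from sklearn.metrics import confusion_matrix
        from scipy.optimize import linear_sum_assignment

        res = code_and_pca(truth_matrix, 3)
        labels = {m.sample_id: m.subpopulation for m in fixture_meta}
        y = [labels[s] for s in res.sample_ids]
        names = sorted(set(y))
        y_idx = np.array([names.index(v) for v in y])
        km = KMeans(n_clusters=4, n_init=10, random_state=0)
        pred = km.fit_predict(res.coordinates)
        cm = confusion_matrix(y_idx, pred)
        row, col = linear_sum_assignment(-cm)
        agreement = cm[row, col].sum() / len(y_idx)
        assert agreement >= 0.95
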