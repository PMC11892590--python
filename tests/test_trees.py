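"""Tree reading, phylogenetic covariance, and pathwise rates."""

import numpy as np
import pytest

import phyloprev as pp
from phyloprev.trees import TreeValidationError

from conftest import random_tree


class TestReadTrees:
    def test_two_tip_newick(self):
        post = pp.read_trees("(A:1,B:1);")
        assert len(post) == 1
        cov = pp.phylo_covariance(post[0], ["A", "B"])
        assert np.allclose(np.diag(cov.matrix), [1.0, 1.0])

    def test_three_tip_ultrametric_depths(self):
        post = pp.read_trees("((A:1,B:1):1,C:2);")
        cov = pp.phylo_covariance(post[0], ["A", "B", "C"])
        assert np.allclose(np.diag(cov.matrix), [2.0, 2.0, 2.0])

    def test_multi_tree_and_heterogeneous_tips_rejected(self):
        post = pp.read_trees("(A:1,B:1);\n(A:2,B:3);\n")
        assert len(post) == 2
        with pytest.raises(TreeValidationError, match="tree 1"):
            pp.read_trees("(A:1,B:1);\n(A:2,C:3);\n")

    def test_malformed_raises(self):
        with pytest.raises(Exception):
            pp.read_trees("((A:1,B:1;")

    def test_nexus_round_trip(self):
        tree = random_tree(8, seed=3)
        text = pp.write_trees(pp.TreePosterior([tree]), format="nexus")
        back = pp.read_trees(text, format="nexus")
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        c0 = pp.phylo_covariance(tree, taxa).matrix
        c1 = pp.phylo_covariance(back[0], taxa).matrix
        assert np.allclose(c0, c1, rtol=1e-12, atol=0)

    def test_newick_round_trip_preserves_lengths(self):
        """Write-then-read on a random 20-tip tree preserves topology and
        branch lengths to <= 1e-12 relative error (node-by-node via the
        induced covariance, which determines both)."""
        tree = random_tree(20, seed=11)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        text = pp.write_trees(pp.TreePosterior([tree]))
        back = pp.read_trees(text)[0]
        c0 = pp.phylo_covariance(tree, taxa).matrix
        c1 = pp.phylo_covariance(back, taxa).matrix
        assert np.allclose(c0, c1, rtol=1e-12, atol=0)


def _edge_set_covariance(tree, taxa):
    """Brute-force oracle: intersect explicit root-to-tip edge sets and sum
    shared edge lengths."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append(node.edge)
            node = node.parent_node
        paths[leaf.taxon.label] = edges
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = set(id(e) for e in paths[taxa[i]]) & set(
                id(e) for e in paths[taxa[j]])
            m[i, j] = sum(e.length or 0.0 for e in paths[taxa[i]]
                          if id(e) in shared)
    return m


class TestPhyloCovariance:
    def test_star_tree_identity_like(self):
        cov = pp.phylo_covariance(pp.read_trees("(A:1,B:1,C:1);")[0],
                                  ["A", "B", "C"])
        assert np.allclose(cov.matrix, np.eye(3))

    def test_nested_tree_values(self):
        cov = pp.phylo_covariance(pp.read_trees("((A:1,B:1):1,C:2);")[0],
                                  ["A", "B", "C"])
        expect = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        assert np.allclose(cov.matrix, expect)

    def test_missing_species_named_in_error(self):
        tree = pp.read_trees("(A:1,B:1);")[0]
        with pytest.raises(TreeValidationError, match="ZZ"):
            pp.phylo_covariance(tree, ["A", "ZZ"])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_edge_set_oracle(self, seed):
        tree = random_tree(10, seed=seed)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        cov = pp.phylo_covariance(tree, taxa)
        assert np.allclose(cov.matrix, _edge_set_covariance(tree, taxa),
                           atol=1e-10)

    def test_cholesky_with_tiny_jitter(self):
        tree = random_tree(15, seed=5)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        L = pp.phylo_covariance(tree, taxa).cholesky(jitter_rel=1e-10)
        assert np.all(np.isfinite(L))

    def test_rescaling_branches_scales_covariance(self):
        tree = random_tree(8, seed=9)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        c0 = pp.phylo_covariance(tree, taxa).matrix
        scaled = tree.clone(depth=1)
        for e in scaled.preorder_edge_iter():
            if e.length is not None:
                e.length *= 3.5
        c1 = pp.phylo_covariance(scaled, taxa).matrix
        assert np.allclose(c1, 3.5 * c0, rtol=1e-12)


class TestPathwiseRates:
    def test_ultrametric_equals_height(self):
        tree = random_tree(12, seed=2)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        pw = pp.pathwise_rates(pp.TreePosterior([tree]), taxa)
        assert np.allclose(pw.summary.values, pw.summary.values[0], atol=1e-9)

    def test_single_tree_hand_sums(self):
        pw = pp.pathwise_rates(pp.read_trees("((A:2,B:1):1,C:2);"),
                               ["A", "B", "C"])
        assert np.allclose(pw.summary.values, [3.0, 2.0, 2.0])

    def test_even_count_median_is_midpoint(self):
        trees = pp.read_trees("(A:1,B:1);\n(A:2,B:1);\n(A:4,B:1);\n(A:10,B:1);\n")
        pw = pp.pathwise_rates(trees, ["A"])
        assert pw.summary["A"] == 3.0

    def test_matches_hand_summation_on_random_tree(self):
        tree = random_tree(10, seed=4)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        pw = pp.pathwise_rates(pp.TreePosterior([tree]), taxa)
        for leaf in tree.leaf_node_iter():
            total, node = 0.0, leaf
            while node.parent_node is not None:
                total += node.edge.length or 0.0
                node = node.parent_node
            assert pw.summary[leaf.taxon.label] == pytest.approx(total, abs=1e-12)

    def test_pathwise_equals_covariance_diagonal(self):
        tree = random_tree(9, seed=8)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        pw = pp.pathwise_rates(pp.TreePosterior([tree]), taxa)
        cov = pp.phylo_covariance(tree, taxa)
        assert np.allclose(pw.summary.values, np.diag(cov.matrix), rtol=1e-12)

    def test_csv_export_columns(self, tmp_path):
        tree = random_tree(5, seed=1)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        pw = pp.pathwise_rates(pp.TreePosterior([tree]), taxa)
        out = tmp_path / "pw.csv"
        pw.to_csv(out)
        import pandas as pd
        df = pd.read_csv(out)
        assert list(df.columns) == ["species", "median_pathwise_rate", "n_trees"]
        assert len(df) == 5
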