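import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from aflpkit import (
    BinaryProfileMatrix,
    BootstrapConfig,
    TreeNode,
    ValidationError,
    bootstrap_support,
    count_significant_clusters,
    upgma,
)
from conftest import two_block_matrix


def naive_upgma_heights(d, labels):
    """Brute-force O(n^3) UPGMA: returns {frozenset(leaves): height}."""
    clusters = {frozenset([l]): [i] for i, l in enumerate(labels)}
    heights = {}
    while len(clusters) > 1:
        best = None
        for ca in clusters:
            for cb in clusters:
                if min(ca) >= min(cb):
                    continue
                rows, cols = clusters[ca], clusters[cb]
                avg = np.mean([d[i, j] for i in rows for j in cols])
                key = (avg, tuple(sorted((min(ca), min(cb)))))
                if best is None or key < best[0]:
                    best = (key, ca, cb)
        (avg, _), ca, cb = best
        merged = ca | cb
        heights[merged] = avg / 2
        clusters[merged] = clusters.pop(ca) + clusters.pop(cb)
    return heights


def tree_heights(tree):
    return {clade: h for clade, h in tree.clade_heights().items()}


class TestUpgma:
    def test_hand_computed_merge_heights(self):
        ids = list("ABCD")
        d = np.array(
            [
                [0.0, 0.1, 0.4, 0.6],
                [0.1, 0.0, 0.4, 0.6],
                [0.4, 0.4, 0.0, 0.6],
                [0.6, 0.6, 0.6, 0.0],
            ]
        )
        tree = upgma(DistanceMatrix(d, ids=ids))
        h = tree_heights(tree)
        assert h[frozenset("AB")] == pytest.approx(0.05)
        assert h[frozenset("ABC")] == pytest.approx(0.20)
        assert h[frozenset("ABCD")] == pytest.approx(0.30)

    def test_all_zero_matrix_degenerate_and_deterministic(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("ABCD"))
        t1, t2 = upgma(dm), upgma(dm)
        assert all(n.height == 0 for n in t1.walk() if not n.is_leaf)
        assert t1.clades(trivial=True) == t2.clades(trivial=True)
        # lexicographic tie-break merges A with B first
        assert frozenset("AB") in t1.clades()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"T{i}" for i in range(n)]
        got = tree_heights(upgma(DistanceMatrix(d, ids=ids)))
        expect = naive_upgma_heights(d, ids)
        assert set(got) == set(expect)
        for clade in expect:
            assert got[clade] == pytest.approx(expect[clade], abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_average_linkage_heights(self, seed):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(100 + seed)
        n = 7
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = upgma(DistanceMatrix(d, ids=[f"T{i}" for i in range(n)]))
        ours = sorted(h for h in tree_heights(tree).values())
        scipy_heights = sorted(average(squareform(d))[:, 2] / 2)
        np.testing.assert_allclose(ours, scipy_heights, atol=1e-9)

    def test_output_is_ultrametric(self):
        rng = np.random.default_rng(42)
        d = rng.random((9, 9))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = upgma(DistanceMatrix(d, ids=[f"T{i}" for i in range(9)]))

        def leaf_depths(node, acc=0.0):
            if node.is_leaf:
                return [acc]
            out = []
            for c in node.children:
                out.extend(leaf_depths(c, acc + node.height - c.height))
            return out

        depths = leaf_depths(tree)
        assert max(depths) - min(depths) < 1e-9

    def test_nan_distance_rejected(self):
        dm = DistanceMatrix(np.zeros((3, 3)), ids=list("ABC"))
        dm.data[0, 1] = dm.data[1, 0] = np.nan
        with pytest.raises(ValidationError, match="NaN"):
            upgma(dm)


class TestBootstrap:
    def test_two_blocks_get_full_support(self):
        matrix = two_block_matrix(n_per_block=4, n_loci=15)
        tree, consensus = bootstrap_support(
            matrix, BootstrapConfig(n_replicates=100, seed=3)
        )
        block_a = frozenset(f"A{i}" for i in range(4))
        block_b = frozenset(f"B{i}" for i in range(4))
        supports = {
            frozenset(n.leaf_names()): n.support
            for n in tree.internal_nodes(include_root=False)
        }
        # the root splits into the two blocks; at least one is a non-root clade
        assert any(supports.get(b) == 100.0 for b in (block_a, block_b))
        assert all(
            c in (block_a, block_b) or c < block_a or c < block_b
            for c in consensus.clades()
        )

    def test_single_replicate_supports_binary(self, small_matrix):
        tree, _ = bootstrap_support(small_matrix, BootstrapConfig(n_replicates=1, seed=0))
        for n in tree.internal_nodes(include_root=False):
            assert n.support in (0.0, 100.0)

    def test_seeded_determinism(self, small_matrix):
        cfg = BootstrapConfig(n_replicates=50, seed=9)
        t1, c1 = bootstrap_support(small_matrix, cfg)
        t2, c2 = bootstrap_support(small_matrix, cfg)
        s1 = [n.support for n in t1.internal_nodes(include_root=False)]
        s2 = [n.support for n in t2.internal_nodes(include_root=False)]
        assert s1 == s2
        from aflpkit.io import tree_to_newick

        assert tree_to_newick(c1) == tree_to_newick(c2)

    def test_supports_invariant_under_relabeling(self):
        matrix = two_block_matrix(n_per_block=3, n_loci=12)
        relabeled = BinaryProfileMatrix(
            matrix.calls.rename(index=lambda s: "X" + s)
        )
        cfg = BootstrapConfig(n_replicates=60, seed=4)
        t1, _ = bootstrap_support(matrix, cfg)
        t2, _ = bootstrap_support(relabeled, cfg)
        s1 = sorted(
            (len(n.leaf_names()), n.support)
            for n in t1.internal_nodes(include_root=False)
        )
        s2 = sorted(
            (len(n.leaf_names()), n.support)
            for n in t2.internal_nodes(include_root=False)
        )
        assert s1 == s2

    def test_consensus_clades_majority_and_frequency_consistent(self, small_matrix):
        cfg = BootstrapConfig(n_replicates=80, seed=12)
        tree, consensus = bootstrap_support(small_matrix, cfg)
        full_supports = {
            frozenset(n.leaf_names()): n.support
            for n in tree.internal_nodes(include_root=False)
        }
        for node in consensus.internal_nodes(include_root=False):
            assert node.support > 50
            clade = frozenset(node.leaf_names())
            if clade in full_supports:
                assert node.support == pytest.approx(full_supports[clade])

    def test_too_few_loci_rejected(self):
        calls = pd.DataFrame([[1], [0], [1]], index=list("ABC"), columns=["L1"])
        with pytest.raises(ValidationError, match="2 loci"):
            bootstrap_support(BinaryProfileMatrix(calls))


class TestCountSignificant:
    def make_tree(self, supports):
        leaves = [TreeNode(name=f"T{i}") for i in range(4)]
        n1 = TreeNode(height=0.1, support=supports[0], children=leaves[:2])
        n2 = TreeNode(height=0.2, support=supports[1], children=[n1, leaves[2]])
        root = TreeNode(height=0.4, support=supports[2], children=[n2, leaves[3]])
        return root

    def test_direct_count(self):
        assert count_significant_clusters(self.make_tree([97, 96, 40]), 95) == 2

    def test_threshold_above_100(self):
        assert count_significant_clusters(self.make_tree([97, 96, 40]), 101) == 0

    def test_root_excluded(self):
        assert count_significant_clusters(self.make_tree([40, 40, 100]), 95) == 0

    def test_tree_without_supports_rejected(self):
        tree = self.make_tree([None, None, None])
        with pytest.raises(ValidationError, match="support"):
            count_significant_clusters(tree, 95)

    def test_identical_profile_block_counts_once(self):
        # three identical isolates: their internal resolution is a tie-break
        # artifact and must not inflate the cluster count
        a = TreeNode(name="A")
        b = TreeNode(name="B")
        c = TreeNode(name="C")
        d = TreeNode(name="D")
        ab = TreeNode(height=0.0, support=100, children=[a, b])
        abc = TreeNode(height=0.0, support=100, children=[ab, c])
        root = TreeNode(height=0.3, children=[abc, d])
        assert count_significant_clusters(root, 95) == 1
        assert count_significant_clusters(root, 95, collapse_identical=False) == 2

    def test_bootstrap_config_validation(self):
        with pytest.raises(ValidationError):
            BootstrapConfig(n_replicates=0)
        with pytest.raises(ValidationError):
            BootstrapConfig(support_threshold=50)
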