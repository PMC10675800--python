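"""Ward linkage, tree cutting and the two-way clustering of the signal grid."""

from __future__ import annotations

import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from faersig.cluster import (cut_tree, to_newick, two_way_cluster, ward_linkage,
                             write_clusters_tsv, write_linkage_tsv)
from faersig.signal_matrix import SignalMatrix
from oracles import replay_ward_and_check


def two_block_matrix(rng, n1=4, n2=5, dim=6, sep=50.0):
    X = np.vstack([rng.normal(0, 1, size=(n1, dim)),
                   rng.normal(sep, 1, size=(n2, dim))])
    truth = np.array([0] * n1 + [1] * n2)
    return X, truth


class TestWardLinkage:
    def test_two_rows_merge_at_their_euclidean_distance(self):
        tree = ward_linkage(np.array([[0.0, 0.0], [0.0, 3.0]]))
        assert tree.merges == ((0, 1, 3.0, 2),)

    def test_three_one_dimensional_points(self):
        tree = ward_linkage(np.array([[0.0], [1.0], [10.0]]))
        (m1, m2) = tree.merges
        assert m1[:2] == (0, 1) and m1[2] == pytest.approx(1.0)
        # Lance-Williams: d2({0,1},{2}) = (2*100 + 2*81 - 1)/3 = 361/3
        assert m2[2] == pytest.approx(math.sqrt(361 / 3))
        replay_ward_and_check(tree, np.array([[0.0], [1.0], [10.0]]))

    def test_planted_blocks_join_last(self):
        rng = np.random.default_rng(11)
        X, truth = two_block_matrix(rng)
        tree = ward_linkage(X)
        left, right, _, size = tree.merges[-1]
        assert size == len(X)
        labels = cut_tree(tree, 2).label_vector([str(i) for i in range(len(X))])
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_stepwise_ward_objective_is_minimal(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = rng.integers(3, 8)
            X = rng.normal(size=(n, rng.integers(1, 5)))
            replay_ward_and_check(ward_linkage(X), X)

    def test_matches_scipy_ward_heights(self):
        from scipy.cluster.hierarchy import linkage
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 4))
        tree = ward_linkage(X)
        Z = linkage(X, method="ward")
        assert np.allclose(sorted(tree.heights), sorted(Z[:, 2]), atol=1e-8)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            X = rng.normal(size=(rng.integers(2, 15), 3))
            h = ward_linkage(X).heights
            assert np.all(np.diff(h) >= -1e-10)

    def test_squared_height_convention(self):
        X = np.array([[0.0], [3.0]])
        tree = ward_linkage(X, height_convention="squared")
        assert tree.merges[0][2] == pytest.approx(9.0)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 2"):
            ward_linkage(np.zeros((1, 3)))
        with pytest.raises(ValueError, match="row 1"):
            ward_linkage(np.array([[0.0], [np.nan]]))

    def test_permutation_invariance_of_partitions(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(10, 5))
        labels = [str(i) for i in range(10)]
        perm = rng.permutation(10)
        t1 = ward_linkage(X, labels=labels)
        t2 = ward_linkage(X[perm], labels=[labels[i] for i in perm])
        for k in range(1, 11):
            c1 = cut_tree(t1, k)
            c2 = cut_tree(t2, k)
            v1 = [c1.labels[s] for s in labels]
            v2 = [c2.labels[s] for s in labels]
            assert adjusted_rand_score(v1, v2) == 1.0


@pytest.fixture(scope="module")
def tree():
    rng = np.random.default_rng(8)
    return ward_linkage(rng.normal(size=(7, 3)))


class TestCutTree:

    def test_k_extremes(self, tree):
        singles = cut_tree(tree, 7)
        assert len(set(singles.labels.values())) == 7
        one = cut_tree(tree, 1)
        assert set(one.labels.values()) == {1}

    def test_every_k_yields_k_nonempty_clusters(self, tree):
        for k in range(1, 8):
            cut = cut_tree(tree, k)
            assert len(set(cut.labels.values())) == k
            assert sorted(set(cut.labels.values())) == list(range(1, k + 1))

    def test_k_out_of_range(self, tree):
        with pytest.raises(ValueError):
            cut_tree(tree, 0)
        with pytest.raises(ValueError):
            cut_tree(tree, 8)

    def test_leaf_order_is_a_permutation_of_leaves(self, tree):
        cut = cut_tree(tree, 3)
        assert sorted(cut.leaf_order) == sorted(tree.leaf_labels)


class TestTwoWay:
    def make_signal_matrix(self, X, drugs=None, events=None):
        drugs = drugs or [f"d{i}" for i in range(X.shape[0])]
        events = events or [f"e{j}" for j in range(X.shape[1])]
        return SignalMatrix(drugs=tuple(drugs), events=tuple(events), lnror=X,
                            event_totals=np.full(X.shape[1], 1000))

    def test_recovers_planted_blocks_on_both_axes(self):
        rng = np.random.default_rng(13)
        row_truth = np.array([0, 0, 0, 1, 1, 1])
        col_truth = np.array([0] * 5 + [1] * 5)
        base = np.where((row_truth[:, None] == 0) & (col_truth[None, :] == 0), 3.0, 0.0)
        base += np.where((row_truth[:, None] == 1) & (col_truth[None, :] == 1), 3.0, 0.0)
        X = base + rng.normal(0, 0.1, size=base.shape)
        m = self.make_signal_matrix(X)
        res = two_way_cluster(m, k_drugs=2, k_events=2)
        drug_labels = res.drug_clusters.label_vector(m.drugs)
        event_labels = res.event_clusters.label_vector(m.events)
        assert adjusted_rand_score(row_truth, drug_labels) == 1.0
        assert adjusted_rand_score(col_truth, event_labels) == 1.0

    def test_transpose_swaps_axes(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(5, 8))
        m = self.make_signal_matrix(X)
        mt = SignalMatrix(drugs=m.events, events=m.drugs, lnror=X.T,
                          event_totals=np.full(5, 10))
        res = two_way_cluster(m, k_drugs=2, k_events=3)
        rest = two_way_cluster(mt, k_drugs=3, k_events=2)
        assert res.drug_clusters.labels == rest.event_clusters.labels
        assert res.event_clusters.labels == rest.drug_clusters.labels

    def test_reordering_is_a_pure_permutation(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(6, 9))
        m = self.make_signal_matrix(X)
        res = two_way_cluster(m, k_drugs=2, k_events=3)
        assert sorted(res.reordered.to_numpy().ravel()) == pytest.approx(
            sorted(X.ravel()))
        assert sorted(res.reordered.index) == sorted(m.drugs)

    def test_needs_two_rows_and_columns(self):
        m = self.make_signal_matrix(np.zeros((1, 4)))
        with pytest.raises(ValueError):
            two_way_cluster(m, k_drugs=1, k_events=2)


class TestExports:
    def test_newick_round_trips_through_biopython(self, tmp_path):
        from io import StringIO
        from Bio import Phylo
        rng = np.random.default_rng(17)
        tree = ward_linkage(rng.normal(size=(6, 3)),
                            labels=["drug A", "b", "c", "d", "e", "f"])
        nwk = to_newick(tree)
        parsed = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == sorted(
            ["drug A", "b", "c", "d", "e", "f"])
        # root-to-leaf path length equals the root height for every leaf
        root_height = tree.merges[-1][2]
        depths = parsed.depths()
        for leaf in parsed.get_terminals():
            assert depths[leaf] == pytest.approx(root_height, rel=1e-6)

    def test_linkage_and_cluster_tsv(self, tmp_path):
        rng = np.random.default_rng(18)
        tree = ward_linkage(rng.normal(size=(5, 2)))
        write_linkage_tsv(tree, tmp_path / "link.tsv")
        lines = (tmp_path / "link.tsv").read_text().splitlines()
        assert lines[0] == "left\tright\theight\tsize"
        assert len(lines) == 1 + 4
        cut = cut_tree(tree, 2)
        write_clusters_tsv(cut, tmp_path / "cl.tsv")
        rows = (tmp_path / "cl.tsv").read_text().splitlines()[1:]
        assert len(rows) == 5
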