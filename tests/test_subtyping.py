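import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage

from ecvnet.ecv import ECvMatrix
from ecvnet.subtyping import (
    adjusted_rand_index,
    cluster_patients,
    compare_assignments,
    linkage_to_newick,
    rank_edges_by_variance,
    rank_genes_by_variance,
    select_top_edges,
    silhouette_scan,
)


def _matrix(values, prefix="e"):
    n, e = np.asarray(values).shape
    return ECvMatrix(
        [f"s{i:02d}" for i in range(n)], [f"{prefix}{j:02d}" for j in range(e)],
        np.asarray(values, dtype=float),
    )


class TestVarianceRanking:
    def test_matches_direct_formula(self):
        values = np.array([[0.0, 1.0, 5.0], [2.0, 1.0, 5.0], [4.0, 3.0, 5.0]])
        sel = rank_edges_by_variance(_matrix(values))
        expected = values.var(axis=0, ddof=1)  # 4.0, 4/3, 0.0
        assert sel.edge_ids == ["e00", "e01", "e02"]
        np.testing.assert_allclose(sel.variances, sorted(expected, reverse=True))

    def test_constant_column_ranked_last(self, rng):
        values = rng.normal(size=(10, 3))
        values[:, 1] = 7.0
        sel = rank_edges_by_variance(_matrix(values))
        assert sel.edge_ids[-1] == "e01"
        assert sel.variances[-1] == 0.0

    def test_row_duplication_preserves_ranking(self, rng):
        values = rng.normal(size=(8, 5))
        doubled = np.vstack([values, values])
        m1 = _matrix(values)
        m2 = ECvMatrix([f"t{i}" for i in range(16)], m1.edge_ids, doubled)
        assert rank_edges_by_variance(m1).edge_ids == rank_edges_by_variance(m2).edge_ids

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            rank_edges_by_variance(_matrix([[1.0, 2.0]]))

    def test_tie_break_ascending_edge_id(self):
        values = np.array([[0.0, 0.0], [1.0, 1.0]])
        sel = rank_edges_by_variance(_matrix(values))
        assert sel.edge_ids == ["e00", "e01"]


class TestSelectTopEdges:
    def test_n_larger_than_e_returns_all(self, rng):
        m = _matrix(rng.normal(size=(6, 4)))
        sel = rank_edges_by_variance(m)
        assert select_top_edges(sel, m, n=250).n_edges == 4

    def test_n_one_returns_highest_variance_column(self, rng):
        values = rng.normal(size=(20, 5))
        values[:, 3] *= 10
        m = _matrix(values)
        red = select_top_edges(rank_edges_by_variance(m), m, n=1)
        assert red.edge_ids == ["e03"]

    def test_invalid_n_rejected(self, rng):
        m = _matrix(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            select_top_edges(rank_edges_by_variance(m), m, n=0)

    def test_columns_in_rank_order(self, rng):
        m = _matrix(rng.normal(size=(15, 8)))
        sel = rank_edges_by_variance(m)
        red = select_top_edges(sel, m, n=5)
        assert red.edge_ids == sel.edge_ids[:5]


class TestClusterPatients:
    def test_two_separated_blobs(self, rng):
        blob1 = rng.normal(0, 0.2, size=(20, 5))
        blob2 = rng.normal(8, 0.2, size=(20, 5))
        m = _matrix(np.vstack([blob1, blob2]))
        assign = cluster_patients(m, k=2)
        truth = {s: ("a" if i < 20 else "b") for i, s in enumerate(m.sample_ids)}
        assert adjusted_rand_index(assign.labels, truth) == 1.0

    def test_k1_gives_single_label(self, rng):
        m = _matrix(rng.normal(size=(6, 3)))
        assign = cluster_patients(m, k=1)
        assert set(assign.labels.values()) == {1}

    def test_k_above_n_rejected(self, rng):
        m = _matrix(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError, match="k must be"):
            cluster_patients(m, k=5)

    def test_single_linkage_merge_order_matches_naive_agglomeration(self):
        # 5 points in 1-D: closest-pair merges, min-distance between clusters
        points = np.array([0.0, 1.0, 3.0, 7.0, 20.0])[:, None]
        m = _matrix(points)
        tree = cluster_patients(m, k=1, linkage_method="single").merge_tree

        # naive O(n^3) single-linkage agglomeration oracle
        clusters = {i: {i} for i in range(5)}
        next_id = 5
        merges = []
        while len(clusters) > 1:
            best = None
            for a, b in itertools.combinations(sorted(clusters), 2):
                d = min(abs(points[i, 0] - points[j, 0])
                        for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
            d, a, b = best
            merges.append((d, clusters[a] | clusters[b]))
            clusters[next_id] = clusters.pop(a) | clusters.pop(b)
            next_id += 1
        for (height, members), row in zip(merges, tree):
            assert row[2] == pytest.approx(height)
            assert int(row[3]) == len(members)

    def test_labels_deterministic_and_size_ordered(self, rng):
        values = np.vstack([
            rng.normal(0, 0.1, size=(10, 3)),
            rng.normal(5, 0.1, size=(25, 3)),
            rng.normal(-5, 0.1, size=(15, 3)),
        ])
        m = _matrix(values)
        assign = cluster_patients(m, k=3)
        sizes = {lab: sum(1 for v in assign.labels.values() if v == lab) for lab in (1, 2, 3)}
        assert sizes[1] >= sizes[2] >= sizes[3]

    def test_invariance_to_column_order(self, rng):
        values = rng.normal(size=(20, 6))
        m1 = _matrix(values)
        perm = rng.permutation(6)
        m2 = ECvMatrix(m1.sample_ids, [m1.edge_ids[j] for j in perm], values[:, perm])
        a1 = cluster_patients(m1, k=3)
        a2 = cluster_patients(m2, k=3)
        assert a1.labels == a2.labels

    def test_invariance_to_row_order_up_to_relabelling(self, rng):
        values = np.vstack([
            rng.normal(0, 0.3, size=(12, 4)),
            rng.normal(4, 0.3, size=(12, 4)),
        ])
        m1 = _matrix(values)
        perm = rng.permutation(24)
        m2 = ECvMatrix([m1.sample_ids[i] for i in perm], m1.edge_ids, values[perm])
        a1 = cluster_patients(m1, k=2)
        a2 = cluster_patients(m2, k=2)
        assert adjusted_rand_index(a1.labels, a2.labels) == 1.0

    def test_scale_columns_flag(self, rng):
        values = rng.normal(size=(10, 3))
        values[:, 0] *= 100
        assign = cluster_patients(_matrix(values), k=2, scale_columns=True)
        assert assign.scaled_columns


class TestAdjustedRandIndex:
    def test_identical_assignments(self):
        labels = {f"s{i}": i % 3 for i in range(30)}
        assert adjusted_rand_index(labels, labels) == 1.0

    def test_all_in_one_cluster_vs_any(self, rng):
        a = {f"s{i}": 1 for i in range(30)}
        b = {f"s{i}": int(rng.integers(0, 3)) for i in range(30)}
        assert adjusted_rand_index(a, b) == 0.0

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(10):
            a = {f"s{i}": int(rng.integers(0, 3)) for i in range(30)}
            b = {f"s{i}": int(rng.integers(0, 3)) for i in range(30)}
            samples = sorted(a)
            n11 = n00 = n10 = n01 = 0
            for s, t in itertools.combinations(samples, 2):
                same_a, same_b = a[s] == a[t], b[s] == b[t]
                n11 += same_a and same_b
                n00 += (not same_a) and (not same_b)
                n10 += same_a and not same_b
                n01 += (not same_a) and same_b
            total = n11 + n00 + n10 + n01
            expected_index = ((n11 + n10) * (n11 + n01)) / total
            max_index = 0.5 * ((n11 + n10) + (n11 + n01))
            oracle = (n11 - expected_index) / (max_index - expected_index)
            assert adjusted_rand_index(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import adjusted_rand_score

        a = {f"s{i}": int(rng.integers(0, 4)) for i in range(50)}
        b = {f"s{i}": int(rng.integers(0, 4)) for i in range(50)}
        order = sorted(a)
        expected = adjusted_rand_score([a[s] for s in order], [b[s] for s in order])
        assert adjusted_rand_index(a, b) == pytest.approx(expected, abs=1e-12)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="share no samples"):
            adjusted_rand_index({"a": 1}, {"b": 1})


class TestCompareAssignments:
    def test_contingency_table_counts(self):
        a = {"s1": 1, "s2": 1, "s3": 2}
        b = {"s1": "x", "s2": "y", "s3": "y"}
        table, ari = compare_assignments(a, b)
        assert table.loc[1, "x"] == 1
        assert table.loc[1, "y"] == 1
        assert table.loc[2, "y"] == 1

    def test_restricted_to_intersection(self):
        a = {"s1": 1, "s2": 2, "zz": 3}
        b = {"s1": 1, "s2": 2, "qq": 9}
        table, ari = compare_assignments(a, b)
        assert table.to_numpy().sum() == 2
        assert ari == 1.0


class TestExpressionBaseline:
    def test_rank_genes_by_variance(self, rng):
        values = rng.normal(size=(4, 30))
        values[2] *= 5
        ranked = rank_genes_by_variance(values, ["a", "b", "c", "d"])
        assert ranked[0] == "c"


class TestNewickExport:
    def test_newick_parses_and_keeps_leaves(self, rng):
        values = rng.normal(size=(6, 3))
        tree = linkage(values, method="average")
        newick = linkage_to_newick(tree, [f"s{i}" for i in range(6)])
        import dendropy

        parsed = dendropy.Tree.get(data=newick, schema="newick")
        taxa = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert taxa == {f"s{i}" for i in range(6)}


class TestSilhouetteScan:
    def test_prefers_true_k(self, rng):
        values = np.vstack([
            rng.normal(0, 0.2, size=(15, 4)),
            rng.normal(5, 0.2, size=(15, 4)),
            rng.normal(-5, 0.2, size=(15, 4)),
        ])
        df = silhouette_scan(_matrix(values), ks=(2, 3, 4, 5))
        best_k = int(df.loc[df["mean_silhouette"].idxmax(), "k"])
        assert best_k == 3
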