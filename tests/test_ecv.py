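import numpy as np
import pytest

from ecvnet.bspline import predict
from ecvnet.core_io import ExpressionMatrix, NetworkStructure
from ecvnet.ecv import (
    DeltaECvTable,
    ECvMatrix,
    GroupAssignment,
    compute_ecv,
    delta_ecv,
    extract_subtype_specific_edges,
    induced_subnetwork,
    largest_weak_component,
    out_degrees,
)
from ecvnet.network import SearchConfig, estimate_network, score_network
from ecvnet.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="module")
def fitted_cohort():
    cfg = GeneratorConfig(seed=42)
    X, truth = generate_cohort(cfg)
    net = estimate_network(X, search_config=SearchConfig(restarts=2, seed=42))
    return X, truth, net


class TestComputeEcv:
    def test_identity_like_smooth_returns_parent_value(self, rng):
        # y = x on symmetric data: the centered smooth is ~identity
        x = np.sort(rng.uniform(-4, 4, 500))
        y = x.copy()
        X = ExpressionMatrix(["P", "C"], [f"s{i}" for i in range(500)], np.vstack([x, y]))
        net = score_network(X, NetworkStructure(["P", "C"], [("P", "C")]))
        ecv = compute_ecv(net, X)
        i = int(np.argmin(np.abs(x - 2.5)))
        assert ecv.values[i, 0] == pytest.approx(x[i] - x.mean(), abs=0.05)

    def test_intercept_only_child_contributes_no_columns(self, rng):
        X = ExpressionMatrix(
            ["A", "B"], [f"s{i}" for i in range(100)], rng.normal(size=(2, 100))
        )
        net = score_network(X, NetworkStructure(["A", "B"], []))
        ecv = compute_ecv(net, X)
        assert ecv.n_edges == 0
        assert ecv.values.shape == (100, 0)

    def test_missing_gene_named_in_error(self, fitted_cohort):
        X, truth, net = fitted_cohort
        parent = net.structure.edges[0][0]
        keep = [g for g in X.gene_ids if g != parent]
        idx = [X.gene_ids.index(g) for g in keep]
        partial = ExpressionMatrix(keep, X.sample_ids, X.values[idx])
        with pytest.raises(ValueError, match=parent):
            compute_ecv(net, partial)

    def test_reconstruction_identity(self, fitted_cohort):
        # intercept + row-sum of incoming ECvs == predict() for every sample
        X, truth, net = fitted_cohort
        ecv = compute_ecv(net, X)
        frame = ecv.to_frame()
        for child in net.structure.nodes:
            model = net.models[child]
            if not model.parents:
                continue
            cols = [f"{p}->{child}" for p in model.parents]
            total = model.mu + frame[cols].sum(axis=1).to_numpy()
            for i in range(0, X.n_samples, 17):
                values = [X.gene(p)[i] for p in model.parents]
                assert total[i] == pytest.approx(predict(model, values), abs=1e-9)

    def test_training_mean_of_every_column_is_zero(self, fitted_cohort):
        X, truth, net = fitted_cohort
        ecv = compute_ecv(net, X)
        assert np.abs(ecv.values.mean(axis=0)).max() < 1e-7

    def test_out_of_range_samples_clamped(self, fitted_cohort):
        X, truth, net = fitted_cohort
        extreme = ExpressionMatrix(X.gene_ids, ["far"], np.full((X.n_genes, 1), 100.0))
        ecv = compute_ecv(net, extreme)
        assert np.all(np.isfinite(ecv.values))


class TestDeltaEcv:
    def test_two_groups_reduce_to_mean_difference(self):
        ecv = ECvMatrix(["a", "b", "c", "d"], ["e1"], np.array([[1.0], [1.0], [3.0], [3.0]]))
        groups = GroupAssignment({"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        table = delta_ecv(ecv, groups)
        assert table.value("g1", "e1") == pytest.approx(2.0)
        assert table.value("g2", "e1") == pytest.approx(2.0)

    def test_three_group_worked_example(self):
        # R1={1,3}, R2={2,4}, R3={5,7}: group-1 contrast is |2 - 18/4| = 2.5
        ecv = ECvMatrix(
            [f"s{i}" for i in range(6)], ["e1"],
            np.array([[1.0], [3.0], [2.0], [4.0], [5.0], [7.0]]),
        )
        groups = GroupAssignment(
            {"s0": "R1", "s1": "R1", "s2": "R2", "s3": "R2", "s4": "R3", "s5": "R3"}
        )
        table = delta_ecv(ecv, groups)
        assert table.value("R1", "e1") == pytest.approx(2.5)
        assert table.value("R2", "e1") == pytest.approx(1.0)
        assert table.value("R3", "e1") == pytest.approx(3.5)

    def test_translation_invariance(self, rng):
        values = rng.normal(size=(9, 4))
        samples = [f"s{i}" for i in range(9)]
        groups = GroupAssignment({s: f"g{i % 3}" for i, s in enumerate(samples)})
        t1 = delta_ecv(ECvMatrix(samples, list("ABCD"), values), groups)
        t2 = delta_ecv(ECvMatrix(samples, list("ABCD"), values + 7.5), groups)
        np.testing.assert_allclose(t1.values, t2.values, atol=1e-12)

    def test_matches_naive_loop_oracle(self):
        for trial in range(100):
            r = np.random.default_rng(trial)
            n, e, m = int(r.integers(4, 12)), int(r.integers(1, 6)), int(r.integers(2, 4))
            samples = [f"s{i}" for i in range(n)]
            labels = {s: f"g{r.integers(0, m)}" for s in samples}
            while len(set(labels.values())) < 2:
                labels = {s: f"g{r.integers(0, m)}" for s in samples}
            values = r.normal(size=(n, e))
            ecv = ECvMatrix(samples, [f"e{j}" for j in range(e)], values)
            groups = GroupAssignment(labels)
            table = delta_ecv(ecv, groups)
            for g in groups.group_names:
                inside = [i for i, s in enumerate(samples) if labels[s] == g]
                outside = [i for i, s in enumerate(samples) if labels[s] != g]
                for j in range(e):
                    expected = abs(
                        np.mean([values[i, j] for i in inside])
                        - np.mean([values[i, j] for i in outside])
                    )
                    assert table.value(g, f"e{j}") == pytest.approx(expected, abs=1e-12)

    def test_empty_group_rejected(self):
        ecv = ECvMatrix(["a", "b"], ["e1"], np.array([[1.0], [2.0]]))
        groups = GroupAssignment({"a": "g1", "b": "g2", "zz": "g3"})
        with pytest.raises(ValueError, match="g3"):
            delta_ecv(ecv, groups)

    def test_two_group_symmetry_exact(self, rng):
        values = rng.normal(size=(10, 5))
        samples = [f"s{i}" for i in range(10)]
        groups = GroupAssignment({s: "A" if i < 4 else "B" for i, s in enumerate(samples)})
        table = delta_ecv(ECvMatrix(samples, list("VWXYZ"), values), groups)
        np.testing.assert_array_equal(table.values[0], table.values[1])


class TestExtractSubtypeSpecific:
    def _table(self, values, groups=("g1", "g2", "g3")):
        e = values.shape[1]
        return DeltaECvTable(list(groups), [f"e{j:02d}" for j in range(e)], values)

    def test_full_overlap_gives_empty_exclusive_sets(self):
        values = np.tile(np.linspace(1, 0, 10), (2, 1))
        table = extract_subtype_specific_edges(self._table(values, ("a", "b")), 0.3)
        assert table.top_sets["a"] == table.top_sets["b"]
        assert table.exclusive_sets == {"a": [], "b": []}

    def test_disjoint_top1_edges(self):
        values = np.zeros((3, 10))
        values[0, 0], values[1, 1], values[2, 2] = 5.0, 4.0, 3.0
        table = extract_subtype_specific_edges(self._table(values), 0.1)
        assert table.exclusive_sets == {"g1": ["e00"], "g2": ["e01"], "g3": ["e02"]}

    def test_ceiling_of_fraction(self):
        values = np.arange(30, dtype=float).reshape(3, 10)
        table = extract_subtype_specific_edges(self._table(values), 0.25)
        assert all(len(v) == 3 for v in table.top_sets.values())  # ceil(2.5) = 3

    def test_exclusive_sets_pairwise_disjoint_and_subset_of_top(self, rng):
        for _ in range(20):
            values = np.abs(rng.normal(size=(3, 15)))
            table = extract_subtype_specific_edges(self._table(values), 0.2)
            names = table.group_names
            for i, g in enumerate(names):
                assert set(table.exclusive_sets[g]) <= set(table.top_sets[g])
                for h in names[i + 1:]:
                    assert not set(table.exclusive_sets[g]) & set(table.exclusive_sets[h])

    def test_relabelling_invariance(self, rng):
        values = np.abs(rng.normal(size=(3, 12)))
        t1 = extract_subtype_specific_edges(self._table(values, ("g1", "g2", "g3")), 0.25)
        t2 = extract_subtype_specific_edges(self._table(values, ("x", "y", "z")), 0.25)
        for a, b in zip(("g1", "g2", "g3"), ("x", "y", "z")):
            assert t1.exclusive_sets[a] == t2.exclusive_sets[b]

    def test_invalid_fraction_rejected(self):
        table = self._table(np.ones((3, 4)))
        with pytest.raises(ValueError):
            extract_subtype_specific_edges(table, 0.0)
        with pytest.raises(ValueError):
            extract_subtype_specific_edges(table, 1.5)

    def test_tie_break_by_edge_id(self):
        values = np.ones((2, 4))
        table = extract_subtype_specific_edges(self._table(values, ("a", "b")), 0.5)
        assert table.top_sets["a"] == ["e00", "e01"]


class TestInducedSubnetwork:
    def test_empty_edge_set(self):
        net = NetworkStructure([], [("A", "B")])
        sub = induced_subnetwork(net, [])
        assert sub.nodes == [] and sub.edges == []

    def test_largest_component(self):
        net = NetworkStructure([], [("A", "B"), ("B", "C"), ("D", "E")])
        sub = induced_subnetwork(net, ["A->B", "B->C", "D->E"], largest_component=True)
        assert set(sub.nodes) == {"A", "B", "C"}

    def test_out_degree(self):
        net = NetworkStructure([], [("B", "A"), ("B", "C")])
        assert out_degrees(net)["B"] == 2
        assert out_degrees(net)["A"] == 0

    def test_unknown_edge_rejected(self):
        net = NetworkStructure([], [("A", "B")])
        with pytest.raises(ValueError, match="not present"):
            induced_subnetwork(net, ["B->A"])

    def test_largest_weak_component_tie_break(self):
        net = NetworkStructure([], [("X", "Y"), ("A", "B")])
        comp = largest_weak_component(net)
        assert set(comp.nodes) == {"A", "B"}  # ties -> smallest member id


class TestEcvMatrixIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        ecv = ECvMatrix(
            ["s1", "s2"], ["A->B", "B->C"], rng.normal(size=(2, 2))
        )
        path = tmp_path / "ecv.tsv"
        ecv.write_tsv(path)
        back = ECvMatrix.read_tsv(path)
        assert back.sample_ids == ecv.sample_ids
        assert back.edge_ids == ecv.edge_ids
        np.testing.assert_array_equal(back.values, ecv.values)
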