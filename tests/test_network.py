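"""Structure learning, BIC family scores, strengths and weighted degree."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tracnet.dataset import UniversalDataset
from tracnet.features import pairwise_mi
from tracnet.network import (
    UniversalGraph,
    edge_strengths,
    family_score,
    learn_structure,
    weighted_degree,
)


def make_dataset(columns: dict[str, np.ndarray]) -> UniversalDataset:
    labels = list(columns)
    values = np.column_stack([columns[k] for k in labels])
    prov = pd.DataFrame(
        {"trajectory_id": "t", "source_frame": np.arange(values.shape[0])}
    )
    return UniversalDataset(values, labels, prov)


def enumerate_dags(nodes: list[str]):
    """All DAGs over the nodes (25 for three nodes), as edge sets."""
    possible = [(a, b) for a in nodes for b in nodes if a != b]
    for mask in itertools.product([0, 1], repeat=len(possible)):
        edges = {e for e, m in zip(possible, mask) if m}
        if any((b, a) in edges for a, b in edges):
            continue
        try:
            UniversalGraph(nodes, edges)
        except ValueError:
            continue
        yield edges


def total_score(dataset: UniversalDataset, edges: set) -> float:
    nodes = dataset.contact_labels
    return sum(
        family_score(dataset, v, tuple(sorted(p for p, c in edges if c == v)))
        for v in nodes
    )


class TestFamilyScore:
    def test_closed_form_no_parents(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 1000)
        data = make_dataset({"y": y, "pad": rng.integers(0, 2, 1000)})
        p = y.mean()
        h_nats = -(p * math.log(p) + (1 - p) * math.log(1 - p))
        expected = -1000 * h_nats - math.log(1000) / 2
        assert family_score(data, "y") == pytest.approx(expected, rel=1e-12)

    def test_deterministic_parent_beats_empty(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 1000)
        data = make_dataset({"x": x, "y": x.copy()})
        assert family_score(data, "y", ("x",)) > family_score(data, "y")

    def test_irrelevant_parent_decreases_score(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 2000)
        y = x ^ (rng.random(2000) < 0.1)
        noise = rng.integers(0, 2, 2000)
        data = make_dataset({"x": x, "y": y.astype(int), "z": noise})
        assert family_score(data, "y", ("x", "z")) < family_score(data, "y", ("x",))

    def test_parent_limit_enforced(self):
        rng = np.random.default_rng(3)
        cols = {f"c{i}_d": rng.integers(0, 2, 50) for i in range(6)}
        data = make_dataset(cols)
        with pytest.raises(ValueError, match="max_parents"):
            family_score(data, "c0_d", ("c1_d", "c2_d", "c3_d", "c4_d"), max_parents=3)

    def test_decomposability(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, 800)
        y = (x ^ (rng.random(800) < 0.2)).astype(int)
        z = (y ^ (rng.random(800) < 0.2)).astype(int)
        data = make_dataset({"x": x, "y": y, "z": z})
        edges = {("x", "y"), ("y", "z")}
        graph = learn_structure(data, seed=0)
        assert graph.total_score() == pytest.approx(
            total_score(data, graph.edges), rel=1e-12
        )
        # a single-edge change alters exactly one family term
        with_edge = total_score(data, edges)
        without = total_score(data, edges - {("y", "z")})
        delta = family_score(data, "z", ("y",)) - family_score(data, "z")
        assert with_edge - without == pytest.approx(delta, rel=1e-12)


def chain_dataset(seed: int, n: int = 5000) -> UniversalDataset:
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    y = (x ^ (rng.random(n) < 0.15)).astype(int)
    z = (y ^ (rng.random(n) < 0.15)).astype(int)
    return make_dataset({"x": x, "y": y, "z": z})


class TestLearnStructure:
    def test_chain_matches_exhaustive_enumeration(self):
        data = chain_dataset(0)
        graph = learn_structure(data, restarts=3, seed=0)
        best = max(total_score(data, e) for e in enumerate_dags(data.contact_labels))
        assert graph.total_score() == pytest.approx(best, rel=1e-12)
        skeleton = {tuple(sorted(e)) for e in graph.edges}
        assert skeleton == {("x", "y"), ("y", "z")}

    def test_independent_coins_give_empty_graph(self):
        rng = np.random.default_rng(10)
        data = make_dataset({f"c{i}_d": rng.integers(0, 2, 5000) for i in range(5)})
        graph = learn_structure(data, seed=0)
        assert graph.edges == set()

    def test_determinism(self):
        data = chain_dataset(3)
        g1 = learn_structure(data, restarts=2, seed=7)
        g2 = learn_structure(data, restarts=2, seed=7)
        assert g1.edges == g2.edges

    def test_constant_column_strict_mode(self):
        data = make_dataset(
            {"a_b": np.ones(100, dtype=int), "c_d": np.random.default_rng(0).integers(0, 2, 100)}
        )
        with pytest.raises(ValueError, match="constant"):
            learn_structure(data, strict=True)
        with pytest.warns(UserWarning, match="constant"):
            graph = learn_structure(data)
        assert "a_b" not in graph.nodes

    def test_result_is_acyclic(self):
        # UniversalGraph validates acyclicity on construction
        graph = learn_structure(chain_dataset(5), restarts=3, seed=1)
        assert not graph._find_cycle()


class TestStrengthsAndDegree:
    def test_identical_balanced_columns_edge_is_one_bit(self):
        x = np.array([1] * 200 + [0] * 200)
        data = make_dataset({"a_b": x, "c_d": x.copy()})
        graph = UniversalGraph(["a_b", "c_d"], {("a_b", "c_d")})
        edge_strengths(graph, data)
        assert graph.edge_strength[("a_b", "c_d")] == pytest.approx(1.0, abs=1e-12)

    def test_independent_columns_edge_near_zero(self):
        rng = np.random.default_rng(11)
        data = make_dataset(
            {"a_b": rng.integers(0, 2, 10000), "c_d": rng.integers(0, 2, 10000)}
        )
        graph = UniversalGraph(["a_b", "c_d"], {("a_b", "c_d")})
        edge_strengths(graph, data)
        assert graph.edge_strength[("a_b", "c_d")] < 0.01

    def test_strengths_match_pairwise_mi(self, small_analysis):
        graph, data = small_analysis["graph"], small_analysis["dataset"]
        for (p, c), s in graph.edge_strength.items():
            assert s == pairwise_mi(data.column(p), data.column(c))

    def test_weighted_degree_sums_incident_strengths(self):
        graph = UniversalGraph(
            ["a", "b", "c", "d"],
            {("a", "b"), ("c", "b")},
            {("a", "b"): 0.5, ("c", "b"): 0.3},
        )
        deg = weighted_degree(graph)
        assert deg["b"] == pytest.approx(0.8)
        assert deg["d"] == 0.0

    def test_handshake_identity(self, small_analysis):
        graph = small_analysis["graph"]
        deg = weighted_degree(graph)
        assert sum(deg.values()) == pytest.approx(
            2 * sum(graph.edge_strength.values()), rel=1e-12
        )


class TestGraphContainer:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            UniversalGraph(["a", "b"], {("a", "b"), ("b", "a")})

    def test_neighbors_are_parents_and_children(self):
        g = UniversalGraph(["a", "b", "c"], {("a", "b"), ("b", "c")})
        assert g.neighbors("b") == ["a", "c"]

    def test_edge_tsv_round_trip(self, tmp_path):
        g = UniversalGraph(["a", "b", "c"], {("a", "b")}, {("a", "b"): 0.25})
        path = tmp_path / "edges.tsv"
        g.write_edges_tsv(path)
        back = UniversalGraph.from_edges_tsv(path)
        assert back.edges == g.edges
        assert back.edge_strength[("a", "b")] == 0.25
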