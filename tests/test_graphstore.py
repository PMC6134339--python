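"""Property-graph laws: MERGE idempotence, union algebra, pattern
matching vs brute-force enumeration, and export round trips."""

import itertools

import numpy as np
import pytest

from assocnet.graphstore import (
    AssociationGraph,
    EdgeConstraint,
    NodeConstraint,
    PatternQuery,
    export_graph,
    import_graphml,
    match_pattern,
    parse_query,
    union,
)
from assocnet.synthdata import toy_graph_fixture


def random_graph(seed: int, n_nodes: int = 60, n_edges: int = 150) -> AssociationGraph:
    rng = np.random.default_rng(seed)
    labels = ["wgcna", "PROBE", "SYMBOL", "pheno", "cellprop"]
    g = AssociationGraph()
    keys = []
    for i in range(n_nodes):
        label = labels[int(rng.integers(len(labels)))]
        keys.append(
            g.merge_node(label, f"n{i}", "ds", "1",
                         logfc=float(np.round(rng.normal(), 3)))
        )
    types = ["correlation", "enrichment", "mapping"]
    for _ in range(n_edges):
        a, b = rng.integers(n_nodes, size=2)
        if a == b:
            continue
        g.merge_edge(keys[a], keys[b], types[int(rng.integers(3))],
                     graph_index=int(rng.integers(1, 30)),
                     weight=float(np.round(rng.uniform(-1, 1), 3)))
    return g


class TestMerge:
    def test_node_idempotent(self):
        g = AssociationGraph()
        g.merge_node("wgcna", "blue", "ds1", "1")
        g.merge_node("wgcna", "blue", "ds1", "1")
        assert len(g.nodes) == 1

    def test_property_overlay_keeps_prior_keys(self):
        g = AssociationGraph()
        k = g.merge_node("PROBE", "p1", "ds1", "1", p=0.01)
        g.merge_node("PROBE", "p1", "ds1", "1", logfc=2.5)
        assert g.nodes[k] == {"p": 0.01, "logfc": 2.5}

    def test_square_is_part_of_identity(self):
        g = AssociationGraph()
        g.merge_node("wgcna", "blue", "ds1", "1")
        g.merge_node("wgcna", "blue", "ds2", "1")
        assert len(g.nodes) == 2

    def test_unknown_label_rejected(self):
        g = AssociationGraph()
        with pytest.raises(ValueError):
            g.merge_node("nonsense", "x")

    def test_edge_idempotent_and_type_in_identity(self):
        g = AssociationGraph()
        a = g.merge_node("PROBE", "p1", "ds", "1")
        b = g.merge_node("SYMBOL", "G1")
        g.merge_edge(a, b, "mapping", graph_index=2)
        g.merge_edge(a, b, "mapping", graph_index=2)
        assert len(g.edges) == 1
        g.merge_edge(a, b, "correlation", graph_index=2, weight=0.5)
        assert len(g.edges) == 2

    def test_edge_autocreates_endpoints(self):
        g = AssociationGraph()
        g.merge_edge(("PROBE", "p1", "ds", "1"), ("SYMBOL", "G1", "", ""), "mapping")
        assert len(g.nodes) == 2

    def test_invalid_edge_type_rejected(self):
        g = AssociationGraph()
        with pytest.raises(ValueError):
            g.merge_edge(("PROBE", "p", "", ""), ("SYMBOL", "s", "", ""), "friendship")


class TestUnion:
    def test_union_with_empty_is_identity(self):
        g = random_graph(0)
        u = union([g, AssociationGraph()])
        assert set(u.nodes) == set(g.nodes) and set(u.edges) == set(g.edges)

    def test_union_idempotent(self):
        g = random_graph(1)
        u = union([g, g])
        assert len(u.nodes) == len(g.nodes) and len(u.edges) == len(g.edges)

    def test_union_associative(self):
        a, b, c = random_graph(2), random_graph(3), random_graph(4)
        left = union([union([a, b]), c])
        right = union([a, union([b, c])])
        assert set(left.nodes) == set(right.nodes)
        assert set(left.edges) == set(right.edges)

    def test_shared_nodes_appear_once(self):
        graphs = []
        for i in range(5):
            g = AssociationGraph()
            p = g.merge_node("PROBE", f"p{i}", "ds", "1")
            s = g.merge_node("SYMBOL", "SHARED")
            g.merge_edge(p, s, "mapping", graph_index=i + 1)
            graphs.append(g)
        u = union(graphs)
        symbols = [k for k in u.nodes if k[0] == "SYMBOL"]
        assert len(symbols) == 1 and len(u.edges) == 5


def bruteforce_paths(g: AssociationGraph, query: PatternQuery):
    """Independent enumeration over all node tuples of the right length."""
    nodes = list(g.nodes)
    edge_lookup: dict[tuple, list] = {}
    for (s, t, typ, gi), props in g.edges.items():
        edge_lookup.setdefault((s, t), []).append(((s, t, typ, gi), props))
        edge_lookup.setdefault((t, s), []).append(((s, t, typ, gi), props))
    k = len(query.node_constraints)
    out = []
    for combo in itertools.permutations(nodes, k):
        if not all(
            nc.matches(key, g.nodes[key])
            for nc, key in zip(query.node_constraints, combo)
        ):
            continue
        ok = True
        for i, ec in enumerate(query.edge_constraints):
            pair = (combo[i], combo[i + 1])
            if not any(ec.matches(ek, props) for ek, props in edge_lookup.get(pair, [])):
                ok = False
                break
        if ok:
            out.append(combo)
    return sorted(out)


def test_match_equals_bruteforce_on_random_graphs():
    query = PatternQuery(
        node_constraints=[
            NodeConstraint("pheno"),
            NodeConstraint("wgcna"),
            NodeConstraint("PROBE", [("logfc", ">", 0.0)]),
        ],
        edge_constraints=[
            EdgeConstraint(None, [("weight", ">", 0.0)]),
            EdgeConstraint(None),
        ],
    )
    for seed in range(5):
        g = random_graph(seed, n_nodes=40, n_edges=120)
        _, paths = match_pattern(g, query)
        assert paths == bruteforce_paths(g, query)


def test_unsatisfiable_label_sequence_empty():
    g = toy_graph_fixture()
    q = PatternQuery(
        node_constraints=[NodeConstraint("CELL"), NodeConstraint("pheno")],
        edge_constraints=[EdgeConstraint(None)],
    )
    _, paths = match_pattern(g, q)
    assert paths == []


def test_missing_property_predicate_fails_candidate():
    g = AssociationGraph()
    a = g.merge_node("PROBE", "p1", "ds", "1")  # no logfc property
    b = g.merge_node("SYMBOL", "G1")
    g.merge_edge(a, b, "mapping")
    q = PatternQuery(
        node_constraints=[NodeConstraint("PROBE", [("logfc", ">", 0)]), NodeConstraint("SYMBOL")],
        edge_constraints=[EdgeConstraint(None)],
    )
    _, paths = match_pattern(g, q)
    assert paths == []


class TestQueryDSL:
    def test_string_dsl_roundtrip(self):
        q = parse_query("pheno - correlation[weight>0.6] - wgcna[square=toy] - mapping - PROBE[logfc>2]")
        assert [nc.label for nc in q.node_constraints] == ["pheno", "wgcna", "PROBE"]
        assert q.edge_constraints[0].type == "correlation"
        assert q.node_constraints[1].predicates == [("square", "=", "toy")]

    def test_dsl_matches_toy_worked_query(self):
        g = toy_graph_fixture()
        q = parse_query(
            "pheno - correlation[weight>0.6] - wgcna - mapping - PROBE[logfc>2] - mapping - SYMBOL"
        )
        _, paths = match_pattern(g, q)
        assert len(paths) == 1

    def test_json_form(self):
        q = parse_query(
            '{"nodes": [{"label": "pheno"}, {"label": "wgcna"}],'
            ' "edges": [{"type": "correlation", "predicates": [["weight", ">", 0.6]]}]}'
        )
        g = toy_graph_fixture()
        _, paths = match_pattern(g, q)
        assert len(paths) == 2  # cd4_count-turquoise and crp-blue

    def test_malformed_predicate_rejected(self):
        with pytest.raises(ValueError):
            parse_query("pheno[weight!!0.6]")


class TestExports:
    def test_graphml_roundtrip_identity(self, tmp_path):
        g = random_graph(7)
        path = tmp_path / "g.graphml"
        export_graph(g, path, format="graphml")
        back = import_graphml(path)
        assert set(back.nodes) == set(g.nodes)
        assert set(back.edges) == set(g.edges)
        for k in g.nodes:
            assert back.nodes[k] == pytest.approx(g.nodes[k])

    def test_cypher_export_deterministic(self, tmp_path):
        g = random_graph(8)
        p1, p2 = tmp_path / "a.cypher", tmp_path / "b.cypher"
        export_graph(g, p1, format="cypher")
        export_graph(g, p2, format="cypher")
        assert p1.read_bytes() == p2.read_bytes()
        text = p1.read_text()
        assert text.index("MERGE (n:") < text.index("MERGE (a)-")

    def test_tsv_pair_row_counts(self, tmp_path):
        g = random_graph(9)
        files = export_graph(g, tmp_path / "g.tsv", format="tsv_pair")
        nodes_rows = files[0].read_text().strip().splitlines()
        edges_rows = files[1].read_text().strip().splitlines()
        assert len(nodes_rows) - 1 == len(g.nodes)
        assert len(edges_rows) - 1 == len(g.edges)
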