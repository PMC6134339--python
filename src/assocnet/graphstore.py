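"""Typed multipartite property graph with MERGE semantics.

Nodes carry one of twelve admissible labels and are identified by the
key (label, name, square, edge): ``square`` scopes a node to a dataset
("" for global annotation nodes shared across datasets) and ``edge``
scopes it to a contrast.  Edges carry one of exactly three types —
correlation, enrichment or mapping — plus the index of the bipartite
graph they came from, and are identified by (source key, target key,
type, graph_index).  MERGE is idempotent with last-write-wins property
overlay, so folding many bipartite graphs into one union is associative
and repeat-safe.  Pattern matching is undirected path search with
property predicates, the in-process analogue of a Cypher
``MATCH ... WHERE`` query; exports cover GraphML, node/edge TSV pairs
(Cytoscape-ready) and a deterministic Cypher MERGE script.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = [
    "NODE_LABELS",
    "EDGE_TYPES",
    "NodeKey",
    "AssociationGraph",
    "PatternQuery",
    "match_pattern",
    "union",
    "export_graph",
    "import_graphml",
    "parse_query",
]

NODE_LABELS = frozenset(
    {
        "PROBETYPE", "PROBE", "SYMBOL", "wgcna", "baylor", "reactomePW",
        "PalWangPW", "ImmunePW", "cellEx", "CELL", "cellprop", "pheno",
    }
)
EDGE_TYPES = frozenset({"correlation", "enrichment", "mapping"})

NodeKey = tuple[str, str, str, str]  # (label, name, square, edge)
EdgeKey = tuple[NodeKey, NodeKey, str, int]

_OPS = {
    "=": lambda a, b: a == b,
    ">": lambda a, b: a > b,
    "<": lambda a, b: a < b,
    ">=": lambda a, b: a >= b,
    "<=": lambda a, b: a <= b,
}


def node_key(label: str, name: str, square: str = "", edge: str = "") -> NodeKey:
    if label not in NODE_LABELS:
        raise ValueError(f"unknown node label {label!r}")
    return (label, str(name), str(square), str(edge))


@dataclass
class AssociationGraph:
    """In-process multipartite property graph."""

    nodes: dict[NodeKey, dict] = field(default_factory=dict)
    edges: dict[EdgeKey, dict] = field(default_factory=dict)

    # -- MERGE semantics -------------------------------------------------
    def merge_node(
        self,
        label: str,
        name: str,
        square: str = "",
        edge: str = "",
        **properties,
    ) -> NodeKey:
        """Insert-or-overlay a node; returns its key.

        Existing properties are kept, new values win on collision —
        the behaviour of Cypher MERGE followed by SET.
        """
        key = node_key(label, name, square, edge)
        if key in self.nodes:
            self.nodes[key].update(properties)
        else:
            self.nodes[key] = dict(properties)
        return key

    def merge_edge(
        self,
        source: NodeKey,
        target: NodeKey,
        type: str,
        graph_index: int = 0,
        **properties,
    ) -> EdgeKey:
        """Idempotent edge insert; missing endpoints are auto-created."""
        if type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {type!r}")
        for k in (source, target):
            if k[0] not in NODE_LABELS:
                raise ValueError(f"unknown node label {k[0]!r}")
            if k not in self.nodes:
                self.nodes[k] = {}
        key = (source, target, type, int(graph_index))
        if key in self.edges:
            self.edges[key].update(properties)
        else:
            self.edges[key] = dict(properties)
        return key

    # -- views -----------------------------------------------------------
    def edge_types(self) -> set[str]:
        return {k[2] for k in self.edges}

    def graph_indices(self) -> set[int]:
        return {k[3] for k in self.edges}

    def neighbors(self, key: NodeKey):
        """Undirected adjacency: yields (other key, edge key, properties)."""
        for (s, t, typ, gi), props in self.edges.items():
            if s == key:
                yield t, (s, t, typ, gi), props
            elif t == key:
                yield s, (s, t, typ, gi), props

    def copy(self) -> "AssociationGraph":
        return AssociationGraph(
            nodes={k: dict(v) for k, v in self.nodes.items()},
            edges={k: dict(v) for k, v in self.edges.items()},
        )


def union(graphs: list[AssociationGraph]) -> AssociationGraph:
    """Fold MERGE over all inputs: associative, idempotent on keys."""
    out = AssociationGraph()
    for g in graphs:
        for key, props in g.nodes.items():
            out.merge_node(key[0], key[1], key[2], key[3], **props)
        for (s, t, typ, gi), props in g.edges.items():
            out.merge_edge(s, t, typ, gi, **props)
    return out


# -- pattern matching ----------------------------------------------------


@dataclass
class NodeConstraint:
    label: str | None = None
    predicates: list[tuple[str, str, object]] = field(default_factory=list)  # (prop, op, value)

    def matches(self, key: NodeKey, props: dict) -> bool:
        if self.label is not None and key[0] != self.label:
            return False
        merged = {"name": key[1], "square": key[2], "edge": key[3], **props}
        return _check(self.predicates, merged)


@dataclass
class EdgeConstraint:
    type: str | None = None
    predicates: list[tuple[str, str, object]] = field(default_factory=list)

    def matches(self, edge_key: EdgeKey, props: dict) -> bool:
        if self.type is not None and edge_key[2] != self.type:
            return False
        return _check(self.predicates, props)


def _check(predicates, props: dict) -> bool:
    for prop, op, value in predicates:
        if prop not in props:
            return False  # predicate on a missing property fails the candidate
        try:
            if not _OPS[op](props[prop], value):
                return False
        except TypeError:
            return False
    return True


@dataclass
class PatternQuery:
    """Alternating node / edge constraints describing an undirected path."""

    node_constraints: list[NodeConstraint]
    edge_constraints: list[EdgeConstraint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.node_constraints:
            raise ValueError("pattern needs >= 1 node constraint")
        if len(self.edge_constraints) != len(self.node_constraints) - 1:
            raise ValueError("need exactly one edge constraint between consecutive nodes")


def match_pattern(
    graph: AssociationGraph, query: PatternQuery
) -> tuple[AssociationGraph, list[tuple[NodeKey, ...]]]:
    """All simple paths satisfying every constraint, plus their union subgraph.

    Matching is undirected; paths are returned in lexicographic order of
    their node-key tuples and may not revisit a node.
    """
    paths: list[tuple[tuple[NodeKey, ...], tuple[EdgeKey, ...]]] = []
    starts = [
        key for key, props in graph.nodes.items() if query.node_constraints[0].matches(key, props)
    ]
    adjacency: dict[NodeKey, list] = {}
    for (s, t, typ, gi), props in graph.edges.items():
        ekey = (s, t, typ, gi)
        adjacency.setdefault(s, []).append((t, ekey, props))
        adjacency.setdefault(t, []).append((s, ekey, props))

    def extend(path_nodes: list[NodeKey], path_edges: list[EdgeKey]) -> None:
        depth = len(path_nodes)
        if depth == len(query.node_constraints):
            paths.append((tuple(path_nodes), tuple(path_edges)))
            return
        current = path_nodes[-1]
        ec = query.edge_constraints[depth - 1]
        nc = query.node_constraints[depth]
        for other, ekey, eprops in adjacency.get(current, []):
            if other in path_nodes:
                continue
            if not ec.matches(ekey, eprops):
                continue
            if not nc.matches(other, graph.nodes[other]):
                continue
            extend(path_nodes + [other], path_edges + [ekey])

    for start in sorted(starts):
        extend([start], [])
    paths.sort(key=lambda pe: pe[0])
    # parallel edges can reach the same node sequence twice; a path is
    # reported once per node sequence
    seen: set[tuple[NodeKey, ...]] = set()
    deduped = []
    for pnodes, pedges in paths:
        if pnodes not in seen:
            seen.add(pnodes)
            deduped.append((pnodes, pedges))
    paths = deduped

    sub = AssociationGraph()
    for pnodes, pedges in paths:
        for k in pnodes:
            sub.merge_node(k[0], k[1], k[2], k[3], **graph.nodes[k])
        for s, t, typ, gi in pedges:
            sub.merge_edge(s, t, typ, gi, **graph.edges[(s, t, typ, gi)])
    return sub, [pnodes for pnodes, _ in paths]


def parse_query(spec: str | dict) -> PatternQuery:
    """Build a PatternQuery from JSON or a compact string DSL.

    The DSL alternates node and edge terms separated by ``-``::

        pheno - correlation[weight>0.6] - wgcna[square=ds1] - mapping - PROBE[logfc>2]

    Node terms are ``label[pred,pred,...]``; edge terms are
    ``type[pred,...]`` with type one of the three edge types or ``*``.
    Predicates are ``prop OP value`` with OP in ``= > < >= <=``; values
    parse as JSON when possible, else as strings.
    """
    if isinstance(spec, str) and spec.lstrip().startswith("{"):
        spec = json.loads(spec)
    if isinstance(spec, dict):
        nodes = [
            NodeConstraint(n.get("label"), [tuple(p) for p in n.get("predicates", [])])
            for n in spec["nodes"]
        ]
        edges = [
            EdgeConstraint(e.get("type"), [tuple(p) for p in e.get("predicates", [])])
            for e in spec.get("edges", [])
        ]
        return PatternQuery(nodes, edges)

    terms = [t.strip() for t in str(spec).split("-")]
    nodes, edges = [], []
    for i, term in enumerate(terms):
        label, preds = _parse_term(term)
        if i % 2 == 0:
            nodes.append(NodeConstraint(None if label == "*" else label, preds))
        else:
            edges.append(EdgeConstraint(None if label == "*" else label, preds))
    return PatternQuery(nodes, edges)


def _parse_term(term: str):
    preds: list[tuple[str, str, object]] = []
    label = term
    if "[" in term:
        if not term.endswith("]"):
            raise ValueError(f"malformed term {term!r}")
        label, inner = term.split("[", 1)
        for raw in inner[:-1].split(","):
            raw = raw.strip()
            if not raw:
                continue
            for op in (">=", "<=", "=", ">", "<"):
                if op in raw:
                    prop, val = raw.split(op, 1)
                    try:
                        value = json.loads(val.strip())
                    except json.JSONDecodeError:
                        value = val.strip()
                    preds.append((prop.strip(), op, value))
                    break
            else:
                raise ValueError(f"malformed predicate {raw!r}")
    return label.strip(), preds


# -- exports -------------------------------------------------------------


def _key_id(key: NodeKey) -> str:
    return "|".join(key)


def _to_networkx(graph: AssociationGraph) -> nx.MultiGraph:
    g = nx.MultiGraph()
    for key, props in graph.nodes.items():
        g.add_node(
            _key_id(key), label=key[0], name=key[1], square=key[2], edge=key[3], **props
        )
    for (s, t, typ, gi), props in graph.edges.items():
        # _src records edge orientation: MultiGraph iteration may flip endpoints
        g.add_edge(
            _key_id(s), _key_id(t), key=f"{typ}|{gi}",
            type=typ, graph_index=gi, _src=_key_id(s), **props,
        )
    return g


def export_graph(graph: AssociationGraph, path: str | Path, format: str = "graphml") -> list[Path]:
    """Write the graph as GraphML, a nodes/edges TSV pair, or a Cypher script.

    All formats are deterministic: rows/statements are sorted by
    identity key, so re-exporting the same graph is byte-identical.
    """
    path = Path(path)
    if format == "graphml":
        g = _to_networkx(graph)
        nx.write_graphml(g, path)
        return [path]
    if format == "tsv_pair":
        nodes_path = path.with_suffix(".nodes.tsv")
        edges_path = path.with_suffix(".edges.tsv")
        prop_keys = sorted({p for props in graph.nodes.values() for p in props})
        with open(nodes_path, "w") as fh:
            fh.write("\t".join(["id", "label", "name", "square", "edge", *prop_keys]) + "\n")
            for key in sorted(graph.nodes):
                props = graph.nodes[key]
                row = [_key_id(key), *key] + [_fmt(props.get(p)) for p in prop_keys]
                fh.write("\t".join(row) + "\n")
        eprop_keys = sorted({p for props in graph.edges.values() for p in props})
        with open(edges_path, "w") as fh:
            fh.write("\t".join(["source", "target", "type", "graph_index", *eprop_keys]) + "\n")
            for key in sorted(graph.edges):
                s, t, typ, gi = key
                props = graph.edges[key]
                row = [_key_id(s), _key_id(t), typ, str(gi)] + [
                    _fmt(props.get(p)) for p in eprop_keys
                ]
                fh.write("\t".join(row) + "\n")
        return [nodes_path, edges_path]
    if format == "cypher":
        lines = []
        for key in sorted(graph.nodes):
            props = {"square": key[2], "edge": key[3], **graph.nodes[key]}
            lines.append(f"MERGE (n:{key[0]} {{name: {json.dumps(key[1])}}}) SET n += {_cyprops(props)};")
        for s, t, typ, gi in sorted(graph.edges):
            props = {"graph_index": gi, **graph.edges[(s, t, typ, gi)]}
            lines.append(
                f"MATCH (a:{s[0]} {{name: {json.dumps(s[1])}}}), (b:{t[0]} {{name: {json.dumps(t[1])}}}) "
                f"MERGE (a)-[r:{typ}]-(b) SET r += {_cyprops(props)};"
            )
        path.write_text("\n".join(lines) + "\n")
        return [path]
    raise ValueError(f"unknown export format {format!r}")


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _cyprops(props: dict) -> str:
    items = ", ".join(f"{k}: {json.dumps(v)}" for k, v in sorted(props.items()))
    return "{" + items + "}"


def import_graphml(path: str | Path) -> AssociationGraph:
    g = nx.read_graphml(path, force_multigraph=True)
    out = AssociationGraph()
    for _, data in g.nodes(data=True):
        data = dict(data)
        label = data.pop("label")
        name = data.pop("name")
        square = data.pop("square", "")
        edge = data.pop("edge", "")
        out.merge_node(label, name, square, edge, **data)
    for u, v, data in g.edges(data=True):
        data = dict(data)
        typ = data.pop("type")
        gi = int(data.pop("graph_index", 0))
        src = data.pop("_src", u)
        if src != u:
            u, v = v, u
        ukey = tuple(u.split("|"))
        vkey = tuple(v.split("|"))
        out.merge_edge(ukey, vkey, typ, gi, **data)
    return out
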