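"""In-memory labeled property graph with integrity constraints.

The store implements the classical property-graph tuple
``(V, E, rho, lambda1, lambda2, sigma)``: a finite node set ``V``, an edge
set ``E`` disjoint from it, a total endpoint function mapping each edge to
an ordered node pair, a total labelling of nodes with non-empty label sets,
a total single-label labelling of edges, and a partial property function
assigning at most one value per (element, property-name) pair.  Values are
scalars (int, float, str, bool) or homogeneous lists (used for raw sample
arrays).  A missing value is expressed by property absence, which is how
missing signal samples are represented downstream.

Label vocabularies are open registries seeded with the session-schema
vocabulary (experiments, recordings, channels, measures, timestamps, signal
values and the edges wiring them); user-defined labels and properties may
be registered at any time.

Integrity constraints mirror graph-database semantics: each mutating
operation is transactional — if a constraint would be violated the mutation
is rolled back and :class:`~physiograph.errors.ConstraintViolationError`
is raised.
"""

from __future__ import annotations

import json
import operator
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Iterator

import networkx as nx

from .errors import (
    ConstraintViolationError,
    MissingEndpointError,
    RetroactiveViolationError,
    UnknownLabelError,
    ValidationError,
)

#: Node labels the schema layer uses, pre-registered on every new graph.
DEFAULT_VERTEX_LABELS = frozenset(
    {
        "Experiment",
        "Recording",
        "Participant",
        "Channel",
        "Timestamp",
        "TimestampMeasure",
        "EpochMeasure",
        "ElectrodeMeasure",
        "SignalValue",
    }
)

#: Edge labels the schema layer uses.
DEFAULT_EDGE_LABELS = frozenset(
    {
        "PART_OF",
        "TAKES_PART_IN",
        "TAKES",
        "HAS_RECORDING_TYPE",
        "HAS_MEASURE",
        "HAS_SIGNAL",
        "NEXT",
        "IN_SEC",
        "START_IN_SEC",
        "END_IN_SEC",
        "INFLUENCE_ON",
    }
)

_SCALAR_TYPES = (int, float, str, bool)

_OPS: dict[str, Callable[[Any, Any], bool]] = {
    "<": operator.lt,
    "<=": operator.le,
    "=": operator.eq,
    "==": operator.eq,
    ">=": operator.ge,
    ">": operator.gt,
    "!=": operator.ne,
}


def _check_value(v: Any) -> None:
    if isinstance(v, _SCALAR_TYPES):
        return
    if isinstance(v, (list, tuple)):
        if any(not isinstance(x, _SCALAR_TYPES) for x in v):
            raise ValidationError("list property values must hold scalars")
        return
    raise ValidationError(f"unsupported property value type: {type(v)!r}")


@dataclass
class Node:
    id: int
    labels: set[str]
    props: dict[str, Any] = field(default_factory=dict)


@dataclass
class Edge:
    id: int
    source: int
    target: int
    label: str
    props: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class IntegrityConstraint:
    """Uniqueness or mandatory-property constraint scoped to one label.

    ``uniqueness``: no two nodes carrying ``target_label`` may share a value
    of ``property`` (absent values do not collide).
    ``mandatory``: every element carrying ``target_label`` must have a
    non-null value for ``property``.
    """

    kind: str  # "uniqueness" | "mandatory"
    target_label: str
    property: str

    def __post_init__(self) -> None:
        if self.kind not in ("uniqueness", "mandatory"):
            raise ValidationError(f"unknown constraint kind {self.kind!r}")


def default_constraints() -> list[IntegrityConstraint]:
    """The constraint set registered on every new session graph."""
    return [
        IntegrityConstraint("uniqueness", "Experiment", "name"),
        IntegrityConstraint("uniqueness", "Participant", "user_id"),
        IntegrityConstraint("uniqueness", "Timestamp", "value"),
        IntegrityConstraint("uniqueness", "Measure", "signal_id"),
        IntegrityConstraint("mandatory", "Channel", "type"),
    ]


#: Labels treated as "Measure" for constraint scoping: the measure node
#: labels all imply measure-hood even though the store has no label
#: hierarchy.
_MEASURE_LABELS = {"TimestampMeasure", "EpochMeasure", "ElectrodeMeasure"}


def _has_label(el: Node | Edge, label: str) -> bool:
    if isinstance(el, Edge):
        return el.label == label
    if label in el.labels:
        return True
    if label == "Measure" and el.labels & _MEASURE_LABELS:
        return True
    return False


class PropertyGraph:
    """Mutable labeled property graph with transactional constraint checks."""

    def __init__(self, *, seed_schema: bool = True) -> None:
        self._nodes: dict[int, Node] = {}
        self._edges: dict[int, Edge] = {}
        self._out: dict[int, set[int]] = {}  # node id -> outgoing edge ids
        self._in: dict[int, set[int]] = {}
        self._next_id = 0
        self.vertex_labels: set[str] = set()
        self.edge_labels: set[str] = set()
        self.properties: set[str] = set()
        self.constraints: list[IntegrityConstraint] = []
        # value index per uniqueness constraint: (label, prop) -> {value: node id}
        self._uniq: dict[tuple[str, str], dict[Any, int]] = {}
        if seed_schema:
            self.vertex_labels |= DEFAULT_VERTEX_LABELS
            self.edge_labels |= DEFAULT_EDGE_LABELS
            for c in default_constraints():
                self.register_constraint(c)

    # ------------------------------------------------------------------
    # registries
    def register_vertex_label(self, label: str) -> None:
        self.vertex_labels.add(label)

    def register_edge_label(self, label: str) -> None:
        self.edge_labels.add(label)

    def register_property(self, name: str) -> None:
        self.properties.add(name)

    # ------------------------------------------------------------------
    # accessors
    def node(self, node_id: int) -> Node:
        return self._nodes[node_id]

    def edge(self, edge_id: int) -> Edge:
        return self._edges[edge_id]

    def has_node(self, node_id: int) -> bool:
        return node_id in self._nodes

    def nodes(self) -> Iterator[Node]:
        return iter(self._nodes.values())

    def edges(self) -> Iterator[Edge]:
        return iter(self._edges.values())

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def out_edges(self, node_id: int, label: str | None = None) -> list[Edge]:
        es = [self._edges[i] for i in sorted(self._out.get(node_id, ()))]
        return es if label is None else [e for e in es if e.label == label]

    def in_edges(self, node_id: int, label: str | None = None) -> list[Edge]:
        es = [self._edges[i] for i in sorted(self._in.get(node_id, ()))]
        return es if label is None else [e for e in es if e.label == label]

    def successors(self, node_id: int, label: str | None = None) -> list[int]:
        return [e.target for e in self.out_edges(node_id, label)]

    def predecessors(self, node_id: int, label: str | None = None) -> list[int]:
        return [e.source for e in self.in_edges(node_id, label)]

    # ------------------------------------------------------------------
    # mutation
    def _fresh_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def create_node(self, labels: Iterable[str], props: dict[str, Any] | None = None) -> int:
        """Create a node, verify constraints, return its fresh id.

        Raises ``UnknownLabelError`` for unregistered labels and
        ``ConstraintViolationError`` (with rollback) when the new node would
        break a registered constraint.
        """
        labels = set(labels)
        if not labels:
            raise ValidationError("a node needs at least one label")
        unknown = labels - self.vertex_labels
        if unknown:
            raise UnknownLabelError(f"unregistered vertex label(s): {sorted(unknown)}")
        props = dict(props or {})
        for k, v in props.items():
            _check_value(v)
            self.properties.add(k)
        nid = self._fresh_id()
        node = Node(nid, labels, props)
        self._nodes[nid] = node
        self._out[nid] = set()
        self._in[nid] = set()
        try:
            self._verify_element(node)
        except ConstraintViolationError:
            del self._nodes[nid], self._out[nid], self._in[nid]
            raise
        self._index_node(node)
        return nid

    def create_edge(self, source: int, target: int, label: str,
                    props: dict[str, Any] | None = None) -> int:
        """Create a directed edge ``source -> target`` and return its id."""
        if source not in self._nodes:
            raise MissingEndpointError(f"source node {source} does not exist")
        if target not in self._nodes:
            raise MissingEndpointError(f"target node {target} does not exist")
        if label not in self.edge_labels:
            raise UnknownLabelError(f"unregistered edge label: {label!r}")
        props = dict(props or {})
        for k, v in props.items():
            _check_value(v)
            self.properties.add(k)
        eid = self._fresh_id()
        edge = Edge(eid, source, target, label, props)
        self._edges[eid] = edge
        self._out[source].add(eid)
        self._in[target].add(eid)
        try:
            self._verify_element(edge)
        except ConstraintViolationError:
            self._out[source].discard(eid)
            self._in[target].discard(eid)
            del self._edges[eid]
            raise
        return eid

    def delete_edge(self, edge_id: int) -> None:
        e = self._edges.pop(edge_id)
        self._out[e.source].discard(edge_id)
        self._in[e.target].discard(edge_id)

    def set_property(self, element_id: int, name: str, value: Any) -> None:
        """Set one property on a node or edge, constraint-checked."""
        el = self._nodes.get(element_id) or self._edges.get(element_id)
        if el is None:
            raise MissingEndpointError(f"no element with id {element_id}")
        _check_value(value)
        self.properties.add(name)
        had, old = name in el.props, el.props.get(name)
        el.props[name] = value
        try:
            self._verify_element(el)
        except ConstraintViolationError:
            if had:
                el.props[name] = old
            else:
                del el.props[name]
            raise
        if isinstance(el, Node):
            if had:
                self._unindex_value(el, name, old)
            self._index_node(el, only_prop=name)

    # ------------------------------------------------------------------
    # constraints
    def register_constraint(self, c: IntegrityConstraint) -> None:
        """Enforce ``c`` from now on; existing contents must already satisfy it."""
        bad = self._violations([c])
        if bad:
            raise RetroactiveViolationError("; ".join(bad))
        self.constraints.append(c)
        if c.kind == "uniqueness":
            idx = self._uniq.setdefault((c.target_label, c.property), {})
            for n in self._nodes.values():
                if _has_label(n, c.target_label) and c.property in n.props:
                    v = n.props[c.property]
                    idx[tuple(v) if isinstance(v, list) else v] = n.id

    def _verify_element(self, el: Node | Edge) -> None:
        for c in self.constraints:
            if not _has_label(el, c.target_label):
                continue
            if c.kind == "mandatory":
                if el.props.get(c.property) is None:
                    raise ConstraintViolationError(
                        f"mandatory property {c.property!r} missing on "
                        f"{c.target_label} element {el.id}"
                    )
            else:  # uniqueness applies to nodes
                if isinstance(el, Edge) or c.property not in el.props:
                    continue
                v = el.props[c.property]
                key = tuple(v) if isinstance(v, list) else v
                holder = self._uniq.setdefault((c.target_label, c.property), {}).get(key)
                if holder is not None and holder != el.id:
                    raise ConstraintViolationError(
                        f"duplicate {c.target_label}.{c.property} value {v!r}"
                    )

    def _index_node(self, node: Node, only_prop: str | None = None) -> None:
        for c in self.constraints:
            if c.kind != "uniqueness" or not _has_label(node, c.target_label):
                continue
            if only_prop is not None and c.property != only_prop:
                continue
            if c.property in node.props:
                v = node.props[c.property]
                key = tuple(v) if isinstance(v, list) else v
                self._uniq.setdefault((c.target_label, c.property), {})[key] = node.id

    def _unindex_value(self, node: Node, prop: str, old: Any) -> None:
        key = tuple(old) if isinstance(old, list) else old
        for c in self.constraints:
            if c.kind == "uniqueness" and c.property == prop and _has_label(node, c.target_label):
                idx = self._uniq.get((c.target_label, c.property), {})
                if idx.get(key) == node.id:
                    del idx[key]

    def _violations(self, constraints: list[IntegrityConstraint]) -> list[str]:
        msgs = []
        for c in constraints:
            if c.kind == "uniqueness":
                seen: dict[Any, int] = {}
                for n in self._nodes.values():
                    if _has_label(n, c.target_label) and c.property in n.props:
                        v = n.props[c.property]
                        key = tuple(v) if isinstance(v, list) else v
                        if key in seen:
                            msgs.append(
                                f"nodes {seen[key]} and {n.id} share "
                                f"{c.target_label}.{c.property}={v!r}"
                            )
                        else:
                            seen[key] = n.id
            else:
                for el in list(self._nodes.values()) + list(self._edges.values()):
                    if _has_label(el, c.target_label) and el.props.get(c.property) is None:
                        msgs.append(
                            f"element {el.id} with label {c.target_label} lacks "
                            f"mandatory {c.property!r}"
                        )
        return msgs

    def check_constraints(self) -> list[str]:
        """Batch re-verification of every registered constraint from scratch."""
        return self._violations(self.constraints)

    # ------------------------------------------------------------------
    # matching
    def match(
        self,
        label: str | None = None,
        props: dict[str, Any] | None = None,
        element: str = "node",
    ) -> list[Node] | list[Edge]:
        """Return elements matching a label and property predicates.

        Each predicate value is either a constant (equality) or a tuple
        ``(op, constant)`` with ``op`` one of ``< <= = == >= > !=``.
        """
        pool: Iterable[Node | Edge]
        if element == "node":
            pool = self._nodes.values()
        elif element == "edge":
            pool = self._edges.values()
        else:
            raise ValidationError("element must be 'node' or 'edge'")
        out = []
        for el in pool:
            if label is not None and not _has_label(el, label):
                continue
            ok = True
            for k, pred in (props or {}).items():
                v = el.props.get(k)
                if isinstance(pred, tuple):
                    op, const = pred
                    if v is None or not _OPS[op](v, const):
                        ok = False
                        break
                elif v != pred:
                    ok = False
                    break
            if ok:
                out.append(el)
        out.sort(key=lambda e: e.id)
        return out

    # ------------------------------------------------------------------
    # serialization
    def to_dict(self) -> dict[str, Any]:
        """JSON-ready dict: nodes id/labels/props, edges id/src/dst/label/props."""
        return {
            "format": "physiograph-graph",
            "version": 1,
            "vertex_labels": sorted(self.vertex_labels),
            "edge_labels": sorted(self.edge_labels),
            "constraints": [
                {"kind": c.kind, "label": c.target_label, "property": c.property}
                for c in self.constraints
            ],
            "nodes": [
                {"id": n.id, "labels": sorted(n.labels), "props": n.props}
                for n in sorted(self._nodes.values(), key=lambda n: n.id)
            ],
            "edges": [
                {
                    "id": e.id,
                    "src": e.source,
                    "dst": e.target,
                    "label": e.label,
                    "props": e.props,
                }
                for e in sorted(self._edges.values(), key=lambda e: e.id)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PropertyGraph":
        g = cls(seed_schema=False)
        g.vertex_labels = set(d.get("vertex_labels", []))
        g.edge_labels = set(d.get("edge_labels", []))
        id_map: dict[int, int] = {}
        for nd in d["nodes"]:
            id_map[nd["id"]] = g.create_node(nd["labels"], nd["props"])
        for ed in d["edges"]:
            g.create_edge(id_map[ed["src"]], id_map[ed["dst"]], ed["label"], ed["props"])
        for cd in d.get("constraints", []):
            g.register_constraint(IntegrityConstraint(cd["kind"], cd["label"], cd["property"]))
        return g

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "PropertyGraph":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    # GraphML round trip: labels stored as a sorted '|' join, property maps
    # JSON-encoded into a single attribute so typed and list values survive.
    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.graph["vertex_labels"] = json.dumps(sorted(self.vertex_labels))
        g.graph["edge_labels"] = json.dumps(sorted(self.edge_labels))
        g.graph["constraints"] = json.dumps(
            [[c.kind, c.target_label, c.property] for c in self.constraints]
        )
        for n in self._nodes.values():
            g.add_node(n.id, labels="|".join(sorted(n.labels)),
                       props=json.dumps(n.props, sort_keys=True))
        for e in self._edges.values():
            g.add_edge(e.source, e.target, key=e.id, label=e.label,
                       props=json.dumps(e.props, sort_keys=True))
        return g

    def to_graphml(self, path: str) -> None:
        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def from_graphml(cls, path: str) -> "PropertyGraph":
        nxg = nx.read_graphml(path, force_multigraph=True)
        g = cls(seed_schema=False)
        g.vertex_labels = set(json.loads(nxg.graph.get("vertex_labels", "[]")))
        g.edge_labels = set(json.loads(nxg.graph.get("edge_labels", "[]")))
        id_map = {}
        for nid, data in sorted(nxg.nodes(data=True), key=lambda kv: int(kv[0])):
            id_map[nid] = g.create_node(
                data["labels"].split("|"), json.loads(data.get("props", "{}"))
            )
        edges = sorted(nxg.edges(keys=True, data=True), key=lambda t: int(t[2]))
        for u, v, _k, data in edges:
            g.create_edge(id_map[u], id_map[v], data["label"], json.loads(data.get("props", "{}")))
        for kind, lab, prop in json.loads(nxg.graph.get("constraints", "[]")):
            g.register_constraint(IntegrityConstraint(kind, lab, prop))
        return g

    def isomorphic_to(self, other: "PropertyGraph") -> bool:
        """Structural equality up to id renaming (labels + props + adjacency)."""

        def nmatch(a, b):
            return a["labels"] == b["labels"] and a["props"] == b["props"]

        def ematch(a, b):
            aa = sorted((d["label"], d["props"]) for d in a.values())
            bb = sorted((d["label"], d["props"]) for d in b.values())
            return aa == bb

        return nx.is_isomorphic(self.to_networkx(), other.to_networkx(),
                                node_match=nmatch, edge_match=ematch)
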