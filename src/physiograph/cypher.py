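"""openCypher text emission and replay.

The graph store is database-free, but every graph can be exported as an
openCypher ``CREATE`` script (plus ``CREATE CONSTRAINT`` DDL) loadable into
a Neo4j-compatible database.  Emission is deterministic and byte-stable:
nodes and edges are written in id order, labels and property keys sorted.

``replay_script`` parses exactly the dialect ``emit_create_script``
produces (it is not a general openCypher parser) and rebuilds an
isomorphic in-memory graph, which gives a text-only round trip that can be
verified without a live database.
"""

from __future__ import annotations

import json
import re
from typing import Any

from .errors import ValidationError
from .graph import IntegrityConstraint, PropertyGraph


def _quote_label(label: str) -> str:
    return label if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", label) else f"`{label}`"


def _literal(v: Any) -> str:
    """Cypher literal: JSON syntax matches for strings/numbers/bools/lists."""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float, str)):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_literal(x) for x in v) + "]"
    raise ValidationError(f"cannot emit property value of type {type(v)!r}")


def _props_map(props: dict[str, Any]) -> str:
    if not props:
        return ""
    inner = ", ".join(f"{k}: {_literal(props[k])}" for k in sorted(props))
    return " {" + inner + "}"


def emit_constraints(constraints: list[IntegrityConstraint]) -> str:
    """``CREATE CONSTRAINT`` DDL, one statement per registered constraint."""
    lines = []
    for c in constraints:
        lab = _quote_label(c.target_label)
        if c.kind == "uniqueness":
            lines.append(
                f"CREATE CONSTRAINT ON (n:{lab}) ASSERT (n.{c.property}) IS UNIQUE;"
            )
        else:
            lines.append(
                f"CREATE CONSTRAINT ON (n:{lab}) ASSERT EXISTS (n.{c.property});"
            )
    return "\n".join(lines) + ("\n" if lines else "")


def emit_create_script(graph: PropertyGraph) -> str:
    """Full graph as constraint DDL + CREATE statements in id order.

    Each node becomes ``CREATE (n<id>:Label {props});`` and each edge
    ``MATCH``+``CREATE`` on the node ids, mirroring elementary node/edge
    creation queries.  Node variables encode the original ids only for
    readability; replay renumbers.
    """
    out = [emit_constraints(graph.constraints)]
    for n in sorted(graph.nodes(), key=lambda n: n.id):
        labels = ":".join(_quote_label(l) for l in sorted(n.labels))
        out.append(f"CREATE (n{n.id}:{labels}{_props_map(n.props)});\n")
    for e in sorted(graph.edges(), key=lambda e: e.id):
        out.append(
            f"MATCH (a), (b) WHERE id(a) = {e.source} AND id(b) = {e.target} "
            f"CREATE (a)-[:{_quote_label(e.label)}{_props_map(e.props)}]->(b);\n"
        )
    return "".join(out)


_CONSTRAINT_RE = re.compile(
    r"CREATE CONSTRAINT ON \(n:`?([^`)]+)`?\) ASSERT "
    r"(?:\(n\.(\w+)\) IS UNIQUE|EXISTS \(n\.(\w+)\));"
)
_NODE_RE = re.compile(r"CREATE \(n(\d+):((?:`[^`]+`|\w+)(?::(?:`[^`]+`|\w+))*)( \{.*\})?\);")
_EDGE_RE = re.compile(
    r"MATCH \(a\), \(b\) WHERE id\(a\) = (\d+) AND id\(b\) = (\d+) "
    r"CREATE \(a\)-\[:(`[^`]+`|\w+)( \{.*\})?\]->\(b\);"
)


_KEY_RE = re.compile(r"\s*,?\s*(\w+): ")
_DECODER = json.JSONDecoder()


def _parse_props(text: str | None) -> dict[str, Any]:
    """Parse an emitted ``{key: literal, ...}`` map.

    Keys are bare identifiers; values are JSON literals except the bare
    booleans ``true``/``false`` which JSON also accepts, so each value is
    consumed with a raw JSON decode from its start offset.
    """
    if not text:
        return {}
    body = text.strip()[1:-1].strip()  # strip braces
    props: dict[str, Any] = {}
    pos = 0
    while pos < len(body):
        m = _KEY_RE.match(body, pos)
        if not m:
            raise ValidationError(f"unparseable property map near: {body[pos:]!r}")
        value, end = _DECODER.raw_decode(body, m.end())
        props[m.group(1)] = value
        pos = end
    return props


def replay_script(text: str) -> PropertyGraph:
    """Rebuild a graph from a script produced by :func:`emit_create_script`."""
    g = PropertyGraph(seed_schema=False)
    pending: list[IntegrityConstraint] = []
    id_map: dict[int, int] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        m = _CONSTRAINT_RE.fullmatch(line)
        if m:
            label, uniq, mand = m.groups()
            kind = "uniqueness" if uniq else "mandatory"
            pending.append(IntegrityConstraint(kind, label, uniq or mand))
            continue
        m = _NODE_RE.fullmatch(line)
        if m:
            old_id = int(m.group(1))
            labels = [l.strip("`") for l in re.findall(r"`[^`]+`|\w+", m.group(2))]
            for l in labels:
                g.register_vertex_label(l)
            id_map[old_id] = g.create_node(labels, _parse_props(m.group(3)))
            continue
        m = _EDGE_RE.fullmatch(line)
        if m:
            src, dst = int(m.group(1)), int(m.group(2))
            label = m.group(3).strip("`")
            g.register_edge_label(label)
            g.create_edge(id_map[src], id_map[dst], label, _parse_props(m.group(4)))
            continue
        raise ValidationError(f"unparseable script line: {line!r}")
    for c in pending:
        g.register_constraint(c)
    return g
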