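"""Per-experiment timeline and signal-value binding.

Every experiment owns a single timeline: an ordered linked list of
``Timestamp`` nodes (integer millisecond offsets from recording start)
chained by ``NEXT`` edges.  All signals of one experiment share this
timeline, so a timestamp node is created at most once per distinct offset
(enforced by the uniqueness constraint on ``Timestamp.value``) and may be
referenced by any number of signals.

Two binding shapes exist:

* timestamp signals — each sample refers to one moment; the sample's
  ``SignalValue`` node receives an ``IN_SEC`` edge from its timestamp;
* epoch signals (including electrode signals) — each value refers to an
  interval; ``START_IN_SEC`` and ``END_IN_SEC`` edges mark the bounds.

Epoch intervals are half-open ``[start, end)``; consecutive epochs share
their boundary timestamp node.  Sub-millisecond offsets are rejected, not
rounded.  The experiment node keeps a ``TAKES`` edge to the earliest
timestamp (re-pointed if an earlier one is later inserted).
"""

from __future__ import annotations

from bisect import bisect_left, insort
from typing import Any, Sequence

import numpy as np

from .errors import KindMismatchError, TimelineError
from .graph import PropertyGraph

_MEASURE_KIND_LABEL = {
    "timestamp": "TimestampMeasure",
    "epoch": "EpochMeasure",
    "electrode": "ElectrodeMeasure",
}


def _as_ms(value: Any) -> int:
    """Integer milliseconds; rejects negatives and sub-ms fractions."""
    if isinstance(value, float):
        if not value.is_integer():
            raise TimelineError(f"sub-millisecond offset {value!r} not representable")
        value = int(value)
    if not isinstance(value, (int, np.integer)):
        raise TimelineError(f"timestamp offset must be an integer, got {value!r}")
    if value < 0:
        raise TimelineError(f"negative timestamp offset {value}")
    return int(value)


class Timeline:
    """One experiment's view of the graph's Timestamp chain.

    The chain itself (and the value -> node index) is shared graph-wide,
    because Timestamp values are globally unique: signals of different
    experiments stored in one graph reference the same Timestamp nodes.
    Each Timeline tracks which values its experiment references so the
    experiment's TAKES edge always points at its own first timestamp.
    """

    def __init__(self, graph: PropertyGraph, experiment_node: int) -> None:
        self.graph = graph
        self.experiment_node = experiment_node
        if not hasattr(graph, "_ts_values"):
            graph._ts_values = []  # sorted ms values (graph-wide)
            graph._ts_index = {}  # ms value -> node id
        self._own_min: int | None = None  # earliest value this experiment uses

    # ------------------------------------------------------------------
    @property
    def _values(self) -> list[int]:
        return self.graph._ts_values

    @property
    def _index(self) -> dict[int, int]:
        return self.graph._ts_index

    @property
    def head(self) -> int | None:
        """Node id of this experiment's earliest timestamp (TAKES target)."""
        return self._index[self._own_min] if self._own_min is not None else None

    def values(self) -> list[int]:
        return list(self._values)

    def node_at(self, value_ms: int) -> int | None:
        return self._index.get(value_ms)

    def get_or_create_timestamp(self, value_ms: int) -> int:
        """Return the Timestamp node for ``value_ms``, splicing a new one
        into the shared chain if absent."""
        value_ms = _as_ms(value_ms)
        g = self.graph
        nid = self._index.get(value_ms)
        if nid is None:
            nid = g.create_node({"Timestamp"}, {"value": value_ms})
            pos = bisect_left(self._values, value_ms)
            pred = self._index[self._values[pos - 1]] if pos > 0 else None
            succ = self._index[self._values[pos]] if pos < len(self._values) else None
            if pred is not None and succ is not None:
                for e in g.out_edges(pred, "NEXT"):
                    if e.target == succ:
                        g.delete_edge(e.id)
            if pred is not None:
                g.create_edge(pred, nid, "NEXT")
            if succ is not None:
                g.create_edge(nid, succ, "NEXT")
            insort(self._values, value_ms)
            self._index[value_ms] = nid
        if self._own_min is None or value_ms < self._own_min:
            # new earliest moment for this experiment: re-point TAKES
            for e in g.out_edges(self.experiment_node, "TAKES"):
                g.delete_edge(e.id)
            g.create_edge(self.experiment_node, nid, "TAKES")
            self._own_min = value_ms
        return nid

    # ------------------------------------------------------------------
    def _measure_kind(self, measure: int) -> str:
        labels = self.graph.node(measure).labels
        for kind, lab in _MEASURE_KIND_LABEL.items():
            if lab in labels:
                return kind
        raise KindMismatchError(f"node {measure} is not a measure node")

    def attach_timestamp_values(
        self, measure: int, series: Sequence[tuple[int, Any]]
    ) -> int | None:
        """Bind a timestamp-signal series ``[(t_ms, value), ...]``.

        One SignalValue node per sample, chained by NEXT; the measure points
        at the first node via HAS_SIGNAL; each sample's timestamp points at
        it via IN_SEC.  ``value=None`` yields a node without a ``value``
        property (an explicitly missing sample).  Returns the first
        SignalValue node id, or None for an empty series.
        """
        if self._measure_kind(measure) != "timestamp":
            raise KindMismatchError("attach_timestamp_values needs a timestamp measure")
        series = [( _as_ms(t), v) for t, v in series]
        if any(b < a for (a, _), (b, _) in zip(series, series[1:])):
            raise TimelineError("timestamp series must be non-decreasing")
        g = self.graph
        prev = first = None
        for t_ms, value in series:
            props = {} if value is None else {"value": value}
            sv = g.create_node({"SignalValue"}, props)
            ts = self.get_or_create_timestamp(t_ms)
            g.create_edge(ts, sv, "IN_SEC")
            if prev is None:
                first = sv
                g.create_edge(measure, sv, "HAS_SIGNAL")
            else:
                g.create_edge(prev, sv, "NEXT")
            prev = sv
        return first

    def attach_epoch_values(
        self,
        measure: int,
        series: Sequence[tuple[int, int, Any]],
        *,
        allow_overlap: bool = False,
    ) -> int | None:
        """Bind an epoch-signal series ``[(start_ms, end_ms, payload), ...]``.

        A scalar payload is stored as the settled ``value`` property; a
        sequence payload is stored as the raw ``data`` array; None yields a
        value-less node.  Epochs must be ordered and non-overlapping unless
        ``allow_overlap`` (sliding windows), where only starts must strictly
        increase.  Returns the first SignalValue node id.
        """
        if self._measure_kind(measure) == "timestamp":
            raise KindMismatchError("attach_epoch_values needs an epoch/electrode measure")
        series = [(_as_ms(s), _as_ms(e), p) for s, e, p in series]
        last_start, last_end = -1, 0
        for start_ms, end_ms, _ in series:
            if start_ms >= end_ms:
                raise TimelineError(f"epoch [{start_ms}, {end_ms}) is empty or inverted")
            if start_ms <= last_start:
                raise TimelineError("epoch starts must strictly increase")
            if not allow_overlap and start_ms < last_end:
                raise TimelineError(
                    f"epoch [{start_ms}, {end_ms}) overlaps its predecessor"
                )
            last_start, last_end = start_ms, end_ms
        g = self.graph
        prev = first = None
        for start_ms, end_ms, payload in series:
            if payload is None:
                props: dict[str, Any] = {}
            elif isinstance(payload, (list, tuple, np.ndarray)):
                props = {"data": [float(x) for x in payload]}
            else:
                props = {"value": payload}
            sv = g.create_node({"SignalValue"}, props)
            g.create_edge(self.get_or_create_timestamp(start_ms), sv, "START_IN_SEC")
            g.create_edge(self.get_or_create_timestamp(end_ms), sv, "END_IN_SEC")
            if prev is None:
                first = sv
                g.create_edge(measure, sv, "HAS_SIGNAL")
            else:
                g.create_edge(prev, sv, "NEXT")
            prev = sv
        return first

    # ------------------------------------------------------------------
    def walk(self) -> list[int]:
        """Timestamp node ids in NEXT-chain order starting at the head."""
        out = []
        nid = self.head
        while nid is not None:
            out.append(nid)
            nxt = self.graph.successors(nid, "NEXT")
            nid = nxt[0] if nxt else None
        return out
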