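"""Retrieval layer: competency-question queries, tabular export, and
per-epoch feature-vector extraction.

Five canonical retrieval patterns are executed natively against the
in-memory graph:

* CQ1 — experiments having a recording whose channel of a given type
  carries a measure of a given name;
* CQ2 — the measure nodes themselves for such (channel type, measure name)
  pairs;
* CQ3 — the (start, end, value) time series of one signal, identified by
  ``signal_id`` (end is null for timestamp signals);
* CQ4 — a multivariate table joining several signals on their shared start
  timestamp (left join: a signal missing at a start yields null);
* CQ5 — CQ4 restricted to rows where designated signals' values satisfy
  comparison predicates (a null value fails every predicate).

Each query also has an openCypher rendering for replay against a live
graph database.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Any, Sequence

import pandas as pd

from .calculators import signal_chain
from .errors import EpochGridMismatchError, UnknownSignalError, ValidationError
from .graph import _OPS, PropertyGraph
from .schema import RecordingHandle, channel_measures

_MEASURE_LABELS = ("TimestampMeasure", "EpochMeasure", "ElectrodeMeasure")

#: Metadata columns of the export table (the "+7" of the n+7 contract).
EXPORT_METADATA_COLUMNS = (
    "experiment",
    "source_database",
    "participant",
    "channel_type",
    "measure_name",
    "epoch_start",
    "epoch_end",
)


@dataclass
class SignalTable:
    """Ordered tabular signal data; rows sorted by start time."""

    columns: list[str]
    rows: list[tuple]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.columns)

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(self.columns)
            for row in self.rows:
                w.writerow(["" if v is None else v for v in row])


@dataclass(frozen=True)
class Restriction:
    """Predicate over one signal's per-row value: ``property op constant``."""

    signal_id: int
    property: str = "value"
    operator: str = "="
    constant: Any = None

    def __post_init__(self) -> None:
        if self.operator not in _OPS:
            raise ValidationError(f"unknown operator {self.operator!r}")

    def test(self, value: Any) -> bool:
        if value is None:
            return False
        return _OPS[self.operator](value, self.constant)


# ----------------------------------------------------------------------
# traversal helpers


def _is_measure(graph: PropertyGraph, nid: int) -> bool:
    return bool(graph.node(nid).labels & set(_MEASURE_LABELS))


def find_measure(graph: PropertyGraph, signal_id: int) -> int:
    hits = [
        n.id
        for n in graph.nodes()
        if _is_measure(graph, n.id) and n.props.get("signal_id") == signal_id
    ]
    if not hits:
        raise UnknownSignalError(f"no measure with signal_id {signal_id}")
    return hits[0]


def _sv_times(graph: PropertyGraph, sv: int) -> tuple[int | None, int | None]:
    """(start, end) ms of one SignalValue; IN_SEC gives (t, None)."""
    for lab, as_pair in (("IN_SEC", False), ("START_IN_SEC", True)):
        pred = graph.predecessors(sv, lab)
        if pred:
            start = graph.node(pred[0]).props["value"]
            if not as_pair:
                return start, None
            endp = graph.predecessors(sv, "END_IN_SEC")
            return start, (graph.node(endp[0]).props["value"] if endp else None)
    return None, None


def _sv_value(graph: PropertyGraph, sv: int) -> Any:
    props = graph.node(sv).props
    if "value" in props:
        return props["value"]
    return props.get("data")


# ----------------------------------------------------------------------
# CQ1 / CQ2


def find_experiments(
    graph: PropertyGraph, channel_type: str, measure_name: str
) -> list[int]:
    """CQ1: experiment node ids reachable as
    Experiment <-PART_OF- Recording -HAS_RECORDING_TYPE-> Channel{type}
    -HAS_MEASURE-> measure{name}."""
    out = set()
    for ch in graph.match("Channel", {"type": channel_type}):
        names = {
            graph.node(m).props.get("name")
            for m in graph.successors(ch.id, "HAS_MEASURE")
        }
        if measure_name not in names:
            continue
        for rec in graph.predecessors(ch.id, "HAS_RECORDING_TYPE"):
            for exp in graph.successors(rec, "PART_OF"):
                if "Experiment" in graph.node(exp).labels:
                    out.add(exp)
    return sorted(out)


def find_signals(
    graph: PropertyGraph, channel_type: str, measure_name: str
) -> list[int]:
    """CQ2: measure node ids under channels of the given type with the
    given measure name."""
    out = []
    for ch in graph.match("Channel", {"type": channel_type}):
        for m in graph.successors(ch.id, "HAS_MEASURE"):
            if graph.node(m).props.get("name") == measure_name:
                out.append(m)
    return sorted(out)


# ----------------------------------------------------------------------
# CQ3 / CQ4 / CQ5


def get_time_series(graph: PropertyGraph, signal_id: int) -> SignalTable:
    """CQ3: (start_ms, end_ms, value) rows of one signal in chain order."""
    measure = find_measure(graph, signal_id)
    rows = []
    for sv in signal_chain(graph, measure):
        start, end = _sv_times(graph, sv)
        rows.append((start, end, _sv_value(graph, sv)))
    return SignalTable(["start_ms", "end_ms", "value"], rows)


def get_multivariate(
    graph: PropertyGraph,
    signal_ids: Sequence[int],
    restrictions: Sequence[Restriction] | None = None,
) -> SignalTable:
    """CQ4/CQ5: join signals on shared start timestamps; the first id is
    the anchor defining the row set."""
    if not signal_ids:
        raise ValidationError("need at least one signal id")
    anchor, *others = signal_ids

    def start_map(sid: int) -> tuple[list[tuple[int, int]], dict[int, int]]:
        measure = find_measure(graph, sid)
        ordered, by_start = [], {}
        for sv in signal_chain(graph, measure):
            start, end = _sv_times(graph, sv)
            ordered.append((start, end, sv))
            by_start[start] = sv
        return ordered, by_start

    anchor_rows, _ = start_map(anchor)
    other_maps = {sid: start_map(sid)[1] for sid in others}
    restr_maps = {
        r.signal_id: start_map(r.signal_id)[1] for r in (restrictions or [])
    }
    columns = ["start_ms", "end_ms"] + [f"signal_{sid}" for sid in signal_ids]
    rows = []
    for start, end, sv in anchor_rows:
        if restrictions:
            ok = True
            for r in restrictions:
                rsv = restr_maps[r.signal_id].get(start)
                value = (
                    graph.node(rsv).props.get(r.property) if rsv is not None else None
                )
                if not r.test(value):
                    ok = False
                    break
            if not ok:
                continue
        values = [_sv_value(graph, sv)]
        for sid in others:
            osv = other_maps[sid].get(start)
            values.append(_sv_value(graph, osv) if osv is not None else None)
        rows.append((start, end, *values))
    return SignalTable(columns, rows)


# ----------------------------------------------------------------------
# tabular export (n + 7 columns)


def export_table(
    graph: PropertyGraph, channel_type: str, value_props: Sequence[str]
) -> SignalTable:
    """Epoch-signal export for a channel type: one row per SignalValue of
    every electrode measure, ``len(value_props)`` value columns plus the 7
    metadata columns (experiment, source_database, participant,
    channel_type, measure_name, epoch_start, epoch_end)."""
    columns = list(EXPORT_METADATA_COLUMNS[:5]) + list(value_props) + list(
        EXPORT_METADATA_COLUMNS[5:]
    )
    rows = []
    for ch in graph.match("Channel", {"type": channel_type}):
        recs = graph.predecessors(ch.id, "HAS_RECORDING_TYPE")
        exp_name = part_id = source = None
        if recs:
            rec = recs[0]
            exps = graph.successors(rec, "PART_OF")
            if exps:
                ep = graph.node(exps[0]).props
                exp_name = ep.get("id", ep.get("name"))
            parts = graph.predecessors(rec, "TAKES_PART_IN")
            if parts:
                pp = graph.node(parts[0]).props
                part_id = pp.get("id", pp.get("user_id"))
            source = graph.node(rec).props.get("source")
        for m in graph.successors(ch.id, "HAS_MEASURE"):
            mnode = graph.node(m)
            if "ElectrodeMeasure" not in mnode.labels:
                continue
            for sv in signal_chain(graph, m):
                start, end = _sv_times(graph, sv)
                props = graph.node(sv).props
                rows.append(
                    (
                        exp_name,
                        source,
                        part_id,
                        channel_type,
                        mnode.props.get("name"),
                        *[props.get(p) for p in value_props],
                        start,
                        end,
                    )
                )
    rows.sort(key=lambda r: (str(r[4]), r[-2] if r[-2] is not None else -1))
    return SignalTable(columns, rows)


# ----------------------------------------------------------------------
# feature vectors


BAND_ORDER = ("delta", "theta", "alpha", "beta", "gamma")
ECG_STAT_ORDER = tuple(
    f"{pre}_{s}" for pre in ("HRV", "IBI") for s in ("min", "max", "var", "mean")
)
GSR_STAT_ORDER = ("GSR_min", "GSR_max", "GSR_avg", "no_of_peaks")


@dataclass
class FeatureConfig:
    """Deterministic feature ordering for vector extraction.

    ``eeg_order`` fixes the electrode sequence (defaults to measure-name
    sort); the MI block iterates electrode pairs lexicographically.  When
    ``valence_signal_id``/``arousal_signal_id`` are set a quadrant label
    column (HVHA/HVLA/LVHA/LVLA from the value signs) is appended.
    """

    eeg_order: list[str] | None = None
    ecg_order: list[str] = field(default_factory=lambda: ["left", "right"])
    valence_signal_id: int | None = None
    arousal_signal_id: int | None = None


def quadrant_label(valence: float, arousal: float) -> str:
    v = "H" if valence > 0 else "L"
    a = "H" if arousal > 0 else "L"
    return f"{v}V{a}A"


def _channel_of_type(graph: PropertyGraph, handle: RecordingHandle, ch_type: str) -> int | None:
    for ch in handle.channel_nodes:
        if graph.node(ch).props.get("type") == ch_type:
            return ch
    return None


def extract_feature_vectors(
    graph: PropertyGraph,
    handle: RecordingHandle,
    config: FeatureConfig = FeatureConfig(),
) -> tuple[list[list[Any]], list[str]]:
    """Per-epoch feature vectors for one recording.

    Per epoch, the concatenation of: the 5 band powers for each EEG
    electrode (in ``eeg_order``); the 8 HRV/IBI statistics for each ECG
    electrode; the 4 GSR peak statistics; then the ``mi`` property for each
    EEG electrode pair in lexicographic order.  For the full montage (14
    EEG, 2 ECG, 1 GSR) this is 5*14 + 8*2 + 4 = 90 node-level values plus
    14*13/2 = 91 edge-level values: 181 features.

    Missing calculator outputs become None entries.  Returns (rows,
    column_names); rows gain a trailing quadrant-label column when the
    config designates valence/arousal signals.
    """
    blocks: list[tuple[str, int, list[int]]] = []  # (type, channel, measures)
    for ch_type in ("EEG", "ECG", "GSR"):
        ch = _channel_of_type(graph, handle, ch_type)
        if ch is None:
            continue
        measures = [
            m
            for m in channel_measures(graph, ch)
            if "ElectrodeMeasure" in graph.node(m).labels
        ]
        order = config.eeg_order if ch_type == "EEG" else (
            config.ecg_order if ch_type == "ECG" else None
        )
        if order:
            by_name = {graph.node(m).props.get("name"): m for m in measures}
            missing = [n for n in order if n not in by_name]
            if missing:
                raise ValidationError(f"{ch_type} electrodes not found: {missing}")
            measures = [by_name[n] for n in order]
        else:
            measures.sort(key=lambda m: str(graph.node(m).props.get("name")))
        if measures:
            blocks.append((ch_type, ch, measures))

    chains = {
        m: signal_chain(graph, m) for _, _, ms in blocks for m in ms
    }
    grids = {
        m: tuple(_sv_times(graph, sv) for sv in chain)
        for m, chain in chains.items()
    }
    if len(set(grids.values())) > 1:
        raise EpochGridMismatchError("channels are not epoched on the same grid")
    if not chains:
        return [], []
    some_grid = next(iter(grids.values()))
    n_epochs = len(some_grid)

    stat_order = {"EEG": BAND_ORDER, "ECG": ECG_STAT_ORDER, "GSR": GSR_STAT_ORDER}
    columns: list[str] = []
    for ch_type, _, measures in blocks:
        for m in measures:
            name = graph.node(m).props.get("name")
            columns += [f"{name}_{stat}" for stat in stat_order[ch_type]]
    eeg_measures = next((ms for t, _, ms in blocks if t == "EEG"), [])
    eeg_names = [graph.node(m).props.get("name") for m in eeg_measures]
    pair_index = []
    for i in range(len(eeg_measures)):
        for j in range(i + 1, len(eeg_measures)):
            a, b = sorted([i, j], key=lambda k: str(eeg_names[k]))
            pair_index.append((a, b))
    pair_index.sort(key=lambda ab: (str(eeg_names[ab[0]]), str(eeg_names[ab[1]])))
    columns += [f"mi_{eeg_names[a]}_{eeg_names[b]}" for a, b in pair_index]

    label_maps = {}
    for which, sid in (
        ("valence", config.valence_signal_id),
        ("arousal", config.arousal_signal_id),
    ):
        if sid is not None:
            measure = find_measure(graph, sid)
            label_maps[which] = {
                _sv_times(graph, sv)[0]: graph.node(sv).props.get("value")
                for sv in signal_chain(graph, measure)
            }
    with_labels = len(label_maps) == 2
    if with_labels:
        columns = columns + ["label"]

    rows = []
    for ei in range(n_epochs):
        row: list[Any] = []
        for ch_type, _, measures in blocks:
            for m in measures:
                props = graph.node(chains[m][ei]).props
                row += [props.get(stat) for stat in stat_order[ch_type]]
        # MI block: the epoch's INFLUENCE_ON edges between EEG value nodes
        mi_lookup = {}
        for i, m in enumerate(eeg_measures):
            sv = chains[m][ei]
            for e in graph.out_edges(sv, "INFLUENCE_ON"):
                mi_lookup[(sv, e.target)] = e.props.get("mi")
        for a, b in pair_index:
            sva, svb = chains[eeg_measures[a]][ei], chains[eeg_measures[b]][ei]
            row.append(mi_lookup.get((sva, svb), mi_lookup.get((svb, sva))))
        if with_labels:
            start = some_grid[ei][0]
            v = label_maps["valence"].get(start)
            a_ = label_maps["arousal"].get(start)
            row.append(quadrant_label(v, a_) if v is not None and a_ is not None else None)
        rows.append(row)
    return rows, columns


def feature_table(
    graph: PropertyGraph, handle: RecordingHandle, config: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    rows, columns = extract_feature_vectors(graph, handle, config)
    return pd.DataFrame(rows, columns=columns)


# ----------------------------------------------------------------------
# openCypher renderings of the competency questions


def cq1_cypher(channel_type: str, measure_name: str) -> str:
    return (
        "MATCH (e:Experiment)<-[:PART_OF]-()-[:HAS_RECORDING_TYPE]->"
        f"(c:Channel {{type:'{channel_type}'}})-[:HAS_MEASURE]->"
        f"(m {{name:'{measure_name}'}})\nRETURN e\n"
    )


def cq2_cypher(channel_type: str, measure_name: str) -> str:
    return (
        f"MATCH (c:Channel {{type:'{channel_type}'}})-[:HAS_MEASURE]->"
        f"(m {{name:'{measure_name}'}}) RETURN m\n"
    )


def cq3_cypher(signal_id: int) -> str:
    return (
        f"MATCH (m {{signal_id:{signal_id}}})-[:HAS_SIGNAL]->"
        "(s1_root:SignalValue)-[:NEXT*0..]->(s1:SignalValue)"
        "<-[:IN_SEC|START_IN_SEC]-(startTimestamp:Timestamp)\n"
        "OPTIONAL MATCH (s1:SignalValue)<-[:END_IN_SEC]-(endTimestamp:Timestamp)\n"
        "RETURN startTimestamp.value, endTimestamp.value, s1.value\n"
    )


def cq4_cypher(signal_ids: Sequence[int]) -> str:
    anchor, *others = signal_ids
    lines = [
        f"MATCH (m1 {{signal_id:{anchor}}})-[:HAS_SIGNAL]->"
        "(s1_root:SignalValue)-[:NEXT*0..]->(s1:SignalValue)"
        "<-[:IN_SEC|START_IN_SEC]-(startTimestamp:Timestamp)",
        "OPTIONAL MATCH (s1:SignalValue)<-[:END_IN_SEC]-(endTimestamp:Timestamp)",
    ]
    for i, sid in enumerate(others, start=2):
        lines.append(
            f"OPTIONAL MATCH (m{i} {{signal_id:{sid}}})-[:HAS_SIGNAL]->"
            f"(s{i}_root:SignalValue)-[:NEXT*0..]->(s{i}:SignalValue)"
            "<-[:IN_SEC|START_IN_SEC]-(startTimestamp)"
        )
    returns = ["startTimestamp.value", "endTimestamp.value"] + [
        f"s{i}.value" for i in range(1, len(signal_ids) + 1)
    ]
    lines.append("RETURN " + ", ".join(returns))
    return "\n".join(lines) + "\n"


def cq5_cypher(signal_ids: Sequence[int], restrictions: Sequence[Restriction]) -> str:
    anchor, *others = signal_ids
    lines = [
        f"MATCH (m1 {{signal_id:{anchor}}})-[:HAS_SIGNAL]->"
        "(s1_root:SignalValue)-[:NEXT*0..]->(s1:SignalValue)"
        "<-[:IN_SEC|START_IN_SEC]-(startTimestamp:Timestamp),"
    ]
    for i, r in enumerate(restrictions, start=1):
        lines.append(
            f"      (r{i} {{signal_id:{r.signal_id}}})-[:HAS_SIGNAL]->"
            f"(rs{i}_root:SignalValue)-[:NEXT*0..]->(rs{i}:SignalValue)"
            "<-[:IN_SEC|START_IN_SEC]-(startTimestamp),"
        )
    lines[-1] = lines[-1].rstrip(",")
    where = " AND ".join(
        f"rs{i}.{r.property} {'=' if r.operator == '==' else r.operator} {r.constant!r}"
        for i, r in enumerate(restrictions, start=1)
    )
    lines.append(f"WHERE {where}")
    lines.append("OPTIONAL MATCH (s1:SignalValue)<-[:END_IN_SEC]-(endTimestamp:Timestamp)")
    for i, sid in enumerate(others, start=2):
        lines.append(
            f"OPTIONAL MATCH (m{i} {{signal_id:{sid}}})-[:HAS_SIGNAL]->"
            f"(s{i}_root:SignalValue)-[:NEXT*0..]->(s{i}:SignalValue)"
            "<-[:IN_SEC|START_IN_SEC]-(startTimestamp)"
        )
    returns = ["startTimestamp.value", "endTimestamp.value"] + [
        f"s{i}.value" for i in range(1, len(signal_ids) + 1)
    ]
    lines.append("RETURN " + ", ".join(returns))
    return "\n".join(lines) + "\n"
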