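"""Typed constructors for the session schema.

Wires the contextual-information side of the graph: an ``Experiment`` node,
``Participant`` nodes, per-participation ``Recording`` nodes, and
``Channel`` nodes.  A Channel belongs to one Recording (it represents the
recorded channel of that recording, not the channel in general) and carries
one or more measure nodes (``TimestampMeasure`` / ``EpochMeasure`` /
``ElectrodeMeasure``) that the signal-value chains hang from.

Emotion-annotation streams (e.g. Russell valence/arousal or Ekman state
estimates) are ordinary timestamp/epoch measures on a dedicated channel
(``type="Annotation"`` by convention); they get no special node type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

from .errors import ValidationError
from .graph import PropertyGraph
from .timeline import Timeline

MEASURE_KINDS = ("timestamp", "epoch", "electrode")

_KIND_LABEL = {
    "timestamp": "TimestampMeasure",
    "epoch": "EpochMeasure",
    "electrode": "ElectrodeMeasure",
}


@dataclass
class ExperimentSpec:
    name: str
    activity: str | None = None
    place: str | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("experiment name must be non-empty")


@dataclass
class ParticipantSpec:
    user_id: int
    gender: str | None = None
    age: int | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.user_id < 0:
            raise ValidationError("user_id must be >= 0")


@dataclass
class ChannelSpec:
    type: str
    recording_standard: str | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.type:
            raise ValidationError("channel type is mandatory")


@dataclass
class MeasureSpec:
    """Declaration of one signal series.

    ``kind='electrode'`` measures are named by electrode placement (10-20
    position for EEG, left/right for ECG, "GSR" for the single GSR sensor);
    for the other kinds ``datatype`` and ``range`` describe the value domain
    (range as a string "low..high inclusive", parseable via
    :func:`parse_range`).
    """

    signal_id: int
    kind: str
    name: str
    datatype: str | None = None
    range: str | None = None
    fs_hz: float | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MEASURE_KINDS:
            raise ValidationError(f"measure kind must be one of {MEASURE_KINDS}")
        if not self.name:
            raise ValidationError("measure name must be non-empty")
        if self.kind != "electrode" and (self.datatype is None or self.range is None):
            raise ValidationError(
                "timestamp/epoch measures need datatype and range"
            )


def parse_range(text: str) -> tuple[float, float]:
    """Parse a ``"low..high inclusive"`` range string into numeric bounds."""
    body = text.replace("inclusive", "").strip()
    low, high = body.split("..")
    return float(low), float(high)


@dataclass
class RecordingHandle:
    """Ids of one recording's node neighbourhood plus its timeline."""

    recording_node: int
    experiment_node: int
    participant_node: int
    channel_nodes: list[int]
    timeline: Timeline


def create_experiment(
    graph: PropertyGraph, spec: ExperimentSpec | str
) -> tuple[int, Timeline]:
    """Create an Experiment node and its (initially empty) timeline.

    The TAKES edge to the first Timestamp node appears when the timeline
    gets its first timestamp.
    """
    if isinstance(spec, str):
        spec = ExperimentSpec(spec)
    props: dict[str, Any] = {"name": spec.name, **spec.extra}
    if spec.activity is not None:
        props["activity"] = spec.activity
    if spec.place is not None:
        props["place"] = spec.place
    nid = graph.create_node({"Experiment"}, props)
    return nid, Timeline(graph, nid)


def create_participant(graph: PropertyGraph, spec: ParticipantSpec | int) -> int:
    if isinstance(spec, int):
        spec = ParticipantSpec(spec)
    props: dict[str, Any] = {"user_id": spec.user_id, **spec.extra}
    if spec.gender is not None:
        props["gender"] = spec.gender
    if spec.age is not None:
        props["age"] = spec.age
    return graph.create_node({"Participant"}, props)


def create_recording(
    graph: PropertyGraph,
    experiment_node: int,
    participant_node: int,
    channels: Sequence[ChannelSpec],
    timeline: Timeline,
) -> RecordingHandle:
    """Create a Recording with its channels and wire the schema edges.

    Edges: Recording-PART_OF->Experiment, Participant-TAKES_PART_IN->Recording,
    Recording-HAS_RECORDING_TYPE->Channel per channel.
    """
    if not channels:
        raise ValidationError("a recording needs at least one channel")
    for node, what in ((experiment_node, "Experiment"), (participant_node, "Participant")):
        if not graph.has_node(node) or what not in graph.node(node).labels:
            raise ValidationError(f"node {node} is not an existing {what} node")
    rec = graph.create_node({"Recording"}, {})
    graph.create_edge(rec, experiment_node, "PART_OF")
    graph.create_edge(participant_node, rec, "TAKES_PART_IN")
    channel_nodes = []
    for ch in channels:
        props: dict[str, Any] = {"type": ch.type, **ch.extra}
        if ch.recording_standard is not None:
            props["recording_standard"] = ch.recording_standard
        cid = graph.create_node({"Channel"}, props)
        graph.create_edge(rec, cid, "HAS_RECORDING_TYPE")
        channel_nodes.append(cid)
    return RecordingHandle(rec, experiment_node, participant_node, channel_nodes, timeline)


def attach_measures(
    graph: PropertyGraph, channel: int, specs: Sequence[MeasureSpec]
) -> list[int]:
    """Create one measure node per spec and HAS_MEASURE edges from the channel."""
    if not graph.has_node(channel) or "Channel" not in graph.node(channel).labels:
        raise ValidationError(f"node {channel} is not a Channel node")
    ids = []
    for spec in specs:
        props: dict[str, Any] = {
            "signal_id": spec.signal_id,
            "name": spec.name,
            **spec.extra,
        }
        if spec.datatype is not None:
            props["datatype"] = spec.datatype
        if spec.range is not None:
            props["range"] = spec.range
        if spec.fs_hz is not None:
            props["fs"] = float(spec.fs_hz)
        mid = graph.create_node({_KIND_LABEL[spec.kind]}, props)
        graph.create_edge(channel, mid, "HAS_MEASURE")
        ids.append(mid)
    return ids


def channel_measures(graph: PropertyGraph, channel: int) -> list[int]:
    """Measure node ids attached to a channel, in creation order."""
    return graph.successors(channel, "HAS_MEASURE")
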