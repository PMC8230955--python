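"""Closed-form graph sizing and disk-size estimation.

For a raw signal of ``f`` Hz lasting ``t`` seconds split into ``m``
electrode measures:

* fixed epochs of ``t_e`` samples: ``s = floor(f*t / t_e)`` value nodes
  per measure, ``S = m*s`` total (an epoch of ``x`` seconds is ``t_e =
  f*x`` samples — expressing the epoch length in samples, like ``w`` and
  ``o`` below, is what makes the closed form exact);
* sliding windows of ``w`` samples with ``o`` overlap:
  ``s = floor((f*t - w) / (w - o))``;
* relationship calculators with no threshold build the complete graph per
  epoch: ``r = m*(m-1)/2`` edges per epoch, ``R = s*r`` total.

The disk model uses the fixed record lengths of a popular graph database:
15 B per node, 34 B per relationship, 41 B per property record, plus a
128 B value record for each string-valued and each array-valued property
(taken as additive to the 41 B property record).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .graph import PropertyGraph

NODE_BYTES = 15
RELATIONSHIP_BYTES = 34
PROPERTY_BYTES = 41
STRING_VALUE_BYTES = 128
ARRAY_VALUE_BYTES = 128


@dataclass(frozen=True)
class SizingParams:
    """Signal-shape parameters; set exactly one of ``te`` or ``(w, o)``.

    ``te`` is the fixed epoch length in samples; ``w``/``o`` are the
    sliding-window length and overlap in samples.
    """

    f: float
    t: float
    m: int
    te: float | None = None
    w: int | None = None
    o: int | None = None

    def __post_init__(self) -> None:
        fixed, sliding = self.te is not None, self.w is not None
        if fixed == sliding:
            raise ValidationError("set exactly one of te or (w, o)")
        if fixed and self.te <= 0:
            raise ValidationError("te must be positive")
        if sliding:
            o = self.o if self.o is not None else 0
            if not 0 <= o < self.w:
                raise ValidationError("need 0 <= o < w (w == o divides by zero)")
        if self.f <= 0 or self.t < 0 or self.m < 0:
            raise ValidationError("f must be positive; t, m non-negative")


@dataclass(frozen=True)
class SizingReport:
    s: int  # SignalValue nodes per measure
    S: int  # total SignalValue nodes (m*s)
    r: int  # INFLUENCE_ON edges per epoch (m*(m-1)/2)
    R: int  # total INFLUENCE_ON edges (s*r)


def predict(params: SizingParams) -> SizingReport:
    """Evaluate the closed-form node/edge counts."""
    ft = params.f * params.t
    if params.te is not None:
        s = int(ft // params.te)
    else:
        o = params.o if params.o is not None else 0
        s = int((ft - params.w) // (params.w - o)) if ft >= params.w else 0
    r = params.m * (params.m - 1) // 2
    return SizingReport(s=s, S=params.m * s, r=r, R=s * r)


def count_properties(graph: PropertyGraph) -> tuple[int, int, int]:
    """(total property records, string-valued, array-valued) in a graph."""
    total = strings = arrays = 0
    for el in list(graph.nodes()) + list(graph.edges()):
        for v in el.props.values():
            total += 1
            if isinstance(v, str):
                strings += 1
            elif isinstance(v, (list, tuple)):
                arrays += 1
    return total, strings, arrays


def estimate_disk(
    n_nodes: int,
    n_relationships: int,
    n_properties: int = 0,
    n_string_props: int = 0,
    n_array_props: int = 0,
) -> int:
    """Bytes needed under the fixed-record-length disk model."""
    return (
        NODE_BYTES * n_nodes
        + RELATIONSHIP_BYTES * n_relationships
        + PROPERTY_BYTES * n_properties
        + STRING_VALUE_BYTES * n_string_props
        + ARRAY_VALUE_BYTES * n_array_props
    )


def estimate_disk_graph(graph: PropertyGraph) -> int:
    """Disk-model bytes for an actual in-memory graph."""
    props, strings, arrays = count_properties(graph)
    return estimate_disk(graph.n_nodes, graph.n_edges, props, strings, arrays)


@dataclass(frozen=True)
class VerificationReport:
    predicted_nodes: int
    actual_nodes: int
    predicted_edges: int
    actual_edges: int

    @property
    def exact(self) -> bool:
        return (
            self.predicted_nodes == self.actual_nodes
            and self.predicted_edges == self.actual_edges
        )


def count_signal_elements(graph: PropertyGraph) -> tuple[int, int]:
    """(SignalValue node count, INFLUENCE_ON edge count) of a graph."""
    nodes = sum(1 for n in graph.nodes() if "SignalValue" in n.labels)
    edges = sum(1 for e in graph.edges() if e.label == "INFLUENCE_ON")
    return nodes, edges


def verify(graph: PropertyGraph, params: SizingParams) -> VerificationReport:
    """Compare predicted vs actual signal-node / influence-edge counts."""
    rep = predict(params)
    nodes, edges = count_signal_elements(graph)
    return VerificationReport(rep.S, nodes, rep.R, edges)
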