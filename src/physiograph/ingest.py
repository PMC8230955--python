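"""Raw-signal ingestion: preprocessing, epoching, and bulk import.

Raw sampled signals (constant sampling rate ``f`` Hz, duration ``t`` s)
become timeline-bound graph signals here.  Fixed epoching of length ``t_e``
seconds yields ``s = floor(f*t / t_e)`` epochs per measure; the sliding
window variant with window ``w`` and overlap ``o`` (both in samples) yields
``s = floor((f*t - w) / (w - o))`` windows.  Trailing partial samples are
discarded.

Default preprocessing per channel type is a zero-phase band-pass
(forward-backward Butterworth): EEG 0.5-45 Hz, ECG 0.5-40 Hz, GSR low-pass
1 Hz; resampling is off by default.  All of it is configurable per measure.

File dialects (all plain CSV):

* raw rows ``index,value`` with the sampling rate declared in the manifest;
* timestamp rows ``t_ms,value`` (empty value = missing sample);
* epoch rows ``start_ms,end_ms,payload`` where payload is either a scalar
  or a ``;``-joined sample array.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml
from scipy import signal as sps

from .errors import EpochGridMismatchError, ValidationError
from .graph import PropertyGraph
from .schema import (
    ChannelSpec,
    ExperimentSpec,
    MeasureSpec,
    ParticipantSpec,
    RecordingHandle,
    attach_measures,
    create_experiment,
    create_participant,
    create_recording,
)
from .timeline import Timeline

DEFAULT_BANDPASS = {
    "EEG": (0.5, 45.0),
    "ECG": (0.5, 40.0),
    "GSR": (None, 1.0),  # low-pass only
}


@dataclass
class RawSignal:
    """A regularly sampled series plus its provenance."""

    samples: np.ndarray
    fs: float
    channel_type: str = ""
    measure_name: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class EpochingConfig:
    """Fixed epochs of ``epoch_s`` seconds, or a sliding window of ``w``
    samples with ``o`` samples of overlap."""

    epoch_s: float | None = None
    w: int | None = None
    o: int | None = None

    def __post_init__(self) -> None:
        fixed = self.epoch_s is not None
        sliding = self.w is not None
        if fixed == sliding:
            raise ValidationError("set exactly one of epoch_s or (w, o)")
        if fixed and self.epoch_s <= 0:
            raise ValidationError("epoch_s must be positive")
        if sliding:
            if self.o is None:
                self.o = 0
            if not (0 <= self.o < self.w):
                raise ValidationError("need 0 <= o < w")

    @property
    def mode(self) -> str:
        return "fixed" if self.epoch_s is not None else "sliding"


@dataclass
class PreprocessConfig:
    bpf_low_hz: float | None = None
    bpf_high_hz: float | None = None
    resample_hz: float | None = None
    order: int = 4

    def __post_init__(self) -> None:
        if (
            self.bpf_low_hz is not None
            and self.bpf_high_hz is not None
            and self.bpf_low_hz >= self.bpf_high_hz
        ):
            raise ValidationError("bpf_low_hz must be < bpf_high_hz")


def epochize(
    sig: RawSignal, cfg: EpochingConfig
) -> list[tuple[int, int, np.ndarray]]:
    """Cut a raw signal into ``(start_ms, end_ms, samples)`` epochs.

    Fixed mode windows are disjoint and consecutive; sliding-mode windows
    advance by ``w - o`` samples and may overlap.  May return an empty list
    when the signal is shorter than one window.
    """
    n = len(sig.samples)
    out = []
    if cfg.mode == "fixed":
        spe = int(round(sig.fs * cfg.epoch_s))
        if spe <= 0:
            raise ValidationError("epoch shorter than one sample")
        count = n // spe
        starts = [i * spe for i in range(count)]
        width = spe
    else:
        w, o = cfg.w, cfg.o
        step = w - o
        count = (n - w) // step if n >= w else 0
        starts = [i * step for i in range(count)]
        width = w
    for s0 in starts:
        start_ms = int(round(s0 / sig.fs * 1000))
        end_ms = int(round((s0 + width) / sig.fs * 1000))
        out.append((start_ms, end_ms, sig.samples[s0 : s0 + width]))
    return out


def predicted_epoch_count(n_samples: int, fs: float, cfg: EpochingConfig) -> int:
    """Closed-form epoch count for a signal of ``n_samples`` at ``fs``."""
    if cfg.mode == "fixed":
        return n_samples // int(round(fs * cfg.epoch_s))
    step = cfg.w - cfg.o
    return max((n_samples - cfg.w) // step, 0) if n_samples >= cfg.w else 0


def preprocess(sig: RawSignal, cfg: PreprocessConfig) -> RawSignal:
    """Band-pass filter then resample; an all-null config is the identity."""
    x, fs = sig.samples, sig.fs
    nyq = fs / 2
    low, high = cfg.bpf_low_hz, cfg.bpf_high_hz
    if (low is not None and low >= nyq) or (high is not None and high >= nyq):
        raise ValidationError("band edge at or above Nyquist")
    if low is not None or high is not None:
        if low is not None and high is not None:
            sos = sps.butter(cfg.order, [low, high], btype="bandpass", fs=fs, output="sos")
        elif high is not None:
            sos = sps.butter(cfg.order, high, btype="lowpass", fs=fs, output="sos")
        else:
            sos = sps.butter(cfg.order, low, btype="highpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    out_fs = fs
    if cfg.resample_hz is not None and cfg.resample_hz != fs:
        ratio = Fraction(cfg.resample_hz / fs).limit_denominator(1000)
        x = sps.resample_poly(x, ratio.numerator, ratio.denominator)
        out_fs = cfg.resample_hz
    return RawSignal(x, out_fs, sig.channel_type, sig.measure_name)


def _epoch_grid(series: Sequence[tuple[int, int, Any]]) -> tuple[tuple[int, int], ...]:
    return tuple((s, e) for s, e, _ in series)


def import_signals(
    graph: PropertyGraph,
    rec: RecordingHandle,
    channel: int,
    signal_lists: Sequence[tuple[MeasureSpec, Sequence]],
    *,
    sliding: bool = False,
) -> list[int]:
    """Create measure nodes for one channel and bind their value series.

    Timestamp-kind series are ``[(t_ms, value), ...]``; epoch/electrode-kind
    series are ``[(start_ms, end_ms, payload), ...]``.  All electrode
    measures of one channel must share an identical epoch grid.
    """
    ch_type = graph.node(channel).props.get("type", "")
    electrode_names = [s.name for s, _ in signal_lists if s.kind == "electrode"]
    if ch_type == "ECG" and electrode_names and sorted(electrode_names) != ["left", "right"]:
        raise ValidationError("an ECG channel carries electrode measures 'left' and 'right'")
    if ch_type == "GSR" and electrode_names and electrode_names != ["GSR"]:
        raise ValidationError("a GSR channel carries a single electrode measure 'GSR'")
    grid = None
    for spec, series in signal_lists:
        if spec.kind == "electrode":
            g = _epoch_grid(series)
            if grid is None:
                grid = g
            elif g != grid:
                raise EpochGridMismatchError(
                    f"electrode measure {spec.name!r} has a different epoch grid"
                )
    measure_ids = attach_measures(graph, channel, [s for s, _ in signal_lists])
    for mid, (spec, series) in zip(measure_ids, signal_lists):
        if spec.kind == "timestamp":
            rec.timeline.attach_timestamp_values(mid, series)
        else:
            rec.timeline.attach_epoch_values(mid, series, allow_overlap=sliding)
    return measure_ids


# ----------------------------------------------------------------------
# file dialects


def read_timestamp_csv(path: str | Path) -> list[tuple[int, float | None]]:
    rows = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#") or row[0] == "t_ms":
                continue
            value = None if row[1] == "" else float(row[1])
            rows.append((int(row[0]), value))
    return rows


def read_epoch_csv(path: str | Path) -> list[tuple[int, int, Any]]:
    rows: list[tuple[int, int, Any]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#") or row[0] == "start_ms":
                continue
            start, end, payload = int(row[0]), int(row[1]), row[2]
            if payload == "":
                rows.append((start, end, None))
            elif ";" in payload:
                rows.append((start, end, [float(v) for v in payload.split(";")]))
            else:
                rows.append((start, end, float(payload)))
    return rows


def read_raw_csv(path: str | Path, fs: float, **meta: str) -> RawSignal:
    values = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#") or row[0] == "index":
                continue
            values.append(float(row[1]))
    return RawSignal(np.asarray(values), fs, **meta)


# ----------------------------------------------------------------------
# session manifest


def load_session(
    manifest_path: str | Path, graph: PropertyGraph | None = None
) -> tuple[PropertyGraph, RecordingHandle]:
    """Build a session graph from a manifest (YAML) plus its signal CSVs.

    Manifest schema (all paths relative to the manifest):

    .. code-block:: yaml

        experiment: {name: ..., activity: ...}
        participant: {user_id: ...}
        epoch_s: 20.0              # default epoching for raw measures
        channels:
          - type: EEG
            recording_standard: "10-20"
            measures:
              - {signal_id: 1, kind: electrode, name: F3,
                 format: raw, file: eeg_F3.csv, fs: 128}
              - {signal_id: 40, kind: epoch, name: valence,
                 datatype: float, range: "-1..1 inclusive",
                 format: epoch, file: valence.csv}
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        man = yaml.safe_load(fh)
    base = manifest_path.parent
    if graph is None:
        graph = PropertyGraph()
    exp_cfg = man["experiment"]
    exp, timeline = create_experiment(
        graph,
        ExperimentSpec(
            exp_cfg["name"],
            exp_cfg.get("activity"),
            exp_cfg.get("place"),
            exp_cfg.get("extra", {}),
        ),
    )
    part_cfg = man["participant"]
    part = create_participant(
        graph,
        ParticipantSpec(
            part_cfg["user_id"],
            part_cfg.get("gender"),
            part_cfg.get("age"),
            part_cfg.get("extra", {}),
        ),
    )
    chan_specs = [
        ChannelSpec(c["type"], c.get("recording_standard"), c.get("extra", {}))
        for c in man["channels"]
    ]
    handle = create_recording(graph, exp, part, chan_specs, timeline)
    default_epoch_s = float(man.get("epoch_s", 20.0))
    for channel_node, ch_cfg in zip(handle.channel_nodes, man["channels"]):
        signal_lists = []
        for m in ch_cfg["measures"]:
            spec = MeasureSpec(
                signal_id=int(m["signal_id"]),
                kind=m["kind"],
                name=str(m["name"]),
                datatype=m.get("datatype"),
                range=m.get("range"),
                fs_hz=m.get("fs"),
                extra=m.get("extra", {}),
            )
            fmt = m.get("format", "epoch" if spec.kind != "timestamp" else "timestamp")
            path = base / m["file"]
            if fmt == "raw":
                raw = read_raw_csv(
                    path, float(m["fs"]),
                    channel_type=ch_cfg["type"], measure_name=spec.name,
                )
                pp = m.get("preprocess")
                if pp:
                    raw = preprocess(raw, PreprocessConfig(
                        pp.get("bpf_low_hz"), pp.get("bpf_high_hz"),
                        pp.get("resample_hz"), pp.get("order", 4)))
                cfg = EpochingConfig(epoch_s=float(m.get("epoch_s", default_epoch_s)))
                series: Sequence = epochize(raw, cfg)
            elif fmt == "timestamp":
                series = read_timestamp_csv(path)
            elif fmt == "epoch":
                series = read_epoch_csv(path)
            else:
                raise ValidationError(f"unknown measure format {fmt!r}")
            signal_lists.append((spec, series))
        import_signals(graph, handle, channel_node, signal_lists)
    return graph, handle
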