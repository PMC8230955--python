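"""Seeded synthetic session generator with known ground truth.

Generates complete multi-channel recording sessions — 14-electrode EEG
(10-20 names), two-electrode ECG (left/right), single-electrode GSR, and
Russell-model valence/arousal annotation streams — as raw sample arrays
and/or on-disk CSV sessions consumable by the ingest layer.  Every
generator is driven by one ``numpy`` Generator seeded from the recipe, so
a fixed seed reproduces the session byte-for-byte.

The generators make no physiological-realism claim; they exist to give
every downstream computation a checkable ground truth: EEG electrodes are
sums of band-centred sinusoids plus Gaussian noise (so the dominant band
is known), ECG is a beat template placed at beat times with Gaussian RR
intervals (so the IBI series is known), GSR is a flat tonic level with
skin-conductance-response-shaped bumps injected at known times (so the
per-epoch peak count is known), and annotations are piecewise-constant
per-epoch values sampled at a configurable rate (so epoch averages are
known exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .errors import ValidationError
from .ingest import EpochingConfig, RawSignal, epochize

#: 14-channel 10-20 montage (the consumer-headset subset).
TEN_TWENTY_14 = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Sinusoid frequency used to put energy in the centre of each band.
BAND_CENTER_HZ = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 40.0}


@dataclass
class EEGRecipe:
    electrodes: tuple[str, ...] = TEN_TWENTY_14
    fs: float = 128.0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"delta": 4.0, "theta": 2.0, "alpha": 10.0,
                                 "beta": 1.5, "gamma": 1.0}
    )
    noise_sd: float = 1.0
    #: electrode-name pairs that share an extra common component (induces MI)
    shared_pairs: tuple[tuple[str, str], ...] = ()
    shared_amplitude: float = 8.0


@dataclass
class ECGRecipe:
    fs: float = 256.0
    rr_mean_ms: float = 1000.0
    rr_sd_ms: float = 50.0
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.rr_mean_ms <= 300:
            raise ValidationError("rr_mean_ms must exceed the 300 ms refractory scale")


@dataclass
class GSRRecipe:
    fs: float = 32.0
    baseline: float = 2.0
    peak_amplitude: float = 0.5
    max_peaks_per_epoch: int = 3
    noise_sd: float = 0.002
    #: explicit injection times (s); None draws per-epoch counts from the rng
    peak_times_s: tuple[float, ...] | None = None


@dataclass
class AnnotationRecipe:
    model: str = "russell"  # valence/arousal; "ekman" gives six basic-emotion streams
    fs: float = 1.0
    low: float = -1.0
    high: float = 1.0


@dataclass
class SessionRecipe:
    seed: int = 0
    duration_s: float = 120.0
    epoch_s: float = 20.0
    eeg: EEGRecipe = field(default_factory=EEGRecipe)
    ecg: ECGRecipe = field(default_factory=ECGRecipe)
    gsr: GSRRecipe = field(default_factory=GSRRecipe)
    annotations: AnnotationRecipe = field(default_factory=AnnotationRecipe)

    @property
    def n_epochs(self) -> int:
        return int(self.duration_s // self.epoch_s)


@dataclass
class GroundTruth:
    beat_times_ms: list[float] = field(default_factory=list)
    gsr_peak_counts: list[int] = field(default_factory=list)
    dominant_band: dict[str, str] = field(default_factory=dict)
    annotation_values: dict[str, list[float]] = field(default_factory=dict)


# ----------------------------------------------------------------------


def gen_eeg(recipe: SessionRecipe, rng: np.random.Generator) -> tuple[list[RawSignal], GroundTruth]:
    """Per-electrode band-mixture signals with a known dominant band."""
    eeg = recipe.eeg
    for band, freq in BAND_CENTER_HZ.items():
        if eeg.band_amplitudes.get(band, 0) > 0 and freq >= eeg.fs / 2:
            raise ValidationError(f"{band} centre {freq} Hz at or above Nyquist")
    n = int(round(eeg.fs * recipe.duration_s))
    t = np.arange(n) / eeg.fs
    shared: dict[str, np.ndarray] = {}
    for a, b in eeg.shared_pairs:
        comp = eeg.shared_amplitude * np.sin(
            2 * np.pi * BAND_CENTER_HZ["alpha"] * t + rng.uniform(0, 2 * np.pi)
        )
        shared[a] = shared.get(a, 0) + comp
        shared[b] = shared.get(b, 0) + comp
    truth = GroundTruth()
    signals = []
    for el in eeg.electrodes:
        x = np.zeros(n)
        for band, amp in eeg.band_amplitudes.items():
            if amp:
                x += amp * np.sin(2 * np.pi * BAND_CENTER_HZ[band] * t
                                  + rng.uniform(0, 2 * np.pi))
        if eeg.noise_sd:
            x += rng.normal(0, eeg.noise_sd, n)
        if el in shared:
            x = x + shared[el]
        signals.append(RawSignal(x, eeg.fs, "EEG", el))
        amps = {b: a for b, a in eeg.band_amplitudes.items() if a}
        if amps:
            truth.dominant_band[el] = max(amps, key=amps.get)
    return signals, truth


def ecg_beat_template(fs: float) -> np.ndarray:
    """A stylized P-QRS-T complex spanning +-300 ms, R peak at the centre."""
    t = np.arange(-0.3, 0.3, 1.0 / fs)

    def g(mu, sd, amp):
        return amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)

    return (
        g(-0.2, 0.025, 0.12)   # P
        + g(-0.025, 0.01, -0.15)  # Q
        + g(0.0, 0.012, 1.0)   # R
        + g(0.025, 0.01, -0.25)   # S
        + g(0.16, 0.05, 0.3)   # T
    )


def gen_ecg(recipe: SessionRecipe, rng: np.random.Generator) -> tuple[list[RawSignal], GroundTruth]:
    """Left/right ECG traces built from one beat-time sequence.

    RR intervals are Gaussian (truncated above 300 ms); the right trace is
    the same beat train scaled to 0.8 with its own noise.
    """
    ecg = recipe.ecg
    n = int(round(ecg.fs * recipe.duration_s))
    beat_times = []
    t_ms = 500.0  # first beat half a second in
    while t_ms < recipe.duration_s * 1000 - 300:
        beat_times.append(t_ms)
        rr = rng.normal(ecg.rr_mean_ms, ecg.rr_sd_ms)
        t_ms += max(rr, 300.0)
    template = ecg_beat_template(ecg.fs)
    half = len(template) // 2
    base = np.zeros(n)
    for bt in beat_times:
        idx = int(round(bt / 1000 * ecg.fs))
        lo, hi = idx - half, idx - half + len(template)
        s0, s1 = max(lo, 0), min(hi, n)
        base[s0:s1] += template[s0 - lo : s1 - lo]
    truth = GroundTruth(beat_times_ms=list(beat_times))
    left = RawSignal(base + rng.normal(0, ecg.noise_sd, n), ecg.fs, "ECG", "left")
    right = RawSignal(0.8 * base + rng.normal(0, ecg.noise_sd, n), ecg.fs, "ECG", "right")
    return [left, right], truth


def scr_kernel(fs: float, rise_s: float = 0.75, decay_s: float = 2.0) -> np.ndarray:
    """Difference-of-exponentials skin-conductance-response shape, unit peak."""
    t = np.arange(0, rise_s + 5 * decay_s, 1.0 / fs)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


def gen_gsr(recipe: SessionRecipe, rng: np.random.Generator) -> tuple[RawSignal, GroundTruth]:
    """Tonic level plus SCR bumps at known times, counted per epoch.

    Injection times stay >= 1 s after an epoch's start and >= 4 s before
    its end (so each bump's rise completes inside its epoch) and >= 5 s
    apart (so bumps remain separable).
    """
    gsr = recipe.gsr
    n = int(round(gsr.fs * recipe.duration_s))
    x = np.full(n, gsr.baseline)
    n_epochs = recipe.n_epochs
    counts = [0] * n_epochs
    if gsr.peak_times_s is not None:
        times = sorted(gsr.peak_times_s)
    else:
        times = []
        for ei in range(n_epochs):
            lo, hi = ei * recipe.epoch_s + 1.0, (ei + 1) * recipe.epoch_s - 4.0
            slots = np.arange(lo, hi, 5.0)
            k = int(rng.integers(0, min(gsr.max_peaks_per_epoch, len(slots)) + 1))
            chosen = rng.choice(len(slots), size=k, replace=False)
            times += [float(slots[c] + rng.uniform(0, 1.0)) for c in sorted(chosen)]
        times.sort()
    kernel = gsr.peak_amplitude * scr_kernel(gsr.fs)
    for tt in times:
        if not 0 <= tt < recipe.duration_s:
            raise ValidationError(f"peak time {tt} s outside the session")
        idx = int(round(tt * gsr.fs))
        hi = min(idx + len(kernel), n)
        x[idx:hi] += kernel[: hi - idx]
        ei = int(tt // recipe.epoch_s)
        if ei < n_epochs:
            counts[ei] += 1
    if gsr.noise_sd:
        x += rng.normal(0, gsr.noise_sd, n)
    return RawSignal(x, gsr.fs, "GSR", "GSR"), GroundTruth(gsr_peak_counts=counts)


def gen_annotations(
    recipe: SessionRecipe, rng: np.random.Generator
) -> tuple[dict[str, list[tuple[int, float]]], GroundTruth]:
    """Piecewise-constant annotation streams sampled at ``annotations.fs``.

    The underlying truth is one value per epoch; the emitted timestamp
    series samples that step function, so averaging any stream over epochs
    recovers the truth exactly whatever the sampling rate.
    """
    ann = recipe.annotations
    if ann.model == "russell":
        names = ["valence", "arousal"]
    elif ann.model == "ekman":
        names = ["happiness", "sadness", "anger", "fear", "disgust", "surprise"]
    else:
        raise ValidationError(f"unknown annotation model {ann.model!r}")
    n_epochs = recipe.n_epochs
    truth = GroundTruth()
    series: dict[str, list[tuple[int, float]]] = {}
    step_ms = 1000.0 / ann.fs
    n_samples = int(round(recipe.duration_s * ann.fs))
    for name in names:
        values = rng.uniform(ann.low, ann.high, n_epochs)
        values = np.round(values, 4)  # keep CSV text exact
        truth.annotation_values[name] = [float(v) for v in values]
        rows = []
        for i in range(n_samples):
            t_ms = i * step_ms
            if not float(t_ms).is_integer():
                continue  # sub-ms offsets are not representable on the timeline
            ei = min(int(t_ms // (recipe.epoch_s * 1000)), n_epochs - 1)
            rows.append((int(t_ms), float(values[ei])))
        series[name] = rows
    return series, truth


def epoch_average(series: list[tuple[int, float]], epoch_s: float, n_epochs: int) -> list[float]:
    """Average a timestamp series over fixed epochs (half-open intervals)."""
    sums = np.zeros(n_epochs)
    counts = np.zeros(n_epochs)
    for t_ms, v in series:
        ei = int(t_ms // (epoch_s * 1000))
        if ei < n_epochs:
            sums[ei] += v
            counts[ei] += 1
    with np.errstate(invalid="ignore"):
        return [float(s / c) if c else float("nan") for s, c in zip(sums, counts)]


# ----------------------------------------------------------------------
# session assembly


def generate_session(recipe: SessionRecipe) -> tuple[dict[str, Any], GroundTruth]:
    """All raw materials of one session, keyed by channel, plus ground truth."""
    rng = np.random.default_rng(recipe.seed)
    eeg_signals, eeg_truth = gen_eeg(recipe, rng)
    ecg_signals, ecg_truth = gen_ecg(recipe, rng)
    gsr_signal, gsr_truth = gen_gsr(recipe, rng)
    ann_series, ann_truth = gen_annotations(recipe, rng)
    truth = GroundTruth(
        beat_times_ms=ecg_truth.beat_times_ms,
        gsr_peak_counts=gsr_truth.gsr_peak_counts,
        dominant_band=eeg_truth.dominant_band,
        annotation_values=ann_truth.annotation_values,
    )
    return (
        {"eeg": eeg_signals, "ecg": ecg_signals, "gsr": gsr_signal,
         "annotations": ann_series},
        truth,
    )


def _write_raw_csv(path: Path, sig: RawSignal) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("index,value\n")
        for i, v in enumerate(sig.samples):
            fh.write(f"{i},{v:.6f}\n")


def _write_epoch_csv(path: Path, rows: list[tuple[int, int, float]]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("start_ms,end_ms,value\n")
        for s, e, v in rows:
            fh.write(f"{s},{e},{v}\n")


def _write_timestamp_csv(path: Path, rows: list[tuple[int, float]]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("t_ms,value\n")
        for t, v in rows:
            fh.write(f"{t},{v}\n")


def write_session(
    recipe: SessionRecipe,
    out_dir: str | Path,
    *,
    include_raw_annotations: bool = False,
) -> tuple[Path, GroundTruth]:
    """Write a full on-disk session (signal CSVs + manifest) and return the
    manifest path.

    Annotation streams are epoch-averaged into epoch-signal CSVs (the form
    feature extraction consumes); ``include_raw_annotations`` additionally
    emits the raw heterogeneous-rate timestamp streams.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    materials, truth = generate_session(recipe)
    n_epochs = recipe.n_epochs
    epoch_ms = int(recipe.epoch_s * 1000)
    sid = iter(range(1, 10_000))

    channels: list[dict[str, Any]] = []

    eeg_measures = []
    for sig in materials["eeg"]:
        fname = f"eeg_{sig.measure_name}.csv"
        _write_raw_csv(out / fname, sig)
        eeg_measures.append(
            {"signal_id": next(sid), "kind": "electrode", "name": sig.measure_name,
             "format": "raw", "file": fname, "fs": sig.fs}
        )
    channels.append(
        {"type": "EEG", "recording_standard": "10-20", "measures": eeg_measures}
    )

    ecg_measures = []
    for sig in materials["ecg"]:
        fname = f"ecg_{sig.measure_name}.csv"
        _write_raw_csv(out / fname, sig)
        ecg_measures.append(
            {"signal_id": next(sid), "kind": "electrode", "name": sig.measure_name,
             "format": "raw", "file": fname, "fs": sig.fs}
        )
    channels.append({"type": "ECG", "measures": ecg_measures})

    gsr_sig = materials["gsr"]
    _write_raw_csv(out / "gsr_GSR.csv", gsr_sig)
    channels.append(
        {"type": "GSR", "measures": [
            {"signal_id": next(sid), "kind": "electrode", "name": "GSR",
             "format": "raw", "file": "gsr_GSR.csv", "fs": gsr_sig.fs}
        ]}
    )

    ann_measures = []
    rng_range = f"{recipe.annotations.low}..{recipe.annotations.high} inclusive"
    for name, series in materials["annotations"].items():
        avg = epoch_average(series, recipe.epoch_s, n_epochs)
        rows = [(i * epoch_ms, (i + 1) * epoch_ms, avg[i]) for i in range(n_epochs)]
        fname = f"annotation_{name}.csv"
        _write_epoch_csv(out / fname, rows)
        ann_measures.append(
            {"signal_id": next(sid), "kind": "epoch", "name": name,
             "datatype": "float", "range": rng_range,
             "format": "epoch", "file": fname}
        )
        if include_raw_annotations:
            raw_name = f"annotation_{name}_raw.csv"
            _write_timestamp_csv(out / raw_name, series)
            ann_measures.append(
                {"signal_id": next(sid), "kind": "timestamp", "name": f"{name}_raw",
                 "datatype": "float", "range": rng_range,
                 "format": "timestamp", "file": raw_name}
            )
    channels.append({"type": "Annotation", "measures": ann_measures})

    manifest = {
        "experiment": {"name": f"synthetic-session-{recipe.seed}",
                       "activity": "synthetic stimulus"},
        "participant": {"user_id": recipe.seed},
        "epoch_s": recipe.epoch_s,
        "channels": channels,
    }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path, truth


def build_session_graph(recipe: SessionRecipe):
    """In-memory session build (no disk): generate, epochize, import.

    Returns ``(graph, handle, truth, signal_ids)`` where ``signal_ids``
    maps measure names (and ``valence``/``arousal``) to signal ids.
    """
    from .graph import PropertyGraph
    from .ingest import import_signals
    from .schema import (ChannelSpec, ExperimentSpec, MeasureSpec,
                         ParticipantSpec, create_experiment,
                         create_participant, create_recording)

    materials, truth = generate_session(recipe)
    graph = PropertyGraph()
    exp, timeline = create_experiment(
        graph, ExperimentSpec(f"synthetic-session-{recipe.seed}")
    )
    part = create_participant(graph, ParticipantSpec(recipe.seed))
    ann_names = list(materials["annotations"])
    handle = create_recording(
        graph, exp, part,
        [ChannelSpec("EEG", "10-20"), ChannelSpec("ECG"), ChannelSpec("GSR"),
         ChannelSpec("Annotation")],
        timeline,
    )
    cfg = EpochingConfig(epoch_s=recipe.epoch_s)
    sid = iter(range(1, 10_000))
    signal_ids: dict[str, int] = {}

    def electrode_lists(signals):
        lists = []
        for sig in signals:
            spec = MeasureSpec(next(sid), "electrode", sig.measure_name, fs_hz=sig.fs)
            signal_ids[sig.measure_name] = spec.signal_id
            lists.append((spec, epochize(sig, cfg)))
        return lists

    ch_eeg, ch_ecg, ch_gsr, ch_ann = handle.channel_nodes
    import_signals(graph, handle, ch_eeg, electrode_lists(materials["eeg"]))
    import_signals(graph, handle, ch_ecg, electrode_lists(materials["ecg"]))
    import_signals(graph, handle, ch_gsr, electrode_lists([materials["gsr"]]))
    epoch_ms = int(recipe.epoch_s * 1000)
    ann_lists = []
    for name in ann_names:
        avg = epoch_average(materials["annotations"][name], recipe.epoch_s, recipe.n_epochs)
        rows = [(i * epoch_ms, (i + 1) * epoch_ms, avg[i]) for i in range(recipe.n_epochs)]
        spec = MeasureSpec(
            next(sid), "epoch", name, datatype="float",
            range=f"{recipe.annotations.low}..{recipe.annotations.high} inclusive",
        )
        signal_ids[name] = spec.signal_id
        ann_lists.append((spec, rows))
    import_signals(graph, handle, ch_ann, ann_lists)
    return graph, handle, truth, signal_ids
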