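"""Per-epoch feature calculators and the calculator-application engine.

Two calculator shapes exist, mirroring the plug-in contract of the graph
pipeline:

* a *node calculator* maps one epoch's sample array to a property map and
  is written onto each ``SignalValue`` node (GSR peak statistics, ECG
  HRV/IBI statistics, EEG band powers);
* a *relationship calculator* maps two same-epoch sample arrays to a
  scalar and materializes an ``INFLUENCE_ON`` edge between the two
  ``SignalValue`` nodes carrying it (here: mutual information, property
  ``mi``).

Applying the calculators to a channel with ``m`` electrode measures and
``n`` epochs creates, when no threshold is given, the complete graph on
each epoch's ``m`` values: ``n * m*(m-1)/2`` edges.  With a threshold
``mu`` an edge is only created when the computed value is ``>= mu``.
Edges never cross epochs (Cartesian, not strong, product of the sensor
graph with the time-series chain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy import signal as sps

from .errors import EpochGridMismatchError, ValidationError
from .graph import PropertyGraph

NodeCalculator = Callable[[np.ndarray, float], dict[str, Any]]
RelCalculator = Callable[[np.ndarray, np.ndarray, float], float]


# ----------------------------------------------------------------------
# EEG band power (multitaper)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float


#: Canonical EEG rhythm bands; intervals are half-open [low, high) so the
#: shared printed boundaries (4, 8, 12, 30 Hz) are counted once.
DEFAULT_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 100.0),
)


def multitaper_psd(
    x: np.ndarray, fs: float, *, nw: float = 4.0, k: int | None = None,
    adaptive: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided multitaper PSD via Slepian (DPSS) tapers.

    ``k`` defaults to ``2*nw - 1`` tapers.  Per-taper eigenspectra are
    combined by an eigenvalue-weighted average (compensating the energy
    loss of higher-order tapers); ``adaptive=True`` switches to Thomson's
    iterative adaptive weights.  Returns ``(freqs, psd)`` with the usual
    one-sided density normalisation (integral over frequency ~ variance).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 8:
        raise ValidationError("epoch too short for multitaper estimation")
    if k is None:
        k = int(2 * nw - 1)
    tapers, eigvals = sps.windows.dpss(n, nw, Kmax=k, return_ratios=True)
    # eigenspectra: |FFT of tapered signal|^2, one-sided density scaling
    spectra = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2
    spectra /= fs
    if n % 2 == 0:
        spectra[:, 1:-1] *= 2.0
    else:
        spectra[:, 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    if adaptive:
        psd = _adaptive_combine(spectra, eigvals, np.var(x))
    else:
        psd = np.sum(eigvals[:, None] * spectra, axis=0) / np.sum(eigvals)
    return freqs, psd


def _adaptive_combine(
    spectra: np.ndarray, eigvals: np.ndarray, sig_var: float, n_iter: int = 10
) -> np.ndarray:
    psd = spectra[:2].mean(axis=0)
    if sig_var == 0:
        return np.zeros(spectra.shape[1])
    for _ in range(n_iter):
        d = psd[None, :] / (
            eigvals[:, None] * psd[None, :] + (1 - eigvals[:, None]) * sig_var
        )
        w = d**2 * eigvals[:, None]
        psd = np.sum(w * spectra, axis=0) / np.sum(w, axis=0)
    return psd


def eeg_bandpower(
    epoch_samples: Sequence[float],
    fs: float,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    *,
    nw: float = 4.0,
    k: int | None = None,
    adaptive: bool = False,
) -> dict[str, float]:
    """Band powers (PSD integral per band) from a multitaper estimate.

    Bands extending past Nyquist are clipped.  A zero signal yields zero
    power in every band.
    """
    x = np.asarray(epoch_samples, dtype=float)
    freqs, psd = multitaper_psd(x, fs, nw=nw, k=k, adaptive=adaptive)
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    out = {}
    for b in bands:
        hi = min(b.high_hz, fs / 2)
        sel = (freqs >= b.low_hz) & (freqs < hi)
        out[b.name] = float(np.sum(psd[sel]) * df)
    return out


# ----------------------------------------------------------------------
# mutual information (plug-in / maximum-likelihood histogram estimator)


@dataclass(frozen=True)
class MIEstimate:
    """Histogram mutual information in bits, with its entropy terms."""

    mi: float
    hx: float
    hy: float
    hy_given_x: float
    bins: int


def _plugin_entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def default_bins(n: int, cap: int = 16) -> int:
    return max(1, min(cap, int(np.ceil(np.sqrt(n)))))


def mutual_information(
    x: Sequence[float], y: Sequence[float], bins: int | None = None
) -> MIEstimate:
    """Plug-in mutual information ``I(X;Y) = H(Y) - H(Y|X)`` in bits.

    Both arrays are discretized with equal-width bins over their observed
    ranges (a constant array collapses to one bin); the joint histogram's
    empirical frequencies are the maximum-likelihood distribution estimates
    from which all entropies are computed, so ``mi = hx + hy - hxy`` and
    ``hy_given_x = hxy - hx`` hold exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    if x.size < 2:
        raise ValidationError("need at least two samples")
    if bins is None:
        bins = default_bins(x.size)
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    hx = _plugin_entropy(joint.sum(axis=1))
    hy = _plugin_entropy(joint.sum(axis=0))
    hxy = _plugin_entropy(joint.ravel())
    mi = max(hx + hy - hxy, 0.0)
    return MIEstimate(mi=mi, hx=hx, hy=hy, hy_given_x=hxy - hx, bins=bins)


def mi_calculator(x: np.ndarray, y: np.ndarray, fs: float) -> float:
    """Relationship-calculator adapter: MI in bits between two epochs."""
    return mutual_information(x, y).mi


# ----------------------------------------------------------------------
# GSR peak features


@dataclass(frozen=True)
class GSRConfig:
    """Skin-conductance-response detection parameters.

    Onsets are upward zero-crossings of the derivative of the low-passed
    signal; a deflection counts as a peak when the rise from onset to the
    local maximum exceeds ``amp_threshold`` (signal units).
    """

    amp_threshold: float = 0.01
    smooth_hz: float = 1.0
    smooth_order: int = 2


def _lowpass(x: np.ndarray, fs: float, cutoff: float, order: int) -> np.ndarray:
    if cutoff >= fs / 2 or len(x) < 3 * (order + 1):
        return x
    sos = sps.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def gsr_features(
    epoch_samples: Sequence[float], fs: float, config: GSRConfig = GSRConfig()
) -> dict[str, Any]:
    """Per-epoch skin-conductance peak statistics.

    Returns ``GSR_min`` / ``GSR_max`` / ``GSR_avg`` over the detected peak
    amplitudes (rise from onset) plus the count ``no_of_peaks``.  With no
    detected peak the three statistics are None and the count 0.
    """
    x = np.asarray(epoch_samples, dtype=float)
    if x.size == 0:
        raise ValidationError("empty epoch")
    sm = _lowpass(x, fs, config.smooth_hz, config.smooth_order)
    d = np.diff(sm)
    amplitudes = []
    i = 1
    while i < len(d):
        if d[i - 1] <= 0 < d[i]:  # onset: derivative turns upward
            j = i
            while j < len(d) and d[j] > 0:
                j += 1
            rise = sm[j] - sm[i]
            if rise >= config.amp_threshold:
                amplitudes.append(rise)
            i = j + 1
        else:
            i += 1
    if not amplitudes:
        return {"GSR_min": None, "GSR_max": None, "GSR_avg": None, "no_of_peaks": 0}
    amps = np.asarray(amplitudes)
    return {
        "GSR_min": float(amps.min()),
        "GSR_max": float(amps.max()),
        "GSR_avg": float(amps.mean()),
        "no_of_peaks": int(len(amps)),
    }


# ----------------------------------------------------------------------
# ECG R-peak detection and HRV/IBI features


@dataclass(frozen=True)
class ECGConfig:
    """Differentiate-filter-threshold R-peak detector parameters.

    The detector differentiates the signal (4-sample difference), smooths
    the rectified derivative with a short moving window, thresholds it at
    ``threshold_frac`` of its high percentile, and enforces a refractory
    period between beats; the R index is the raw-signal argmax within
    ``search_ms`` of each super-threshold onset.
    """

    threshold_frac: float = 0.4
    refractory_ms: float = 200.0
    search_ms: float = 100.0
    smooth_ms: float = 40.0


def detect_r_peaks(
    epoch_samples: Sequence[float], fs: float, config: ECGConfig = ECGConfig()
) -> np.ndarray:
    """R-peak sample indices within one epoch (possibly empty)."""
    x = np.asarray(epoch_samples, dtype=float)
    if x.size < 8:
        return np.empty(0, dtype=int)
    d = np.zeros_like(x)
    d[4:] = x[4:] - x[:-4]
    feat = np.abs(d)
    win = max(1, int(round(config.smooth_ms / 1000 * fs)))
    feat = np.convolve(feat, np.ones(win) / win, mode="same")
    ref = np.percentile(feat, 99)
    if ref <= 0:
        return np.empty(0, dtype=int)
    thr = config.threshold_frac * ref
    above = feat > thr
    refractory = int(round(config.refractory_ms / 1000 * fs))
    search = max(1, int(round(config.search_ms / 1000 * fs)))
    peaks: list[int] = []
    i = 0
    n = len(x)
    while i < n:
        if above[i]:
            lo, hi = i, min(i + search, n)
            r = lo + int(np.argmax(x[lo:hi]))
            if not peaks or r - peaks[-1] >= refractory:
                peaks.append(r)
            i = max(i + 1, r + refractory)
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def _stats(v: np.ndarray) -> dict[str, float]:
    return {
        "min": float(v.min()),
        "max": float(v.max()),
        "var": float(v.var()),
        "mean": float(v.mean()),
    }


def ecg_features(
    epoch_samples: Sequence[float], fs: float, config: ECGConfig = ECGConfig()
) -> dict[str, Any]:
    """Per-epoch HRV and IBI statistics from detected R peaks.

    IBI is the series of successive R-R intervals (ms); HRV the series of
    successive IBI differences.  For each, the min / max / variance / mean
    over the epoch are returned (8 values).  An epoch spanning fewer than
    three beats yields all-None statistics (missing values, not an error).
    """
    peaks = detect_r_peaks(epoch_samples, fs, config)
    keys = [f"{pre}_{s}" for pre in ("HRV", "IBI") for s in ("min", "max", "var", "mean")]
    if len(peaks) < 3:
        return {k: None for k in keys}
    ibi = np.diff(peaks) / fs * 1000.0
    hrv = np.diff(ibi)
    out: dict[str, Any] = {}
    for pre, series in (("HRV", hrv), ("IBI", ibi)):
        for name, val in _stats(series).items():
            out[f"{pre}_{name}"] = val
    return out


# ----------------------------------------------------------------------
# application engine


def _band_calculator(x: np.ndarray, fs: float) -> dict[str, Any]:
    return eeg_bandpower(x, fs)


def _gsr_calculator(x: np.ndarray, fs: float) -> dict[str, Any]:
    return gsr_features(x, fs)


def _ecg_calculator(x: np.ndarray, fs: float) -> dict[str, Any]:
    return ecg_features(x, fs)


#: Default calculator registry keyed by channel type.
DEFAULT_NODE_CALCULATORS: dict[str, list[NodeCalculator]] = {
    "EEG": [_band_calculator],
    "ECG": [_ecg_calculator],
    "GSR": [_gsr_calculator],
}
DEFAULT_REL_CALCULATORS: dict[str, list[tuple[str, RelCalculator]]] = {
    "EEG": [("mi", mi_calculator)],
}


@dataclass
class CalculatorJob:
    """One channel's worth of calculator work.

    ``measures`` is the set U of electrode-measure node ids (all from
    ``channel``, equal epoch count each); ``mu`` optionally gates
    relationship-edge creation on the computed value.
    """

    channel: int
    measures: list[int]
    node_calcs: list[NodeCalculator] = field(default_factory=list)
    rel_calcs: list[tuple[str, RelCalculator]] = field(default_factory=list)
    mu: float | None = None
    fs: float | None = None


def signal_chain(graph: PropertyGraph, measure: int) -> list[int]:
    """SignalValue node ids of a measure in NEXT-chain order."""
    roots = graph.successors(measure, "HAS_SIGNAL")
    if not roots:
        return []
    out = [roots[0]]
    while True:
        nxt = [t for t in graph.successors(out[-1], "NEXT")
               if "SignalValue" in graph.node(t).labels]
        if not nxt:
            return out
        out.append(nxt[0])


def _measure_fs(graph: PropertyGraph, measure: int, fallback: float | None) -> float:
    fs = graph.node(measure).props.get("fs", fallback)
    if fs is None:
        raise ValidationError(f"measure {measure} has no sampling rate (fs)")
    return float(fs)


def _epoch_key(graph: PropertyGraph, sv: int) -> tuple[int, int]:
    start = [graph.node(s).props["value"] for s in graph.predecessors(sv, "START_IN_SEC")]
    end = [graph.node(s).props["value"] for s in graph.predecessors(sv, "END_IN_SEC")]
    return (start[0] if start else -1, end[0] if end else -1)


def apply_calculators(graph: PropertyGraph, job: CalculatorJob) -> dict[str, int]:
    """Run node and relationship calculators over one channel.

    Node calculators write their property maps onto every SignalValue of
    every measure in the job.  Relationship calculators connect same-epoch
    SignalValue pairs of *different* measures with an ``INFLUENCE_ON`` edge
    (created only when the computed value is ``>= mu`` if ``mu`` is set),
    directed from the lexicographically smaller electrode name to the
    larger.  Returns counts ``{"nodes_updated": ..., "edges_created": ...}``.
    """
    chains = {m: signal_chain(graph, m) for m in job.measures}
    lengths = {len(c) for c in chains.values()}
    if len(lengths) > 1:
        raise EpochGridMismatchError("measures have differing epoch counts")
    n_epochs = lengths.pop() if lengths else 0
    # verify shared epoch grid
    grids = {
        m: tuple(_epoch_key(graph, sv) for sv in chain)
        for m, chain in chains.items()
    }
    if len(set(grids.values())) > 1:
        raise EpochGridMismatchError("measures have differing epoch boundaries")

    nodes_updated = 0
    for m, chain in chains.items():
        fs = _measure_fs(graph, m, job.fs)
        for sv in chain:
            data = graph.node(sv).props.get("data")
            if data is None:
                continue
            arr = np.asarray(data, dtype=float)
            for calc in job.node_calcs:
                for key, val in calc(arr, fs).items():
                    if val is not None:
                        graph.set_property(sv, key, val)
            nodes_updated += 1

    edges_created = 0
    by_name = sorted(
        job.measures, key=lambda m: str(graph.node(m).props.get("name", m))
    )
    for ei in range(n_epochs):
        for a_idx in range(len(by_name)):
            for b_idx in range(a_idx + 1, len(by_name)):
                ma, mb = by_name[a_idx], by_name[b_idx]
                sva, svb = chains[ma][ei], chains[mb][ei]
                da = graph.node(sva).props.get("data")
                db = graph.node(svb).props.get("data")
                if da is None or db is None:
                    continue
                fs = _measure_fs(graph, ma, job.fs)
                for prop, calc in job.rel_calcs:
                    val = float(calc(np.asarray(da), np.asarray(db), fs))
                    if job.mu is not None and not val >= job.mu:
                        continue
                    graph.create_edge(sva, svb, "INFLUENCE_ON", {prop: val})
                    edges_created += 1
    return {"nodes_updated": nodes_updated, "edges_created": edges_created}


def default_job(
    graph: PropertyGraph, channel: int, measures: list[int],
    mu: float | None = None, fs: float | None = None,
) -> CalculatorJob:
    """CalculatorJob with the default registry for the channel's type."""
    ch_type = graph.node(channel).props.get("type", "")
    return CalculatorJob(
        channel=channel,
        measures=measures,
        node_calcs=list(DEFAULT_NODE_CALCULATORS.get(ch_type, [])),
        rel_calcs=list(DEFAULT_REL_CALCULATORS.get(ch_type, [])),
        mu=mu,
        fs=fs,
    )
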