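import numpy as np
import pytest

from physiograph import (
    ChannelSpec,
    MeasureSpec,
    PropertyGraph,
    create_experiment,
    create_participant,
    create_recording,
    import_signals,
)


@pytest.fixture
def graph():
    return PropertyGraph()


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_recording(graph, channels=("EEG", "ECG", "GSR"), name="exp1", user_id=123):
    """Experiment + participant + one recording with the given channel types."""
    exp, timeline = create_experiment(graph, name)
    part = create_participant(graph, user_id)
    handle = create_recording(
        graph, exp, part, [ChannelSpec(t) for t in channels], timeline
    )
    return handle


def epoch_series(values, epoch_ms=20000, start=0):
    """[(start, end, value), ...] on a fixed epoch grid."""
    return [
        (start + i * epoch_ms, start + (i + 1) * epoch_ms, v)
        for i, v in enumerate(values)
    ]


def attach_electrodes(graph, handle, channel, names, series_per_name, first_sid=1):
    """Import electrode measures with identical epoch grids onto a channel."""
    lists = [
        (MeasureSpec(first_sid + i, "electrode", n), series_per_name[n])
        for i, n in enumerate(names)
    ]
    return import_signals(graph, handle, channel, lists)


@pytest.fixture
def small_session(graph):
    """Two EEG electrodes with data arrays on three epochs, plus a valence
    epoch measure — enough structure for query/feature tests."""
    handle = make_recording(graph, channels=("EEG", "Annotation"))
    eeg_ch, ann_ch = handle.channel_nodes
    rng = np.random.default_rng(7)
    series = {
        n: epoch_series([list(rng.normal(size=16)) for _ in range(3)])
        for n in ("F3", "F4")
    }
    measures = attach_electrodes(graph, handle, eeg_ch, ["F3", "F4"], series)
    valence = import_signals(
        graph,
        handle,
        ann_ch,
        [(
            MeasureSpec(50, "epoch", "valence", datatype="float", range="-1..1 inclusive"),
            epoch_series([0.5, -0.25, 0.75]),
        )],
    )[0]
    return {
        "graph": graph,
        "handle": handle,
        "eeg_channel": eeg_ch,
        "eeg_measures": measures,
        "valence_measure": valence,
    }
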