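"""Retrieval queries vs brute-force oracles; export shape; feature vectors."""

import numpy as np
import pytest

from physiograph import (
    ChannelSpec,
    FeatureConfig,
    MeasureSpec,
    PropertyGraph,
    Restriction,
    UnknownSignalError,
    apply_calculators,
    create_experiment,
    create_participant,
    create_recording,
    default_job,
    export_table,
    extract_feature_vectors,
    find_experiments,
    find_signals,
    get_multivariate,
    get_time_series,
    import_signals,
)
from physiograph.query import EXPORT_METADATA_COLUMNS, cq1_cypher, cq2_cypher

from conftest import epoch_series, make_recording


# ----------------------------------------------------------------------
# brute-force oracles: scan every node/edge, no index or traversal shortcuts


def oracle_experiments(graph, channel_type, measure_name):
    hits = set()
    for e in graph.edges():
        if e.label != "HAS_MEASURE":
            continue
        ch, m = graph.node(e.source), graph.node(e.target)
        if ch.props.get("type") != channel_type:
            continue
        if m.props.get("name") != measure_name:
            continue
        for e2 in graph.edges():
            if e2.label == "HAS_RECORDING_TYPE" and e2.target == ch.id:
                for e3 in graph.edges():
                    if e3.label == "PART_OF" and e3.source == e2.source:
                        if "Experiment" in graph.node(e3.target).labels:
                            hits.add(e3.target)
    return sorted(hits)


def oracle_signals(graph, channel_type, measure_name):
    hits = []
    for e in graph.edges():
        if e.label != "HAS_MEASURE":
            continue
        if graph.node(e.source).props.get("type") != channel_type:
            continue
        if graph.node(e.target).props.get("name") == measure_name:
            hits.append(e.target)
    return sorted(hits)


def random_session_graph(rng):
    """A small random multi-recording graph for oracle comparison."""
    g = PropertyGraph()
    channel_types = ["EEG", "ECG", "GSR"]
    measure_pool = ["F3", "F4", "left", "right", "GSR", "O1"]
    sid = 1
    for xi in range(int(rng.integers(1, 3))):
        exp, tl = create_experiment(g, f"exp{xi}")
        for ri in range(int(rng.integers(1, 3))):
            part = create_participant(g, int(rng.integers(0, 10_000)))
            n_ch = int(rng.integers(1, 3))
            types = list(rng.choice(channel_types, size=n_ch, replace=False))
            handle = create_recording(g, exp, part, [ChannelSpec(t) for t in types], tl)
            for ch in handle.channel_nodes:
                lists = []
                for name in rng.choice(measure_pool, size=int(rng.integers(1, 3)),
                                        replace=False):
                    n_ep = int(rng.integers(1, 4))
                    series = epoch_series(
                        [float(v) for v in rng.normal(size=n_ep)], epoch_ms=1000
                    )
                    lists.append((MeasureSpec(sid, "electrode", str(name)), series))
                    sid += 1
                # bypass channel-type naming conventions: random graphs stress
                # the query layer, not the ingest validators
                from physiograph.schema import attach_measures

                mids = attach_measures(g, ch, [s for s, _ in lists])
                for mid, (_, series) in zip(mids, lists):
                    handle.timeline.attach_epoch_values(mid, series)
    return g


class TestSearchQueries:
    def test_cq1_cq2_match_oracle_on_random_graphs(self):
        rng = np.random.default_rng(20260930)
        for _ in range(100):
            g = random_session_graph(rng)
            for ct in ("EEG", "ECG", "GSR"):
                for mn in ("F3", "left", "GSR"):
                    assert find_experiments(g, ct, mn) == oracle_experiments(g, ct, mn)
                    assert find_signals(g, ct, mn) == oracle_signals(g, ct, mn)

    def test_wrong_channel_type_finds_nothing(self, small_session):
        g = small_session["graph"]
        assert find_experiments(g, "ECG", "F4") == []
        assert find_experiments(g, "EEG", "F4") != []

    def test_empty_graph(self, graph):
        assert find_signals(graph, "EEG", "F4") == []

    def test_cypher_renderings_contain_listing_patterns(self):
        assert "(c:Channel {type:'EEG'})-[:HAS_MEASURE]->" in cq2_cypher("EEG", "F4")
        assert "MATCH (e:Experiment)<-[:PART_OF]-()" in cq1_cypher("EEG", "F4")


class TestTimeSeries:
    def test_epoch_signal_rows_carry_both_ends(self, small_session):
        g = small_session["graph"]
        table = get_time_series(g, 50)  # valence epoch measure
        assert table.columns == ["start_ms", "end_ms", "value"]
        assert table.rows == [
            (0, 20000, 0.5),
            (20000, 40000, -0.25),
            (40000, 60000, 0.75),
        ]

    def test_timestamp_signal_rows_have_null_end(self, graph):
        handle = make_recording(graph, channels=("Annotation",))
        spec = MeasureSpec(9, "timestamp", "temp", datatype="float", range="30..45 inclusive")
        import_signals(graph, handle, handle.channel_nodes[0],
                       [(spec, [(0, 36.5), (1000, 36.6), (2000, 36.4)])])
        table = get_time_series(graph, 9)
        assert [r[1] for r in table.rows] == [None, None, None]
        assert [r[0] for r in table.rows] == [0, 1000, 2000]

    def test_unknown_signal_id(self, graph):
        with pytest.raises(UnknownSignalError):
            get_time_series(graph, 404)


class TestMultivariate:
    def test_shared_grid_joins_fully(self, small_session):
        g = small_session["graph"]
        ms = small_session["eeg_measures"]
        sids = [g.node(m).props["signal_id"] for m in ms]
        table = get_multivariate(g, sids)
        assert len(table.rows) == 3
        assert all(v is not None for row in table.rows for v in row)

    def test_single_signal_equals_time_series(self, small_session):
        g = small_session["graph"]
        multi = get_multivariate(g, [50])
        uni = get_time_series(g, 50)
        assert [tuple(r) for r in multi.rows] == [tuple(r) for r in uni.rows]

    def test_missing_timestamps_left_join_to_null(self, graph):
        handle = make_recording(graph, channels=("Annotation",))
        ch = handle.channel_nodes[0]
        full = (MeasureSpec(1, "epoch", "a", datatype="float", range="0..9 inclusive"),
                epoch_series([1.0, 2.0, 3.0], epoch_ms=1000))
        sparse = (MeasureSpec(2, "epoch", "b", datatype="float", range="0..9 inclusive"),
                  epoch_series([5.0], epoch_ms=1000))
        import_signals(graph, handle, ch, [full, sparse])
        table = get_multivariate(graph, [1, 2])
        assert [r[3] for r in table.rows] == [5.0, None, None]

    def test_restriction_filters_rows(self, small_session):
        """Rows survive only where the valence signal meets the predicate."""
        g = small_session["graph"]
        ms = small_session["eeg_measures"]
        sid = g.node(ms[0]).props["signal_id"]
        unrestricted = get_multivariate(g, [sid])
        restricted = get_multivariate(
            g, [sid], [Restriction(50, "value", ">=", 0.5)]
        )
        # oracle: filter the unrestricted rows through the valence series
        valence = {r[0]: r[2] for r in get_time_series(g, 50).rows}
        expected = [
            r for r in unrestricted.rows
            if valence.get(r[0]) is not None and valence[r[0]] >= 0.5
        ]
        assert restricted.rows == expected
        assert len(restricted.rows) == 2  # 0.5 and 0.75 pass, -0.25 fails


class TestExport:
    def test_export_has_n_plus_7_columns(self, small_session):
        g = small_session["graph"]
        ch = small_session["eeg_channel"]
        ms = small_session["eeg_measures"]
        apply_calculators(g, default_job(g, ch, ms, fs=8.0))
        props = ["delta", "theta", "alpha"]
        table = export_table(g, "EEG", props)
        assert len(table.columns) == len(props) + 7
        assert set(EXPORT_METADATA_COLUMNS) <= set(table.columns)
        assert len(table.rows) == 2 * 3  # 2 electrodes x 3 epochs
        for row in table.rows:
            assert row[-2] is not None and row[-1] is not None  # epoch bounds


class TestFeatureVectors:
    def test_small_montage_length_formula(self, small_session):
        """2 EEG electrodes, no ECG/GSR: 5*2 + 2*(2-1)/2 = 11 features."""
        g = small_session["graph"]
        ch = small_session["eeg_channel"]
        ms = small_session["eeg_measures"]
        apply_calculators(g, default_job(g, ch, ms, fs=8.0))
        rows, cols = extract_feature_vectors(g, small_session["handle"])
        assert len(cols) == 11
        assert len(rows) == 3
        assert sum(c.startswith("mi_") for c in cols) == 1
        assert all(v is not None for row in rows for v in row)

    def test_electrode_order_respected(self, small_session):
        g = small_session["graph"]
        ch = small_session["eeg_channel"]
        ms = small_session["eeg_measures"]
        apply_calculators(g, default_job(g, ch, ms, fs=8.0))
        _, cols = extract_feature_vectors(
            g, small_session["handle"], FeatureConfig(eeg_order=["F4", "F3"])
        )
        assert cols[0].startswith("F4_") and cols[5].startswith("F3_")
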