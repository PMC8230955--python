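# physiograph

A labeled-property-graph store and feature pipeline for multi-modal
physiological signal sessions: EEG, ECG and galvanic skin response (GSR)
recordings together with emotion annotations and experiment context, all in
one queryable graph.

Affective-computing experiments produce signals at heterogeneous rates
(128 Hz EEG, 256 Hz ECG, 1–25 Hz annotation streams), from different
devices, with different epoch conventions. `physiograph` integrates them on
a single millisecond timeline inside a property graph, computes the
standard per-epoch features each modality calls for, and answers a fixed
set of retrieval questions — so data from multiple experiments can feed
statistics or machine-learning pipelines in one tabular form.

## The model

The store is a labeled property graph `G = (V, E, ρ, λ1, λ2, σ)`: nodes
`V`, edges `E` disjoint from them, a total endpoint map `ρ: E → V × V`, a
total node labelling `λ1` into non-empty label sets, a single-label edge
labelling `λ2`, and a partial property function `σ` over `(V ∪ E) × Prop`.
Integrity constraints (unique `Experiment.name`, `Participant.user_id`,
`Timestamp.value`, `Measure.signal_id`; mandatory `Channel.type`) are
enforced transactionally — a violating mutation is rejected and rolled
back, matching graph-database semantics.

On top of the store:

- **schema** — `Experiment`, `Participant`, `Recording`, `Channel` and
  measure nodes (`TimestampMeasure` / `EpochMeasure` / `ElectrodeMeasure`)
  wired by `PART_OF`, `TAKES_PART_IN`, `HAS_RECORDING_TYPE`, `HAS_MEASURE`;
- **timeline** — `Timestamp` nodes (integer ms offsets) in a `NEXT`-linked
  chain shared by every signal; timestamp signals bind via `IN_SEC`, epoch
  signals via `START_IN_SEC`/`END_IN_SEC`;
- **calculators** — per-epoch features written onto `SignalValue` nodes:
  multitaper (Slepian-taper) band powers δ/θ/α/β/γ for EEG, R-peak-derived
  HRV/IBI statistics for ECG, skin-conductance-response peak statistics
  for GSR; and histogram mutual information `I(X;Y) = H(Y) − H(Y|X)` (bits)
  on `INFLUENCE_ON` edges between same-epoch values of EEG electrode pairs,
  optionally gated by a threshold μ;
- **query** — the five canonical retrieval patterns (experiment search,
  signal search, uni- and multivariate time series with optional value
  restrictions), an `n + 7`-column tabular export, per-epoch feature-vector
  extraction, and openCypher renderings of everything;
- **sizing** — closed-form node/edge count predictions
  (`s = ⌊f·t/tₑ⌋` epoch nodes per measure, `r = m(m−1)/2` influence edges
  per epoch) and a fixed-record-length disk model;
- **synth** — seeded generators of complete synthetic sessions with known
  ground truth (beat times, injected SCR counts, dominant bands,
  annotation values), so the whole pipeline is testable without any
  external dataset.

For the default montage — 14 EEG electrodes (10-20 names), ECG left/right,
one GSR electrode, 20 s epochs — each epoch yields
`5·14 + 8·2 + 4 = 90` node-level features plus `14·13/2 = 91` pairwise-MI
edge features: a 181-value vector.

## Worked example

```
$ physiograph simulate --seed 7 --duration 120 --out session
wrote session/manifest.yaml
$ physiograph ingest session/manifest.yaml --out graph.json
wrote graph.json (147 nodes, 374 edges)
$ physiograph features graph.json --out features.csv
wrote features.csv: 6 epochs x 181 features
```

The 120 s session splits into six 20 s epochs; `features.csv` holds one
181-value vector per epoch plus a quadrant label (HVHA/HVLA/LVHA/LVLA)
derived from the signs of the valence/arousal annotations:

```
    F3_alpha  left_IBI_mean  GSR_no_of_peaks  mi_AF3_AF4 label
0  50.368553    1003.289474                1    0.479525  LVHA
1  49.904016     993.215461                0    0.470205  HVHA
2  49.907878    1004.523026                3    0.489608  HVHA
```

`F3_alpha` is the α-band (8–12 Hz) power at electrode F3 — the synthetic
recipe makes α dominant, and a 10 Hz sinusoid of amplitude 10 carries power
A²/2 = 50. `left_IBI_mean` recovers the generator's 1000 ms mean interbeat
interval to within a few ms. `GSR_no_of_peaks` equals the number of
skin-conductance responses injected into that epoch. `mi_AF3_AF4` is the
mutual information (bits) between the two electrodes' samples in that
epoch.

The closed-form sizing report for a 60 s, 128 Hz, 14-measure signal at
epoch length 20 samples:

```
$ physiograph estimate --f 128 --t 60 --m 14 --te 20
{
 "nodes_per_measure": 384,
 "total_signal_nodes": 5376,
 "edges_per_epoch": 91,
 "total_influence_edges": 34944
}
```

Graphs round-trip through JSON, GraphML and openCypher `CREATE` scripts
(`physiograph emit-cypher graph.json`), the latter loadable into a
Neo4j-compatible database.

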