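# Methods

This note records the model, the defaults that matter, the numerical
choices, and what the synthetic generators do and do not emulate.

## Graph model and integrity

The store implements the property-graph tuple `(V, E, ρ, λ1, λ2, σ)` with
directed edges, non-empty node label sets, single edge labels, and at most
one value per (element, property) pair; values are scalars or homogeneous
lists, and a missing measurement is expressed by property absence rather
than a null sentinel. Node and edge ids come from one monotone counter, so
the two id spaces are disjoint and ids are never reused, even after a
rejected mutation.

Label vocabularies are open registries seeded with the session schema
(`Experiment`, `Recording`, `Participant`, `Channel`, `Timestamp`, the
three measure labels, `SignalValue`; edges `PART_OF`, `TAKES_PART_IN`,
`TAKES`, `HAS_RECORDING_TYPE`, `HAS_MEASURE`, `HAS_SIGNAL`, `NEXT`,
`IN_SEC`, `START_IN_SEC`, `END_IN_SEC`, `INFLUENCE_ON`). We use the
space-free CamelCase spellings (`SignalValue`, `ElectrodeMeasure`) because
the query layer emits openCypher and those are the forms valid in patterns
without quoting. Unknown labels are an error; property names are
auto-registered on first use, since the property set is explicitly open to
user-defined names.

Constraint checking is transactional per operation: the default set
(uniqueness on `Experiment.name`, `Participant.user_id`, `Timestamp.value`,
`Measure.signal_id`, where "Measure" covers all three measure labels;
mandatory `Channel.type`) is verified on every node/edge/property mutation,
and a violation rolls the mutation back. Uniqueness is backed by a
per-constraint value index so incremental verification is O(1) per check;
a from-scratch batch re-verification is available and is asserted
equivalent in the tests.

## Timeline

Timestamps are integer milliseconds from recording start; sub-millisecond
offsets are rejected, not rounded. `Timestamp.value` is unique graph-wide,
so the `NEXT`-linked timestamp chain is shared by all experiments stored in
one graph; each experiment's `TAKES` edge points at the earliest timestamp
that experiment references (re-pointed if an earlier one appears later).
Epoch intervals are half-open `[start, end)` so consecutive epochs share
their boundary timestamp node and no sample is counted twice. Fixed-grid
epoch series must be non-overlapping with strictly increasing starts;
sliding-window series relax this to strictly increasing starts only. The
timeline layer never creates `NEXT` self-loops or back-edges, although the
raw store does not forbid them structurally.

## Epoching and preprocessing

A raw signal of `f` Hz and `t` s cut into fixed epochs of `x` s yields
`⌊samples / (f·x)⌋` epochs; a sliding window of `w` samples with overlap
`o` advances by `w − o` and yields `⌊(f·t − w)/(w − o)⌋` windows. Trailing
partial samples are discarded.

The closed-form sizing module expresses the fixed epoch length `tₑ` in
samples, like `w` and `o`: `s = ⌊f·t/tₑ⌋` nodes per measure, `S = m·s`,
`r = m(m−1)/2` influence edges per epoch, `R = s·r`. Expressing `tₑ` in
samples is the only reading under which the node-count formula is exact,
and the tests verify it by integer equality against actually built graphs
over randomized parameter grids. The ingest configuration keeps epoch
length in seconds and converts.

Default preprocessing is a zero-phase (forward-backward) Butterworth
filter, order 4 per pass: EEG band-pass 0.5–45 Hz, ECG band-pass
0.5–40 Hz, GSR low-pass 1 Hz; resampling (polyphase) is off by default.
These brackets cover the analysis bands below; all values are per-measure
configurable. Band edges at or above Nyquist are an error, not silently
clipped.

## Calculators

**EEG band power.** Power spectral density by the multitaper method:
Slepian (DPSS) tapers with time-bandwidth NW = 4 and K = 2·NW − 1 = 7
tapers, combined by an eigenvalue-weighted average to compensate the
energy loss of higher-order tapers; Thomson's iterative adaptive weighting
is available as a config option. Band powers are PSD integrals over δ
[0.5, 4), θ [4, 8), α [8, 12), β [12, 30), γ [30, 100) Hz — half-open so
the shared printed boundaries are counted once — with bands clipped at
Nyquist. A 20 s epoch at 128 Hz gives a half-bandwidth of 0.2 Hz, so
leakage between adjacent bands is negligible for tonal content.

**Mutual information.** Plug-in (maximum-likelihood) histogram estimator in
bits: both arrays are discretized with equal-width bins over their observed
ranges, default bin count ⌈√n⌉ capped at 16; entropies come from the joint
histogram, so `I = H(X) + H(Y) − H(X,Y) = H(Y) − H(Y|X)` holds exactly and
the estimate is symmetric and non-negative by construction. The estimator
is positively biased for independent data (≈ (bins−1)²/(2n ln 2) bits),
which is why the tests compare independent pairs against a permutation
null rather than against zero. The log base and bin rule are config-exposed.

**ECG.** R peaks by a differentiate–smooth–threshold detector: 4-sample
difference, rectification, 40 ms moving-average smoothing, threshold at
0.4 × the 99th percentile of the smoothed feature, a 200 ms refractory
period, and the R index taken as the raw-signal argmax within 100 ms of
each super-threshold onset. All four numbers are config fields. IBI is the
series of successive R-R intervals in ms; HRV is defined here as the series
of successive IBI differences (the usual beat-to-beat variability series);
each contributes its epoch min/max/variance/mean, eight values per
electrode. An epoch with fewer than three detected beats yields all-None
statistics — missing values, not an error.

**GSR.** Skin-conductance-response detection on the 1 Hz-low-passed
signal: onsets are upward zero-crossings of the derivative, and a
deflection counts as a peak when the rise from onset to the following
local maximum exceeds an amplitude threshold (default 0.01 signal units).
Peak amplitude is that rise. `GSR_min`/`GSR_max`/`GSR_avg` summarize the
detected peak amplitudes and `no_of_peaks` counts them; a peakless epoch
has count 0 and None statistics. The detector is deliberately simple and
is validated against the generator's injected ground truth, not against
any published parameterization.

**Application engine.** Node calculators run on each `SignalValue`'s raw
`data` array and write their property maps onto the node. Relationship
calculators connect same-epoch values of *different* electrode measures of
one channel with an `INFLUENCE_ON` edge carrying the computed scalar
(property `mi` for mutual information); with a threshold μ set, an edge is
created only when the value is ≥ μ. Edges never cross epochs — the signal
network is the Cartesian (not strong) product of the sensor graph with the
time chain — and are directed from the lexicographically smaller electrode
name to the larger, an arbitrary but deterministic convention. All
measures in one job must share identical epoch boundaries; this is checked,
not assumed.

## Queries and feature vectors

The five retrieval patterns are executed natively by graph traversal and
are asserted equal, on randomized graphs, to brute-force oracles that scan
every node and edge. Multivariate retrieval joins on the shared *start*
timestamp with left-join semantics (a signal missing at a start yields
null); a restriction predicate fails on null, dropping the row. The
tabular export emits one row per epoch value with `n` requested value
columns plus seven metadata columns (experiment, source_database,
participant, channel_type, measure_name, epoch_start, epoch_end);
`source_database` and the id aliases are optional properties, absent
unless set.

Feature vectors concatenate, per epoch: five band powers per EEG electrode
in configured order (default: measure-name sort; the session manifest's
electrode order is used by the CLI), eight HRV/IBI statistics per ECG
electrode (left before right), the four GSR values, then `mi` per EEG
electrode pair in lexicographic order. Annotation signals designated as
valence/arousal produce a quadrant label (HVHA/HVLA/LVHA/LVLA) from the
signs of their per-epoch values. Missing calculator outputs surface as
None entries rather than being imputed.

## Synthetic sessions

The generators exist to make every property checkable, not to claim
physiological realism. One seeded `numpy` generator drives a session, so a
fixed seed reproduces it byte-for-byte.

- EEG (default 14 electrodes, 128 Hz): per electrode, sinusoids at band
  centres (2, 6, 10, 20, 40 Hz) with a configurable amplitude map
  (α-dominant by default: amplitude 10 vs 1–4 elsewhere) plus unit
  Gaussian noise; optional shared components between electrode pairs
  induce above-baseline mutual information.
- ECG (256 Hz): a stylized P-QRS-T template placed at beat times with
  Gaussian RR intervals (mean 1000 ms, sd 50 ms, truncated above 300 ms);
  the beat times are the ground truth.
- GSR (32 Hz): a flat tonic level (2 µS-like units) with
  difference-of-exponentials SCR bumps (rise 0.75 s, decay 2 s, amplitude
  0.5) injected at known times — at least 1 s after an epoch starts, 4 s
  before it ends, 5 s apart — so per-epoch counts are recoverable exactly.
  Tonic drift is off by default; a drifting baseline would itself register
  as a slow rise and is outside what the count-recovery tests claim.
- Annotations: per-epoch truth values (Russell valence/arousal in [−1, 1],
  or six Ekman streams) emitted as piecewise-constant timestamp streams at
  1, 20 or 25 Hz; epoch-averaging any rate recovers the truth exactly,
  which is the property the heterogeneous-rate tests assert.

Session durations in the tests are 40–200 s with 20 s epochs — small
enough to keep the suite fast while exercising every code path; the graph
and formulas are size-agnostic, and the sizing tests verify the counts
across randomized parameter grids rather than at one scale.

What passing tests therefore do **not** show: robustness to artifacts,
electrode drop-out, movement noise, ectopic beats, overlapping SCRs, or
any real-data class balance. The pipeline's correctness claims are
structural (counts, wiring, round trips, closed forms) and
parameter-recovery claims under the stated noise models.

## Known limitations

- No openCypher parser beyond replaying the package's own emitted scripts;
  the query layer executes only the fixed retrieval patterns natively.
- Single-writer store; no multi-operation transactions.
- No EDF/BDF readers, artifact rejection, ICA, or channel interpolation.
- Inter-epoch and cross-channel influence edges (strong-product structure)
  are out of scope by design.
- The disk model treats the per-property record (41 B) and the string or
  array value record (128 B) as additive; whether a real store shares
  value records is not modelled.
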