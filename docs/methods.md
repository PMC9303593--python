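# Methods

## Sensor error model and the two-step correction

A tri-axial accelerometer at rest measures the gravity vector, so the
Euclidean norm of its three channels, ‖a‖ = (x² + y² + z²)^0.5, should equal
1 g in every attitude. Real tags deviate through a per-axis additive offset
and multiplicative gain error. `accelcal` models the corrupted reading as

    raw = true / gain + offset,

and the correction as its exact inverse, `corrected = (raw − offset) × gain`.
The six-orientation protocol estimates both terms per axis from the two
extreme static means m− (axis pointing down) and m+ (axis up):

    offset = (m− + m+) / 2,        gain = 2 / (m+ − m−).

The gain is written as the reciprocal half-range rather than as the two-stage
"scale each extreme to 1 g" prose description; after offset removal the two
are algebraically identical, and the worked example (−1.0/0.8 g → −0.1 g,
1.1111) is pinned in the tests. Because the fit uses only static gravity
readings, it calibrates the ±1 g range; dynamic excursions beyond ±1 g
(sharp turns, impacts) and temperature dependence are outside its scope.
Latitude variation of gravity (≤ 0.0053 g) is ignored: the reference is
exactly 1 g.

Assumption worth stating: the offset and gain are constant over the
recording. The protocol is cheap enough to repeat per deployment, which is
the recommended guard against drift.

## Static-window detection

Stillness is detected on the vector norm: a sliding window of
`min_duration_s` (default 5 s — long enough to be deliberate, short enough
to admit 5–10 s bench dwells) is moved sample by sample, and positions where
the norm's standard deviation falls below `norm_sd_threshold` (default
0.01 g, roughly twice a quiet MEMS noise floor at 40 Hz) mark stillness. The
union of all such window positions yields maximal non-overlapping static
windows, which therefore align with the true motionless intervals rather
than shrinking by half a window at each end. Window boundaries are then
refined by dropping edge samples whose norm deviates from the window median
by more than the threshold, which stops residual motion from adjacent
transitions biasing the per-axis means; in the noiseless synthetic case this
makes the recovered boundaries exact.

For *fitting*, a window is accepted as one of the six die faces only if its
dominant-axis |mean| exceeds 0.8 g and each other axis stays below 0.4 g.
The sine response justifies the tolerance: an axis 10° off vertical still
reads 98.5 % of full scale, so hand-placed orientations are adequate. When
several windows share a (axis, sign) key, the one with the lowest norm
standard deviation wins — the least-moving window best approximates the
static ideal. For *assessment* (post-hoc mode) no gate applies and any
number of orientations is reported, since archival data rarely cover all
six; the report exposes both per-axis and across-axis mean values and leaves
their interpretation to the user.

## VeDBA

Each axis is split into a static component — a centred running mean over
`static_window_s` (default 2 s, i.e. several wingbeat or stride cycles) —
and a dynamic remainder; VeDBA is the per-sample Euclidean norm of the three
dynamic components. Window length in samples is forced odd for a symmetric
centre; at the series boundaries the window truncates to the available
samples rather than padding, and all segment statistics exclude the first
and last half window by default, where the truncated mean is biased. ODBA
(the absolute-sum variant) is computed alongside for comparability but no
default uses it.

Two consequences of the decomposition matter for quality control and are
asserted as properties: constant offsets cancel in raw − static, so offset
errors barely touch DBA, while a gain on one axis scales that axis's dynamic
component exactly — gain error is what propagates into DBA metrics.

## Flight segmentation

Three named rule sets ship as presets:

* `pigeon_wind_tunnel` (steady flapping): candidate samples have
  1 s-smoothed VeDBA strictly between 0.75 and 3 g, after the first 1 s of
  each flight bout (a maximal run above the lower bound) is discarded.
  Within a candidate run, a segment grows from its anchor until adding a
  sample would make the smoothed-VeDBA range reach 1 g or push the |OLS
  slope| of VeDBA against time above 0.1 g/s; at the first violation the
  segment closes and testing restarts at the violating sample. Segments
  shorter than 2 s are dropped. The slope bound operationalises "no
  apparent trend": 0.1 g/s over a 2 s minimum segment permits at most a
  0.2 g drift, well under the 1 g range budget, and the value is exposed in
  config and in every segment's diagnostics. A `strict` flag discards
  violating runs whole instead of splitting.
* `seabird_level` (level flapping): per-sample VeDBA > 0.3 g and altitude
  rate within ±0.5 m/s (inclusive); maximal runs of at least 2 s. The
  altitude rate is a central difference over a 1 s span on the altitude
  clock (4 Hz typical), truncating to one-sided differences at the edges,
  then nearest-neighbour upsampled onto the acceleration clock. The 2 s
  minimum is this package's choice — long enough to exclude single-wingbeat
  blips without biasing against short level stretches.
* `kittiwake_minutes`: sliding 60 s windows (step 1 s) where the altitude
  spans < 5 m and VeDBA stays above 0.3 g throughout (the objective
  replacement for a visual "no interruption in flapping" check); qualifying
  windows are ranked by altitude span ascending and greedily selected to be
  non-overlapping.

Band bounds are strict inequalities ("between 0.75 and 3 g"), and "varied by
< 1.0 g" is read as max − min of the smoothed series. Every emitted segment
re-checks its own diagnostics against the thresholds that admitted it.
Selection monotonicity (tighter thresholds never enlarge the selected sample
set) holds exactly for the per-sample mask rules (`seabird_level`,
`kittiwake_minutes`); for the split-and-retest steady-flapping rule it holds
for the candidate mask but segment boundaries can shift under re-splitting,
so it is asserted only for the mask-based rules.

## Wingbeat analysis

Peaks are detected on the (dynamic) heave smoothed over `smooth_samples`
(default 3; 0.075 s at 40 Hz), with a minimum separation of one period of
the plausible band's upper frequency (presets: pigeon 3–10 Hz, seabird
2–6 Hz) and a prominence above 0.3 of the running signal amplitude (max −
min over about two slow periods). Separation and prominence are not part of
any field protocol description — they are what makes detection deterministic
— and both are exposed in config. Cycles run peak to peak; frequency is the
inverse duration and amplitude the heave max − min within the cycle.

Cycle profiles assign each sample to percent
floor(100·(t − t₀)/(t₁ − t₀)) of its cycle (bin 100 holds only the terminal
peak sample), average each axis per whole percent across the first
`n_cycles` (default 10, taken consecutively from the segment start), and
smooth circularly over 10 percent bins — the wingbeat being periodic, bins 0
and 100 are the same phase. At realistic rates a cycle has fewer samples
than 101 bins, so bins empty across all contributing cycles are filled by
linear interpolation along the percent axis before smoothing; the profile
records which bins were interpolated. Paired-tag comparison regresses one
profile on the other by ordinary least squares per axis; the slope is the
relative signal amplitude.

The tag-displacement utility returns the arc length 2πr·(P/360) for a
sensor at radius r from the pitch-rotation centre over a pitch excursion of
P degrees — the dimensionally consistent form; the result object carries a
note that some printed versions invert the ratio.

## Synthetic generators

`make_static_sequence` emulates a bench calibration: six dwells (default
10 s at 40 Hz) in the die-face order x+ y+ z+ x− y− z− (consecutive gravity
vectors orthogonal, so each transition is a 90° great-circle rotation), with
a transient norm excursion during rotation (default up to 0.2 g, present
from the first transition sample) mimicking centripetal acceleration under
hand rotation. Corruption divides by gain and adds offset per axis, then
optional white noise. Default error ranges follow the measured spread of
real units: offsets −0.043…0.025 g, gains 0.97…1.023.

`make_flight_trace` builds heave as gravity projection plus
A(t)·sin(2π∫f dt) with piecewise-linear frequency/amplitude profiles, surge
as a phase-lagged copy at a 0.4 relative amplitude leading heave by a
quarter cycle (the heave–surge loop of a real wingbeat; configurable, and no
quantitative claim depends on it), a small sway oscillation, glide intervals
that silence the oscillation, and a 4 Hz altitude channel sharing the trace
clock. `make_paired_tags` scales the dynamic components per axis by known
placement ratios and adds independent noise per tag.

What the generators deliberately do **not** emulate: aerodynamic or
biomechanical realism (stroke asymmetry, body pitch coupling, attachment
looseness dynamics), sensor quantisation, temperature drift, and
non-stationary noise. Passing tests therefore demonstrate that the
*algorithms* recover known structure under controlled corruption and noise —
not that field data meet these assumptions. Ground truth is always returned
machine-readably, and recovery tests compare pipeline output to generator
truth, never to other pipeline output. Identical seeds reproduce traces
bit-for-bit; the seed changes noise only, never ground-truth structure. The
default seed is 20220207.

## Numerical choices and degenerate inputs

* Working unit is g (9.80665 m/s²) throughout; conversion only at I/O.
  Altitude arrives already in metres (pressure-to-altitude conversion is the
  tag vendor's business).
* Time intervals are half-open [start, end); sample i covers t₀ + i/rate,
  making slicing compositional.
* Traces with non-finite samples are rejected at load rather than imputed —
  every downstream operation assumes uniform, gap-free sampling.
* Sampling rate: declared rate wins over timestamp-inferred rate, with a
  warning when they disagree by more than 1 %.
* Degenerate fits raise with specifics: missing (axis, sign) orientations
  are named; a zero half-range reports a degenerate sensor; an m+ below m−
  reports the inverted axis.
* Trace files round-trip losslessly to ≤ 1e-9 g (9-decimal text output).
* A 4 Hz altitude channel shares the acceleration t₀; nothing in typical tag
  documentation fixes this alignment, so the shared-clock convention is an
  explicit assumption of this package.

## Test-suite problem sizes

Synthetic fixtures are sized for sharp assertions at interactive runtimes:
bench sequences of 6 × 10 s at 40 Hz, flight traces of 10–30 s at 40–150 Hz,
and brute-force oracles (O(n²) enumerations, O(n·w) smoothing references) on
series of a few hundred to a few thousand samples. Parameter-recovery sweeps
use seeded property tests over offsets ±0.05 g and gains 0.95–1.05 —
slightly wider than the measured real-tag spread. None of the quantitative
claims depend on longer records: calibration accuracy is set by window
length × rate (400 samples per dwell gives a standard error of
0.005/√400 = 0.00025 g under the 0.005 g noise condition, comfortably inside
the asserted ±0.003 g offset and ±0.005 gain bounds).

## Known limitations

* Calibration is static-range only (±1 g), linear, and temperature-blind.
* Archives lacking all six orientations cannot be corrected, only assessed;
  this is a property of the protocol, not of the implementation.
* The steady-flapping splitter is greedy left-to-right; it guarantees every
  emitted segment satisfies all criteria but does not globally maximise
  selected duration.
* Nearest-neighbour altitude upsampling introduces up to half an altitude
  sample period of timing slack in level-flight boundaries.
* The cycle-profile interpolation of empty percent bins assumes the signal
  varies smoothly within a few percent of the cycle, which holds for
  wingbeat-scale signals sampled at ≥ 20 samples per cycle.
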