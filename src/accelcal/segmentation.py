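"""Selection of analysis-grade flight segments.

Two rule families are implemented, matching the two field situations the
toolkit serves:

* **steady flapping** (wind-tunnel style): runs where the 1 s-smoothed
  VeDBA stays between 0.75 and 3 g, varies by less than 1 g, shows no
  trend over time (operationalised as an OLS slope bound), lasts at
  least 2 s, with the first second of each flight bout discarded;
* **level flapping** (seabird style, altitude-gated): samples where
  VeDBA exceeds 0.3 g and the barometric altitude rate stays within
  ±0.5 m/s, or — for minute-scale comparisons — fixed-length windows in
  which the altitude spans less than 5 m and flapping never stops.

Every returned segment carries the criterion values that admitted it and
is re-checked against its thresholds before being returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .dba import DbaSeries, moving_mean
from .io_traces import AltitudeChannel


@dataclass
class SegmentCriteria:
    """Thresholds for one named selection rule set.  Units: g, seconds,
    metres, m/s; ``trend_slope_max`` is in g per second."""

    rule_set: str = "steady_flapping"
    min_duration_s: float = 2.0
    vedba_smooth_window_s: float | None = 1.0
    vedba_low: float = 0.75
    vedba_high: float = 3.0
    max_vedba_range: float = 1.0
    trend_slope_max: float = 0.1
    discard_head_s: float = 1.0
    altitude_rate_low: float = -0.5
    altitude_rate_high: float = 0.5
    max_altitude_range_m: float = 5.0
    window_s: float = 60.0
    window_step_s: float = 1.0
    strict: bool = False

    def __post_init__(self) -> None:
        if not self.vedba_low < self.vedba_high:
            raise ValueError("vedba_low must be below vedba_high")
        if not self.altitude_rate_low < self.altitude_rate_high:
            raise ValueError("altitude_rate_low must be below altitude_rate_high")


PRESETS: dict[str, SegmentCriteria] = {
    # wind-tunnel pigeons: 0.75-3 g band on 1 s-smoothed VeDBA, <1 g range,
    # no trend, >=2 s (~10 wingbeats), first second of each flight dropped
    "pigeon_wind_tunnel": SegmentCriteria(rule_set="steady_flapping"),
    # seabird level flapping: VeDBA > 0.3 g, altitude rate within +/-0.5 m/s
    "seabird_level": SegmentCriteria(
        rule_set="level_flapping",
        vedba_smooth_window_s=None,
        vedba_low=0.3,
        vedba_high=float("inf"),
        min_duration_s=2.0,
    ),
    # kittiwake minute sections: 60 s windows, <5 m altitude span,
    # uninterrupted flapping (VeDBA floor throughout)
    "kittiwake_minutes": SegmentCriteria(
        rule_set="level_windows",
        vedba_smooth_window_s=None,
        vedba_low=0.3,
        vedba_high=float("inf"),
        min_duration_s=60.0,
        window_s=60.0,
        max_altitude_range_m=5.0,
    ),
}


def get_preset(name: str) -> SegmentCriteria:
    try:
        return replace(PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(PRESETS))}"
        ) from None


@dataclass
class FlightSegment:
    """A half-open run of acceleration samples admitted by a rule set,
    with every criterion value the rule checked recorded in
    ``diagnostics``."""

    start_index: int
    end_index: int
    rule_set: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.end_index - self.start_index

    def duration_s(self, rate: float) -> float:
        return self.n / rate


def altitude_rate(altitude: np.ndarray | AltitudeChannel, rate_hz: float | None = None,
                  span_s: float = 1.0) -> np.ndarray:
    """Rate of change of altitude in m/s on the altitude clock.

    Central difference over ``span_s`` (default 1 s); at the edges the
    span truncates to a forward/backward difference over the available
    samples.  Exact for linear climbs everywhere.
    """
    if isinstance(altitude, AltitudeChannel):
        rate_hz = altitude.rate
        altitude = altitude.values
    if rate_hz is None:
        raise ValueError("rate_hz required when altitude is a bare array")
    alt = np.asarray(altitude, dtype=float)
    if alt.size < 2:
        raise ValueError("altitude rate needs at least two samples")
    k = max(1, int(round(rate_hz * span_s / 2.0)))
    n = alt.size
    idx = np.arange(n)
    lo = np.maximum(idx - k, 0)
    hi = np.minimum(idx + k, n - 1)
    return (alt[hi] - alt[lo]) * rate_hz / (hi - lo)


def resample_to_accel(series: np.ndarray, series_rate: float, n_out: int,
                      out_rate: float, offset_s: float = 0.0) -> np.ndarray:
    """Nearest-neighbour upsampling of a low-rate channel onto the
    acceleration clock (sample i of the output sits at time i/out_rate)."""
    series = np.asarray(series, dtype=float)
    t = np.arange(n_out) / out_rate
    j = np.clip(np.round((t - offset_s) * series_rate).astype(int),
                0, series.size - 1)
    return series[j]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal half-open runs of True in a boolean mask."""
    edges = np.flatnonzero(np.diff(np.concatenate(
        [[0], mask.view(np.int8), [0]])))
    return [(int(a), int(b)) for a, b in zip(edges[::2], edges[1::2])]


def _ols_slope(y: np.ndarray, rate: float) -> float:
    """Slope of y against time (g/s) by ordinary least squares."""
    t = np.arange(y.size) / rate
    return float(stats.linregress(t, y).slope)


class _TrendWindow:
    """Incrementally extendable window tracking range and OLS slope of a
    series against time; O(1) per appended sample."""

    def __init__(self, y: np.ndarray, rate: float, start: int):
        self.y = y
        self.rate = rate
        self.start = start
        self.end = start
        self.lo = np.inf
        self.hi = -np.inf
        self.st = self.sy = self.sty = self.stt = 0.0

    def push(self) -> None:
        v = self.y[self.end]
        t = (self.end - self.start) / self.rate
        self.lo = min(self.lo, v)
        self.hi = max(self.hi, v)
        self.st += t
        self.sy += v
        self.sty += t * v
        self.stt += t * t
        self.end += 1

    @property
    def n(self) -> int:
        return self.end - self.start

    @property
    def value_range(self) -> float:
        return self.hi - self.lo

    @property
    def slope(self) -> float:
        n = self.n
        denom = n * self.stt - self.st**2
        if denom == 0:
            return 0.0
        return (n * self.sty - self.st * self.sy) / denom


def select_steady_flapping(dba: DbaSeries, criteria: SegmentCriteria
                           ) -> list[FlightSegment]:
    """Select steady sustained flapping from a VeDBA series.

    Candidate samples are those whose smoothed VeDBA lies strictly inside
    (vedba_low, vedba_high), after discarding ``discard_head_s`` from the
    start of each flight bout (a maximal run above ``vedba_low``).  Each
    candidate run is consumed left to right: a segment grows from its
    anchor until adding a sample would push the smoothed-VeDBA range to
    ``max_vedba_range`` or the |OLS slope| above ``trend_slope_max``; at
    the first violation the segment is closed and testing restarts at the
    violating sample.  Runs or remainders shorter than ``min_duration_s``
    are dropped.  With ``strict=True`` a run violating range or trend
    anywhere is discarded whole instead of split.
    """
    rate = dba.sampling_rate
    if criteria.vedba_smooth_window_s:
        smoothed = moving_mean(dba.vedba, criteria.vedba_smooth_window_s, rate)
    else:
        smoothed = dba.vedba
    min_len = max(2, int(round(criteria.min_duration_s * rate)))
    head = int(round(criteria.discard_head_s * rate))

    candidate = np.zeros(dba.n, dtype=bool)
    for b0, b1 in _runs(smoothed > criteria.vedba_low):  # flight bouts
        b0 += head
        if b1 > b0:
            candidate[b0:b1] = smoothed[b0:b1] < criteria.vedba_high

    segments: list[FlightSegment] = []
    for r0, r1 in _runs(candidate):
        if r1 - r0 < min_len:
            continue
        if criteria.strict:
            seg = _try_segment(smoothed, rate, r0, r1, criteria)
            if seg is not None:
                segments.append(seg)
            continue
        anchor = r0
        while anchor + min_len <= r1:
            win = _TrendWindow(smoothed, rate, anchor)
            for _ in range(min_len):
                win.push()
            if not _admissible(win, criteria):
                anchor += 1
                continue
            while win.end < r1:
                win.push()
                if not _admissible(win, criteria):
                    win.end -= 1  # retract the violating sample
                    break
            segments.append(_emit(smoothed, rate, anchor, win.end, criteria))
            anchor = win.end
    return segments


def _admissible(win: _TrendWindow, criteria: SegmentCriteria) -> bool:
    return (win.value_range < criteria.max_vedba_range
            and abs(win.slope) <= criteria.trend_slope_max)


def _try_segment(smoothed: np.ndarray, rate: float, i0: int, i1: int,
                 criteria: SegmentCriteria) -> FlightSegment | None:
    seg = _emit(smoothed, rate, i0, i1, criteria, check=False)
    d = seg.diagnostics
    ok = (d["vedba_range"] < criteria.max_vedba_range
          and abs(d["trend_slope"]) <= criteria.trend_slope_max)
    return seg if ok else None


def _emit(smoothed: np.ndarray, rate: float, i0: int, i1: int,
          criteria: SegmentCriteria, check: bool = True) -> FlightSegment:
    chunk = smoothed[i0:i1]
    seg = FlightSegment(
        start_index=i0,
        end_index=i1,
        rule_set=criteria.rule_set,
        diagnostics={
            "vedba_min": float(chunk.min()),
            "vedba_max": float(chunk.max()),
            "vedba_range": float(chunk.max() - chunk.min()),
            "trend_slope": _ols_slope(chunk, rate),
            "duration_s": (i1 - i0) / rate,
        },
    )
    if check:
        d = seg.diagnostics
        assert d["vedba_range"] < criteria.max_vedba_range
        assert abs(d["trend_slope"]) <= criteria.trend_slope_max + 1e-12
        assert d["duration_s"] >= criteria.min_duration_s - 1e-9
    return seg


def select_level_flapping(dba: DbaSeries, alt_rate: np.ndarray,
                          criteria: SegmentCriteria) -> list[FlightSegment]:
    """Select level flapping flight: per-sample VeDBA above the floor AND
    altitude rate within [altitude_rate_low, altitude_rate_high]; maximal
    runs of at least ``min_duration_s`` are returned.

    ``alt_rate`` must already be on the acceleration clock (same length
    as the VeDBA series); use :func:`altitude_rate` +
    :func:`resample_to_accel` to build it from a low-rate channel.
    """
    alt_rate = np.asarray(alt_rate, dtype=float)
    if alt_rate.size != dba.n:
        raise ValueError(
            "alt_rate must be resampled onto the acceleration clock "
            f"(got {alt_rate.size} samples for {dba.n} acceleration samples)"
        )
    rate = dba.sampling_rate
    if criteria.vedba_smooth_window_s:
        vedba = moving_mean(dba.vedba, criteria.vedba_smooth_window_s, rate)
    else:
        vedba = dba.vedba
    mask = ((vedba > criteria.vedba_low)
            & (alt_rate >= criteria.altitude_rate_low)
            & (alt_rate <= criteria.altitude_rate_high))
    min_len = max(1, int(round(criteria.min_duration_s * rate)))
    segments = []
    for i0, i1 in _runs(mask):
        if i1 - i0 < min_len:
            continue
        segments.append(FlightSegment(
            start_index=i0, end_index=i1, rule_set=criteria.rule_set,
            diagnostics={
                "vedba_min": float(vedba[i0:i1].min()),
                "alt_rate_min": float(alt_rate[i0:i1].min()),
                "alt_rate_max": float(alt_rate[i0:i1].max()),
                "duration_s": (i1 - i0) / rate,
            },
        ))
    return segments


def select_level_windows(dba: DbaSeries, altitude: AltitudeChannel,
                         criteria: SegmentCriteria) -> list[FlightSegment]:
    """Select fixed-length level-flight windows ranked by altitude span.

    Slides a ``window_s`` window (step ``window_step_s``) over the trace;
    a window qualifies when the altitude max−min stays below
    ``max_altitude_range_m`` and VeDBA exceeds ``vedba_low`` at every
    acceleration sample (the uninterrupted-flapping check).  Qualifying
    windows are ranked by altitude range ascending and greedily selected
    to be non-overlapping.
    """
    if altitude is None:
        raise ValueError("level-window selection requires an altitude channel")
    rate = dba.sampling_rate
    wlen = int(round(criteria.window_s * rate))
    step = max(1, int(round(criteria.window_step_s * rate)))
    candidates = []
    for i0 in range(0, dba.n - wlen + 1, step):
        i1 = i0 + wlen
        t0, t1 = i0 / rate, i1 / rate
        j0 = max(0, int(np.ceil((t0 - altitude.offset_s) * altitude.rate - 1e-9)))
        j1 = min(altitude.n,
                 int(np.ceil((t1 - altitude.offset_s) * altitude.rate - 1e-9)))
        if j1 - j0 < 2:
            continue
        alt = altitude.values[j0:j1]
        alt_range = float(alt.max() - alt.min())
        vmin = float(dba.vedba[i0:i1].min())
        if alt_range < criteria.max_altitude_range_m and vmin > criteria.vedba_low:
            candidates.append((alt_range, i0, i1, vmin))
    candidates.sort(key=lambda c: (c[0], c[1]))
    chosen: list[FlightSegment] = []
    taken: list[tuple[int, int]] = []
    for alt_range, i0, i1, vmin in candidates:
        if any(i0 < b and a < i1 for a, b in taken):
            continue
        taken.append((i0, i1))
        chosen.append(FlightSegment(
            start_index=i0, end_index=i1, rule_set=criteria.rule_set,
            diagnostics={"altitude_range_m": alt_range, "vedba_min": vmin,
                         "duration_s": (i1 - i0) / rate},
        ))
    chosen.sort(key=lambda s: s.diagnostics["altitude_range_m"])
    return chosen
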