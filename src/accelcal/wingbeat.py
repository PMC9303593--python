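"""Wingbeat detection, cycle metrics, normalized cycle profiles and
paired-tag comparison.

A wingbeat cycle is the interval between successive peaks of the
(dynamic) heave acceleration — the downstroke peaks.  Its inverse
duration is the wingbeat frequency; its heave max−min is the signal
amplitude.  Because peak *timing* is unaffected by per-axis offset or
gain errors, wingbeat frequency is robust to sensor miscalibration and
tag placement, whereas amplitude scales linearly with any gain applied
to heave — the central quality-control distinction this module exposes.

Cycle-normalized profiles express each axis against percentage
progression through the wingbeat (0–100) averaged over a fixed number of
cycles, so that tags sampling at different phases or rates can be
compared point by point; a linear regression between the profiles of two
simultaneously deployed tags measures their relative signal amplitude as
a slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .dba import moving_mean
from .io_traces import AccelTrace

#: plausible wingbeat frequency bands (Hz) by study system
FREQUENCY_BANDS = {"pigeon": (3.0, 10.0), "seabird": (2.0, 6.0)}


@dataclass
class WingbeatCycle:
    """One peak-to-peak wingbeat: duration, frequency and heave amplitude."""

    start_peak_index: int
    end_peak_index: int
    duration_s: float
    frequency_hz: float
    amplitude_g: float


@dataclass
class CycleProfile:
    """Mean per-axis acceleration at each whole percent of the wingbeat
    cycle (101 bins, 0–100), averaged over ``n_cycles`` wingbeats and
    circularly smoothed over ``smoothing_window_pct`` bins.

    ``interpolated_bins`` lists percent bins that received no datapoint
    from any cycle (possible when a cycle spans fewer samples than bins)
    and were filled by linear interpolation before smoothing."""

    percent: np.ndarray
    mean_heave: np.ndarray
    mean_surge: np.ndarray
    mean_sway: np.ndarray
    n_cycles: int
    smoothing_window_pct: int
    interpolated_bins: tuple = ()

    def axis(self, name: str) -> np.ndarray:
        return {"heave": self.mean_heave, "surge": self.mean_surge,
                "sway": self.mean_sway}[name]


@dataclass
class ProfileRegression:
    slope: float
    intercept: float
    r_squared: float
    axis: str


@dataclass
class ArcDisplacement:
    """Arc length swept by a tag at radius r from the pitch-rotation
    centre over a pitch excursion of ``pitch_deg`` degrees."""

    meters: float
    radius_m: float
    pitch_deg: float
    note: str = ("arc length 2πr·(P/360); some sources print the ratio "
                 "inverted (360/P), which is dimensionally inconsistent")

    def __float__(self) -> float:
        return self.meters


def detect_wingbeat_peaks(heave: np.ndarray, rate: float,
                          smooth_samples: int = 3,
                          band_hz: tuple[float, float] = FREQUENCY_BANDS["seabird"],
                          prominence_fraction: float = 0.3) -> np.ndarray:
    """Detect wingbeat (downstroke) peaks in a heave series.

    The series is smoothed over ``smooth_samples`` (a running mean; 3
    samples ≈ 0.075 s at 40 Hz); local maxima separated by at least one
    period of the band's upper frequency are kept when their prominence
    exceeds ``prominence_fraction`` of the running signal amplitude
    (max−min over ~2 slow periods).  Returned indices refer to positions
    in the original series.
    """
    low, high = band_hz
    if low <= 0:
        raise ValueError("band low frequency must be positive")
    if rate <= 2 * high:
        raise ValueError(
            f"sampling rate {rate} Hz too low for a {high} Hz band (Nyquist)"
        )
    y = np.asarray(heave, dtype=float)
    if smooth_samples > 1:
        y = moving_mean(y, smooth_samples / rate, rate)
    min_sep = max(1, int(math.floor(rate / high)))
    peaks, props = signal.find_peaks(y, distance=min_sep, prominence=0.0)
    if peaks.size == 0:
        return peaks
    amp_window_s = 2.0 / low
    running_amp = (moving_mean(_rolling_range(y, amp_window_s, rate),
                               amp_window_s, rate))
    keep = props["prominences"] > prominence_fraction * running_amp[peaks]
    return peaks[keep]


def _rolling_range(y: np.ndarray, window_s: float, rate: float) -> np.ndarray:
    """Centred rolling max−min (truncated at the edges)."""
    w = max(1, int(round(window_s * rate)))
    if w % 2 == 0:
        w += 1
    h = w // 2
    n = y.size
    out = np.empty(n)
    # sliding extrema via stride tricks on a padded copy would allocate
    # n*w; a plain loop over window edges is fine at trace scales
    from numpy.lib.stride_tricks import sliding_window_view
    if n >= w:
        sw = sliding_window_view(y, w)
        core = sw.max(axis=1) - sw.min(axis=1)
        out[h:n - h] = core
        for i in range(h):
            out[i] = y[: i + h + 1].max() - y[: i + h + 1].min()
            out[n - 1 - i] = y[n - 1 - i - h:].max() - y[n - 1 - i - h:].min()
    else:
        out[:] = y.max() - y.min()
    return out


def cycles_from_peaks(heave: np.ndarray, peaks: np.ndarray, rate: float
                      ) -> list[WingbeatCycle]:
    """Build one :class:`WingbeatCycle` per consecutive peak pair.

    Duration is the peak-to-peak interval; frequency its inverse;
    amplitude the heave max−min within the half-open cycle."""
    heave = np.asarray(heave, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    cycles = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        dur = (p1 - p0) / rate
        seg = heave[p0:p1]
        cycles.append(WingbeatCycle(
            start_peak_index=int(p0), end_peak_index=int(p1),
            duration_s=dur, frequency_hz=1.0 / dur,
            amplitude_g=float(seg.max() - seg.min()),
        ))
    return cycles


def mean_cycle_profile(trace: AccelTrace, peaks: np.ndarray,
                       n_cycles: int = 10, smooth_pct: int = 10,
                       smooth: bool = True) -> CycleProfile:
    """Average the heave/surge/sway signal over ``n_cycles`` wingbeats on
    a common 0–100 percent grid.

    Each sample of a cycle is assigned to percent
    ``floor(100·(t−t_start)/(t_end−t_start))``; the terminal peak sample
    alone lands in bin 100.  Per whole percent, each axis is averaged
    across the first ``n_cycles`` cycles, then (when ``smooth``)
    circularly smoothed over ``smooth_pct`` bins — the wingbeat being
    periodic, bins 0 and 100 are neighbours.
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < n_cycles + 1:
        raise ValueError(
            f"need {n_cycles} complete cycles ({n_cycles + 1} peaks), "
            f"got {max(peaks.size - 1, 0)}"
        )
    axes = {r: trace.role(r) for r in ("heave", "surge", "sway")}
    sums = {r: np.zeros(101) for r in axes}
    counts = np.zeros(101)
    for c in range(n_cycles):
        p0, p1 = peaks[c], peaks[c + 1]
        idx = np.arange(p0, p1)
        pct = np.floor(100.0 * (idx - p0) / (p1 - p0)).astype(int)
        np.add.at(counts, pct, 1.0)
        for r, series in axes.items():
            np.add.at(sums[r], pct, series[p0:p1])
        counts[100] += 1.0
        for r, series in axes.items():
            sums[r][100] += series[p1]
    means = {}
    empty = np.flatnonzero(counts == 0)
    filled = np.flatnonzero(counts > 0)
    for r in axes:
        m = np.full(101, np.nan)
        m[filled] = sums[r][filled] / counts[filled]
        if empty.size:
            m[empty] = np.interp(empty, filled, m[filled])
        if smooth and smooth_pct > 1:
            m = _circular_mean(m, smooth_pct)
        means[r] = m
    return CycleProfile(
        percent=np.arange(101),
        mean_heave=means["heave"], mean_surge=means["surge"],
        mean_sway=means["sway"],
        n_cycles=n_cycles,
        smoothing_window_pct=smooth_pct if smooth else 0,
        interpolated_bins=tuple(int(i) for i in empty),
    )


def _circular_mean(y: np.ndarray, window: int) -> np.ndarray:
    """Moving mean treating the percent axis as periodic (bin 100 wraps to
    bin 0; both hold the downstroke peak)."""
    if window % 2 == 0:
        window += 1
    h = window // 2
    # bins 0 and 100 are the same phase: wrap over the 100 distinct bins
    core = y[:100]
    padded = np.concatenate([core[-h:], core, core[:h]])
    kernel = np.ones(window) / window
    sm = np.convolve(padded, kernel, mode="valid")
    return np.concatenate([sm, sm[:1]])


def regress_profiles(profile_a: CycleProfile, profile_b: CycleProfile,
                     axis: str) -> ProfileRegression:
    """OLS of tag A's per-percent means on tag B's for one axis; the slope
    is the relative signal amplitude of A with respect to B."""
    a = profile_a.axis(axis)
    b = profile_b.axis(axis)
    if a.size != b.size:
        raise ValueError("profiles are on different percent grids")
    if np.ptp(b) == 0:
        raise ValueError("reference profile has zero variance")
    fit = stats.linregress(b, a)
    return ProfileRegression(slope=float(fit.slope),
                             intercept=float(fit.intercept),
                             r_squared=float(fit.rvalue**2), axis=axis)


def arc_displacement(r: float, pitch_deg: float) -> ArcDisplacement:
    """Arc length 2πr·(P/360) travelled by a sensor at radius ``r`` from
    the centre of pitch rotation over a pitch excursion of ``P`` degrees.

    Explains why tags mounted further from the rotation centre see larger
    acceleration excursions over the wingbeat cycle."""
    if r < 0:
        raise ValueError("radius must be non-negative")
    if not 0 < pitch_deg <= 360:
        raise ValueError("pitch must lie in (0, 360] degrees")
    return ArcDisplacement(meters=2.0 * math.pi * r * (pitch_deg / 360.0),
                           radius_m=r, pitch_deg=pitch_deg)
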