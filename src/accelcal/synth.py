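"""Synthetic accelerometer traces with machine-readable ground truth.

Three generators cover the pipeline's study conditions:

* :func:`make_static_sequence` — a six-orientation bench calibration
  recording: the tag dwells motionless with each axis up and down,
  joined by smooth 90° rotations whose transient norm excursions mimic
  the centripetal "dips and peaks between flat tops" of a hand-rotated
  tag.  Sensor corruption is applied as the exact inverse of the
  two-step correction (``corrupted = true/gain + offset``), so a fitted
  calibration can invert it exactly in the noiseless limit.
* :func:`make_flight_trace` — flapping flight: heave carries the gravity
  projection plus a sinusoidal wingbeat of known (possibly
  time-varying) frequency and amplitude, surge a phase-lagged copy at
  reduced amplitude, sway a small residual; glide intervals silence the
  oscillation; a 4 Hz barometric altitude channel is attached.
* :func:`make_paired_tags` — two simultaneous tags on one bird whose
  dynamic components differ by known per-axis placement ratios.

Every generator returns its ground truth (window boundaries, peak
times, per-cycle frequency/amplitude, level-flight mask) so recovery
tests compare pipeline output to the generator's truth, never to other
pipeline output.  Identical seeds reproduce traces bit-for-bit;
changing the seed changes only the noise, never the ground-truth
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_traces import AccelTrace, AltitudeChannel

DEFAULT_SEED = 20220207

#: measured spread of real tag errors: offsets −0.043…0.025 g,
#: gains 0.97…1.023 — the generator's realistic default ranges
REALISTIC_OFFSET_RANGE = (-0.043, 0.025)
REALISTIC_GAIN_RANGE = (0.97, 1.023)

_AXES = ("x", "y", "z")


@dataclass
class SensorErrorModel:
    """Per-axis true offset (g) and gain with optional white noise.

    Corruption is the inverse of the two-step correction:
    ``corrupted = true/gain + offset (+ noise)``, so that a calibration
    fitted from the corrupted data inverts it exactly."""

    offset: dict = field(default_factory=lambda: dict.fromkeys(_AXES, 0.0))
    gain: dict = field(default_factory=lambda: dict.fromkeys(_AXES, 1.0))
    noise_sd: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if any(self.gain[a] <= 0 for a in _AXES):
            raise ValueError("true gains must be positive")

    @classmethod
    def random(cls, seed: int = DEFAULT_SEED,
               offset_range: tuple = REALISTIC_OFFSET_RANGE,
               gain_range: tuple = REALISTIC_GAIN_RANGE,
               noise_sd: float = 0.0) -> "SensorErrorModel":
        rng = np.random.default_rng(seed)
        return cls(
            offset={a: float(rng.uniform(*offset_range)) for a in _AXES},
            gain={a: float(rng.uniform(*gain_range)) for a in _AXES},
            noise_sd=noise_sd,
            seed=seed,
        )

    def corrupt(self, xyz: np.ndarray, rng: np.random.Generator | None = None
                ) -> np.ndarray:
        """Apply the sensor error (and noise when ``noise_sd > 0``) to an
        (n, 3) array of true accelerations."""
        out = np.empty_like(xyz, dtype=float)
        for j, a in enumerate(_AXES):
            out[:, j] = xyz[:, j] / self.gain[a] + self.offset[a]
        if self.noise_sd > 0:
            rng = rng or np.random.default_rng(self.seed)
            out = out + rng.normal(0.0, self.noise_sd, out.shape)
        return out


#: dwell order chosen so consecutive gravity vectors are orthogonal,
#: making every transition a simple 90° great-circle rotation
_ORIENTATION_ORDER = (("x", 1), ("y", 1), ("z", 1), ("x", -1), ("y", -1), ("z", -1))


def _gravity(axis: str, sign: int) -> np.ndarray:
    v = np.zeros(3)
    v[_AXES.index(axis)] = float(sign)
    return v


def make_static_sequence(model: SensorErrorModel, rate: float = 40.0,
                         dwell_s: float = 10.0, transition_s: float = 2.0,
                         rotation_bump_g: float = 0.2
                         ) -> tuple[AccelTrace, pd.DataFrame]:
    """Generate a six-orientation bench calibration recording.

    Six motionless dwells of ``dwell_s`` (one per (axis, sign) die face)
    joined by ``transition_s`` rotations; during rotation the norm
    transiently rises by up to ``rotation_bump_g`` (centripetal-like
    excursion), which keeps transitions out of any stillness detector.
    Returns the corrupted trace and a ground-truth table with the true
    window boundaries and (axis, sign) labels.
    """
    if dwell_s < 1:
        raise ValueError("dwell_s must be at least 1 s")
    n_dwell = int(round(dwell_s * rate))
    n_trans = int(round(transition_s * rate))
    chunks = []
    truth_rows = []
    pos = 0
    for k, (axis, sign) in enumerate(_ORIENTATION_ORDER):
        g = _gravity(axis, sign)
        chunks.append(np.tile(g, (n_dwell, 1)))
        truth_rows.append({"axis": axis, "sign": sign,
                           "start_index": pos, "end_index": pos + n_dwell,
                           "true_x": g[0], "true_y": g[1], "true_z": g[2]})
        pos += n_dwell
        if k < len(_ORIENTATION_ORDER) - 1 and n_trans > 0:
            g_next = _gravity(*_ORIENTATION_ORDER[k + 1])
            tau = (np.arange(n_trans) + 0.5) / n_trans
            ang = tau * (np.pi / 2.0)  # orthogonal pair: 90° great circle
            arc = (np.outer(np.cos(ang), g) + np.outer(np.sin(ang), g_next))
            # norm excursion present from the very first transition sample,
            # so no stillness detector can mistake rotation for a dwell
            bump = 1.0 + rotation_bump_g * (0.75 + 0.25 * np.sin(np.pi * tau))
            chunks.append(arc * bump[:, None])
            pos += n_trans
    true_xyz = np.vstack(chunks)
    rng = np.random.default_rng(model.seed)
    corrupted = model.corrupt(true_xyz, rng)
    trace = AccelTrace(
        sampling_rate=rate,
        ax=corrupted[:, 0], ay=corrupted[:, 1], az=corrupted[:, 2],
        meta={"synthetic": "static_sequence", "seed": model.seed,
              "true_offset": dict(model.offset), "true_gain": dict(model.gain)},
    )
    return trace, pd.DataFrame(truth_rows)


def _piecewise(spec, t: np.ndarray) -> np.ndarray:
    """Evaluate a scalar or (times, values) piecewise-linear profile."""
    if np.isscalar(spec):
        return np.full(t.size, float(spec))
    times, values = spec
    return np.interp(t, np.asarray(times, float), np.asarray(values, float))


@dataclass
class FlightModel:
    """Parameters of a synthetic flapping-flight bout.

    Frequency/amplitude/altitude profiles are either scalars or
    ``(times, values)`` pairs interpolated linearly over time.  The
    surge oscillation leads heave by ``surge_phase_lag`` cycles (the
    heave-surge loop of a real wingbeat).  ``glide_intervals`` silence
    the oscillation over [start_s, end_s) spans.
    """

    frequency_hz: object = 5.0
    heave_amplitude_g: object = 1.0
    surge_ratio: float = 0.4
    surge_phase_lag: float = 0.25
    sway_amplitude_g: float = 0.05
    baseline_gravity: tuple = (0.0, 0.0, 1.0)
    glide_intervals: tuple = ()
    altitude_profile: object = 100.0
    altitude_rate_hz: float = 4.0
    noise_sd: float = 0.0
    seed: int = DEFAULT_SEED


def make_flight_trace(model: FlightModel, rate: float = 40.0,
                      duration_s: float = 30.0
                      ) -> tuple[AccelTrace, dict]:
    """Generate a flapping-flight trace with attached altitude channel.

    heave = gravity projection + A(t)·sin(2π φ(t)) with φ = ∫f dt, so
    heave peaks sit at φ = k + 1/4.  Ground truth returned:
    ``peak_times`` (s), ``peak_indices`` (nearest sample),
    ``cycle_frequency_hz``/``cycle_amplitude_g`` per peak-to-peak cycle,
    ``flapping_mask`` per sample and ``altitude`` ground truth.
    """
    t = np.arange(int(round(duration_s * rate))) / rate
    f = _piecewise(model.frequency_hz, t)
    nyq = rate / 2.0
    if np.any(f >= nyq) or np.any(f <= 0):
        raise ValueError(f"frequency profile must stay inside (0, {nyq}) Hz")
    amp = _piecewise(model.heave_amplitude_g, t).copy()
    flapping = np.ones(t.size, dtype=bool)
    for g0, g1 in model.glide_intervals:
        flapping &= ~((t >= g0) & (t < g1))
    amp[~flapping] = 0.0

    # phase at sample midpoints-free cumulative trapezoid of f
    phi = np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) / 2.0)]) / rate
    osc = np.sin(2.0 * np.pi * phi)
    osc_surge = np.sin(2.0 * np.pi * (phi + model.surge_phase_lag))

    g0 = np.asarray(model.baseline_gravity, dtype=float)
    rng = np.random.default_rng(model.seed)
    dyn = np.zeros((t.size, 3))
    dyn[:, 2] = amp * osc  # heave (z); peak-to-trough amplitude = 2A
    dyn[:, 0] = model.surge_ratio * amp * osc_surge
    dyn[:, 1] = model.sway_amplitude_g * np.sin(2.0 * np.pi * (phi + 0.5))
    xyz = g0[None, :] + dyn
    if model.noise_sd > 0:
        xyz = xyz + rng.normal(0.0, model.noise_sd, xyz.shape)

    n_alt = int(round(duration_s * model.altitude_rate_hz))
    t_alt = np.arange(n_alt) / model.altitude_rate_hz
    alt = _piecewise(model.altitude_profile, t_alt)

    # true heave peaks: phi crossing k + 1/4 while flapping
    peak_times, peak_indices = [], []
    targets = np.arange(np.floor(phi[0]), np.ceil(phi[-1]) + 1) + 0.25
    for target in targets:
        j = np.searchsorted(phi, target)
        if j <= 0 or j >= phi.size:
            continue
        frac = (target - phi[j - 1]) / (phi[j] - phi[j - 1])
        tp = t[j - 1] + frac / rate
        i = int(round(tp * rate))
        if 0 <= i < t.size and flapping[i]:
            peak_times.append(tp)
            peak_indices.append(i)
    peak_times = np.array(peak_times)
    peak_indices = np.array(peak_indices, dtype=int)
    with np.errstate(divide="ignore"):
        cyc_dur = np.diff(peak_times)
    truth = {
        "peak_times": peak_times,
        "peak_indices": peak_indices,
        "cycle_frequency_hz": 1.0 / cyc_dur if cyc_dur.size else np.array([]),
        "cycle_amplitude_g": np.array(
            [2.0 * amp[peak_indices[i]:peak_indices[i + 1] + 1].max()
             for i in range(len(peak_indices) - 1)]
        ) if len(peak_indices) > 1 else np.array([]),
        "flapping_mask": flapping,
        "altitude_true": alt,
        "frequency_profile": f,
        "amplitude_profile": amp,
    }
    trace = AccelTrace(
        sampling_rate=rate,
        ax=xyz[:, 0], ay=xyz[:, 1], az=xyz[:, 2],
        altitude=AltitudeChannel(alt, rate=model.altitude_rate_hz),
        meta={"synthetic": "flight", "seed": model.seed},
    )
    return trace, truth


def make_paired_tags(model: FlightModel,
                     placement_ratio_heave: float = 1.0,
                     placement_ratio_surge: float = 1.0,
                     placement_ratio_sway: float = 1.0,
                     independent_noise_sd: float = 0.0,
                     rate: float = 150.0, duration_s: float = 10.0,
                     seeds: tuple[int, int] = (DEFAULT_SEED, DEFAULT_SEED + 1)
                     ) -> tuple[AccelTrace, AccelTrace, dict]:
    """Generate two simultaneous tags with known per-axis amplitude ratios.

    Tag A carries the base dynamic signal; tag B's dynamic components are
    scaled by the placement ratios (same gravity baseline).  Independent
    Gaussian noise (``independent_noise_sd``) is added to each tag.
    """
    for r in (placement_ratio_heave, placement_ratio_surge, placement_ratio_sway):
        if r <= 0:
            raise ValueError("placement ratios must be positive")
    base = FlightModel(**{**model.__dict__, "noise_sd": 0.0})
    trace, truth = make_flight_trace(base, rate=rate, duration_s=duration_s)
    g0 = np.asarray(model.baseline_gravity, dtype=float)
    dyn = trace.xyz() - g0[None, :]
    scale = np.array([placement_ratio_surge, placement_ratio_sway,
                      placement_ratio_heave])  # x=surge, y=sway, z=heave
    xyz_a = g0[None, :] + dyn
    xyz_b = g0[None, :] + dyn * scale[None, :]
    rng_a = np.random.default_rng(seeds[0])
    rng_b = np.random.default_rng(seeds[1])
    if independent_noise_sd > 0:
        xyz_a = xyz_a + rng_a.normal(0.0, independent_noise_sd, xyz_a.shape)
        xyz_b = xyz_b + rng_b.normal(0.0, independent_noise_sd, xyz_b.shape)
    make = lambda xyz, tag: AccelTrace(  # noqa: E731
        sampling_rate=rate, ax=xyz[:, 0], ay=xyz[:, 1], az=xyz[:, 2],
        altitude=trace.altitude,
        meta={"synthetic": "paired", "tag": tag},
    )
    truth = {**truth, "placement_ratios": {"heave": placement_ratio_heave,
                                           "surge": placement_ratio_surge,
                                           "sway": placement_ratio_sway}}
    return make(xyz_a, "A"), make(xyz_b, "B"), truth
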