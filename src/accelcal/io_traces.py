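"""Reading, writing and windowing tri-axial accelerometer traces.

The working unit throughout the package is *g* (standard gravity,
9.80665 m/s²): every behavioural threshold in the toolkit (0.3 g,
0.75–3 g, the 1 g static ideal) is expressed in g, so unit conversion
happens only at I/O time.  Time is handled with half-open intervals
[start, end); sample ``i`` covers ``t0 + i/rate`` to ``t0 + (i+1)/rate``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

STANDARD_GRAVITY = 9.80665  # m/s² per g

_ROLES = frozenset({"heave", "surge", "sway"})


class TraceError(ValueError):
    """Raised for malformed trace files or invalid trace operations."""


@dataclass
class AltitudeChannel:
    """Barometric altitude in metres, possibly at a lower rate than the
    acceleration channels and sharing the trace's t0 (plus ``offset_s``)."""

    values: np.ndarray
    rate: float
    offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise TraceError("altitude rate must be positive")
        if self.values.ndim != 1 or self.values.size < 1:
            raise TraceError("altitude series must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise TraceError("altitude series contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class ChannelConfig:
    """Column mapping and unit declaration for delimited trace files.

    Columns may be names (header present) or integer indices (headerless).
    ``axis_roles`` maps the body-frame roles heave (dorsoventral), surge
    (anteroposterior) and sway (lateral) onto the x/y/z channels and must
    be a bijection.
    """

    ax: object = "ax"
    ay: object = "ay"
    az: object = "az"
    time: object | None = None
    altitude: object | None = None
    axis_roles: dict = field(
        default_factory=lambda: {"surge": "x", "sway": "y", "heave": "z"}
    )
    units: str = "g"  # "g" or "m/s2"
    delimiter: str = ","
    header: bool = True
    sampling_rate: float | None = None
    altitude_rate: float | None = None

    def __post_init__(self) -> None:
        if self.units not in ("g", "m/s2"):
            raise TraceError(f"unknown acceleration units {self.units!r}")
        roles = dict(self.axis_roles)
        if set(roles) != _ROLES or len(set(roles.values())) != 3 or not set(
            roles.values()
        ) <= {"x", "y", "z"}:
            raise TraceError(
                "axis_roles must map heave/surge/sway one-to-one onto x/y/z"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "ChannelConfig":
        """Load a config from a YAML (or JSON — YAML superset) file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class AccelTrace:
    """Uniformly sampled tri-axial acceleration record in g.

    ``ax``/``ay``/``az`` are the sensor's x/y/z channels; which channel
    plays which body-frame role (heave/surge/sway) is recorded in
    ``axis_roles``.  ``altitude`` is an optional barometric channel in
    metres with its own rate, sharing the trace clock.
    """

    sampling_rate: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    t0: float = 0.0
    altitude: AltitudeChannel | None = None
    axis_roles: dict = field(
        default_factory=lambda: {"surge": "x", "sway": "y", "heave": "z"}
    )
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.sampling_rate <= 0:
            raise TraceError("sampling_rate must be positive")
        if not (self.ax.shape == self.ay.shape == self.az.shape):
            raise TraceError("acceleration channels differ in length")
        if self.ax.ndim != 1 or self.ax.size < 1:
            raise TraceError("acceleration channels must be non-empty 1-D arrays")
        for name, a in (("ax", self.ax), ("ay", self.ay), ("az", self.az)):
            if not np.all(np.isfinite(a)):
                raise TraceError(f"channel {name} contains non-finite values")

    @property
    def n(self) -> int:
        return self.ax.size

    @property
    def duration_s(self) -> float:
        return self.n / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.sampling_rate

    def xyz(self) -> np.ndarray:
        """Return the three channels stacked as an (n, 3) array."""
        return np.column_stack([self.ax, self.ay, self.az])

    def channel(self, name: str) -> np.ndarray:
        return {"x": self.ax, "y": self.ay, "z": self.az}[name]

    def role(self, role: str) -> np.ndarray:
        """Return the channel playing a body-frame role (heave/surge/sway)."""
        return self.channel(self.axis_roles[role])


def _columns(df: pd.DataFrame, key: object) -> pd.Series:
    if isinstance(key, int):
        return df.iloc[:, key]
    return df[key]


def read_trace(path: str | Path, cfg: ChannelConfig) -> AccelTrace:
    """Read a delimited text trace file into an :class:`AccelTrace`.

    Values declared in m/s² are converted to g.  The sampling rate comes
    from ``cfg.sampling_rate`` when given; otherwise it is inferred from
    the timestamp column (median inter-sample interval).  If both are
    available and disagree by more than 1%, a warning is issued and the
    declared rate wins.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=cfg.delimiter, header=0 if cfg.header else None)
    try:
        ax = _columns(df, cfg.ax).to_numpy(dtype=float)
        ay = _columns(df, cfg.ay).to_numpy(dtype=float)
        az = _columns(df, cfg.az).to_numpy(dtype=float)
    except (KeyError, IndexError) as exc:
        raise TraceError(f"missing acceleration channel in {path}: {exc}") from exc

    t0 = 0.0
    inferred = None
    if cfg.time is not None:
        t = _columns(df, cfg.time).to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size > 1 and np.any(dt <= 0):
            raise TraceError(f"non-monotonic timestamps in {path}")
        t0 = float(t[0])
        if t.size > 1:
            inferred = 1.0 / float(np.median(dt))

    rate = cfg.sampling_rate
    if rate is None:
        if inferred is None:
            raise TraceError(
                "sampling rate neither declared in config nor inferable "
                "from a timestamp column"
            )
        rate = inferred
    elif inferred is not None and abs(inferred - rate) / rate > 0.01:
        warnings.warn(
            f"inferred rate {inferred:.4g} Hz differs from declared "
            f"{rate:.4g} Hz by >1%; declared rate wins",
            stacklevel=2,
        )

    if cfg.units == "m/s2":
        ax = ax / STANDARD_GRAVITY
        ay = ay / STANDARD_GRAVITY
        az = az / STANDARD_GRAVITY

    altitude = None
    if cfg.altitude is not None:
        alt = _columns(df, cfg.altitude).to_numpy(dtype=float)
        altitude = AltitudeChannel(alt, rate=cfg.altitude_rate or rate)

    return AccelTrace(
        sampling_rate=float(rate),
        ax=ax,
        ay=ay,
        az=az,
        t0=t0,
        altitude=altitude,
        axis_roles=dict(cfg.axis_roles),
        meta={"source": str(path)},
    )


def read_altitude(path: str | Path, rate: float, column: object = "altitude",
                  delimiter: str = ",", header: bool = True,
                  offset_s: float = 0.0) -> AltitudeChannel:
    """Read a standalone altitude file (e.g. a 4 Hz pressure-derived channel)."""
    df = pd.read_csv(path, sep=delimiter, header=0 if header else None)
    return AltitudeChannel(
        _columns(df, column).to_numpy(dtype=float), rate=rate, offset_s=offset_s
    )


def write_trace(trace: AccelTrace, path: str | Path,
                cfg: ChannelConfig | None = None) -> list[Path]:
    """Write a trace as delimited text, one row per sample, 9-decimal
    precision (lossless to well beyond the 1e-9 g round-trip contract).

    When the trace carries an altitude channel at a different rate, a
    second file ``<stem>.alt<suffix>`` is written with the altitude series
    on its own clock (shared t0).  Returns the list of paths written.
    """
    cfg = cfg or ChannelConfig()
    path = Path(path)
    if trace.n < 1:  # defensive: AccelTrace forbids this at construction
        raise TraceError("refusing to write an empty trace")
    df = pd.DataFrame(
        {"time": trace.times, "ax": trace.ax, "ay": trace.ay, "az": trace.az}
    )
    df.to_csv(path, sep=cfg.delimiter, index=False, float_format="%.9f")
    written = [path]
    if trace.altitude is not None:
        alt_path = path.with_name(path.stem + ".alt" + path.suffix)
        alt = trace.altitude
        t = trace.t0 + alt.offset_s + np.arange(alt.n) / alt.rate
        pd.DataFrame({"time": t, "altitude": alt.values}).to_csv(
            alt_path, sep=cfg.delimiter, index=False, float_format="%.9f"
        )
        written.append(alt_path)
    return written


def slice_trace(trace: AccelTrace, start_s: float, end_s: float) -> AccelTrace:
    """Return the half-open sub-trace [start_s, end_s), times relative to t0.

    Sample ``i`` belongs to the slice iff ``start_s <= i/rate < end_s``;
    the altitude channel, when present, is sliced consistently on the
    shared clock.
    """
    if not (0.0 <= start_s < end_s <= trace.duration_s + 1e-9):
        raise TraceError(
            f"invalid slice [{start_s}, {end_s}) of a {trace.duration_s:.3f} s trace"
        )
    r = trace.sampling_rate
    i0 = int(math.ceil(start_s * r - 1e-9))
    i1 = int(math.ceil(end_s * r - 1e-9))
    i1 = min(i1, trace.n)
    if i1 <= i0:
        raise TraceError("empty slice")
    altitude = None
    if trace.altitude is not None:
        alt = trace.altitude
        j0 = int(math.ceil((start_s - alt.offset_s) * alt.rate - 1e-9))
        j1 = int(math.ceil((end_s - alt.offset_s) * alt.rate - 1e-9))
        j0 = max(j0, 0)
        j1 = min(j1, alt.n)
        if j1 > j0:
            altitude = AltitudeChannel(
                alt.values[j0:j1],
                rate=alt.rate,
                offset_s=alt.offset_s + j0 / alt.rate - start_s,
            )
    return replace(
        trace,
        ax=trace.ax[i0:i1],
        ay=trace.ay[i0:i1],
        az=trace.az[i0:i1],
        t0=trace.t0 + i0 / r,
        altitude=altitude,
        meta={**trace.meta, "sliced": (start_s, end_s)},
    )
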