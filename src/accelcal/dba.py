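"""Static/dynamic decomposition and dynamic body acceleration (DBA).

The raw signal of each axis is split into a *static* component — the
slowly varying gravity projection, estimated by a centred running mean
(2 s by default) — and a *dynamic* remainder attributable to body
movement.  VeDBA, the vectorial dynamic body acceleration

    VeDBA = (x_D² + y_D² + z_D²)^0.5,

is the Euclidean norm of the three dynamic components and the standard
proxy for movement-based energy expenditure.  ODBA (the absolute-sum
variant) is computed alongside for comparability but is never used by
any default in this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_traces import AccelTrace


def moving_mean(series: np.ndarray, window_s: float, rate: float) -> np.ndarray:
    """Centred running mean with a window of ``round(window_s × rate)``
    samples, forced odd for a symmetric centre; at the boundaries the
    window truncates to the available samples rather than padding.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot smooth an empty series")
    w = int(round(window_s * rate))
    if w < 1:
        raise ValueError("window shorter than one sample")
    if w % 2 == 0:
        w += 1
    h = w // 2
    c = np.concatenate([[0.0], np.cumsum(x)])
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    return (c[hi + 1] - c[lo]) / (hi + 1 - lo)


@dataclass
class DbaSeries:
    """Per-sample static/dynamic decomposition of a trace plus VeDBA.

    ``edge_exclusion_s`` is half the static window: statistics computed
    on this series exclude that much at each end by default, where the
    truncated smoothing window biases the static estimate.
    """

    vedba: np.ndarray
    odba: np.ndarray
    static_x: np.ndarray
    static_y: np.ndarray
    static_z: np.ndarray
    dynamic_x: np.ndarray
    dynamic_y: np.ndarray
    dynamic_z: np.ndarray
    sampling_rate: float
    static_window_s: float
    edge_policy: str = "truncate"

    @property
    def n(self) -> int:
        return self.vedba.size

    @property
    def edge_exclusion_s(self) -> float:
        return self.static_window_s / 2.0

    def interior(self) -> slice:
        """Slice excluding ``edge_exclusion_s`` at each end (non-empty)."""
        k = int(np.ceil(self.edge_exclusion_s * self.sampling_rate))
        if 2 * k >= self.n:
            return slice(0, self.n)
        return slice(k, self.n - k)

    def dynamic(self, channel: str) -> np.ndarray:
        return {"x": self.dynamic_x, "y": self.dynamic_y,
                "z": self.dynamic_z}[channel]


def compute_dba(trace: AccelTrace, static_window_s: float = 2.0) -> DbaSeries:
    """Decompose a trace and compute VeDBA.

    static = per-axis centred running mean over ``static_window_s``;
    dynamic = raw − static; VeDBA = per-sample norm of the dynamics.
    """
    if trace.duration_s < static_window_s:
        raise ValueError(
            f"trace of {trace.duration_s:.2f} s shorter than the "
            f"{static_window_s} s static window"
        )
    rate = trace.sampling_rate
    static = {c: moving_mean(trace.channel(c), static_window_s, rate)
              for c in ("x", "y", "z")}
    dynamic = {c: trace.channel(c) - static[c] for c in ("x", "y", "z")}
    stacked = np.column_stack([dynamic["x"], dynamic["y"], dynamic["z"]])
    return DbaSeries(
        vedba=np.linalg.norm(stacked, axis=1),
        odba=np.abs(stacked).sum(axis=1),
        static_x=static["x"], static_y=static["y"], static_z=static["z"],
        dynamic_x=dynamic["x"], dynamic_y=dynamic["y"], dynamic_z=dynamic["z"],
        sampling_rate=rate,
        static_window_s=static_window_s,
    )


def mean_vedba(dba: DbaSeries, start_index: int | None = None,
               end_index: int | None = None, *,
               exclude_edges: bool = True) -> float:
    """Arithmetic mean VeDBA over a half-open sample segment (whole series
    when no bounds given).  By default the first and last half static
    window of the *series* are excluded; pass ``exclude_edges=False`` to
    average every sample."""
    lo = 0 if start_index is None else start_index
    hi = dba.n if end_index is None else end_index
    if exclude_edges:
        interior = dba.interior()
        lo = max(lo, interior.start)
        hi = min(hi, interior.stop)
    if hi <= lo:
        raise ValueError("empty segment")
    return float(np.mean(dba.vedba[lo:hi]))
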