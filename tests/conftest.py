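import numpy as np
import pytest

from accelcal import AccelTrace, DbaSeries


@pytest.fixture
def constant_trace() -> AccelTrace:
    """10 s motionless trace at 40 Hz with gravity on +z."""
    n = 400
    return AccelTrace(sampling_rate=40.0, ax=np.zeros(n), ay=np.zeros(n),
                      az=np.ones(n))


def make_dba_from_vedba(vedba: np.ndarray, rate: float = 40.0) -> DbaSeries:
    """Wrap a hand-crafted VeDBA series in a DbaSeries for segmentation
    tests (decomposition fields zeroed; only vedba is consulted)."""
    z = np.zeros_like(vedba)
    return DbaSeries(vedba=np.asarray(vedba, float), odba=np.abs(vedba),
                     static_x=z, static_y=z, static_z=z,
                     dynamic_x=z, dynamic_y=z, dynamic_z=z,
                     sampling_rate=rate, static_window_s=2.0)


def sinusoid_trace(freq: float = 5.0, amp: float = 1.0, rate: float = 150.0,
                   duration_s: float = 10.0, phase: float = 0.0) -> AccelTrace:
    """Flapping-like trace: heave (z) = 1 g gravity + amp·sin(2πft+φ)."""
    t = np.arange(int(duration_s * rate)) / rate
    return AccelTrace(
        sampling_rate=rate,
        ax=np.zeros(t.size), ay=np.zeros(t.size),
        az=1.0 + amp * np.sin(2 * np.pi * freq * t + phase),
    )
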