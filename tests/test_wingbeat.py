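import numpy as np
import pytest

from accelcal import (
    FlightModel,
    SensorErrorModel,
    AccelTrace,
    apply_calibration,
    arc_displacement,
    compute_dba,
    cycles_from_peaks,
    detect_wingbeat_peaks,
    make_flight_trace,
    make_paired_tags,
    mean_cycle_profile,
    regress_profiles,
)
from accelcal.calibration import CalibrationModel
from conftest import sinusoid_trace

PIGEON_BAND = (3.0, 10.0)


class TestDetectPeaks:
    def test_pure_sinusoid_peak_count_and_spacing(self):
        trace = sinusoid_trace(freq=5.0, amp=1.0, rate=150.0, duration_s=10.0)
        peaks = detect_wingbeat_peaks(trace.az, 150.0, band_hz=PIGEON_BAND)
        assert 49 <= peaks.size <= 50
        spacing = np.diff(peaks)
        assert np.all(np.abs(spacing - 30) <= 1)  # 150 Hz / 5 Hz

    def test_constant_series_no_peaks(self):
        assert detect_wingbeat_peaks(np.ones(1000), 150.0,
                                     band_hz=PIGEON_BAND).size == 0

    def test_noisy_flapping_recovers_generator_peaks(self):
        model = FlightModel(frequency_hz=5.0, heave_amplitude_g=1.0,
                            noise_sd=0.05, seed=101)
        trace, truth = make_flight_trace(model, rate=150.0, duration_s=10.0)
        dba = compute_dba(trace)
        peaks = detect_wingbeat_peaks(dba.dynamic_z, 150.0, band_hz=PIGEON_BAND)
        true_idx = truth["peak_indices"]
        assert abs(peaks.size - true_idx.size) <= 1
        matched = sum(np.min(np.abs(true_idx - p)) <= 2 for p in peaks)
        assert matched / peaks.size >= 0.95

    def test_rate_below_nyquist_is_error(self):
        with pytest.raises(ValueError, match="Nyquist"):
            detect_wingbeat_peaks(np.ones(100), 15.0, band_hz=PIGEON_BAND)


class TestCycles:
    def test_sinusoid_cycle_frequency_and_amplitude(self):
        trace = sinusoid_trace(freq=5.0, amp=1.0, rate=150.0, duration_s=10.0)
        peaks = detect_wingbeat_peaks(trace.az, 150.0, band_hz=PIGEON_BAND)
        cycles = cycles_from_peaks(trace.az, peaks, 150.0)
        for c in cycles:
            assert c.frequency_hz == pytest.approx(5.0, abs=0.2)
            assert c.amplitude_g == pytest.approx(2.0, abs=0.05)

    def test_two_peaks_quarter_second_apart(self):
        heave = np.zeros(100)
        cycles = cycles_from_peaks(heave, np.array([10, 47]), 148.0)
        assert len(cycles) == 1
        assert cycles[0].frequency_hz == pytest.approx(4.0)

    def test_fewer_than_two_peaks_empty(self):
        assert cycles_from_peaks(np.zeros(10), np.array([3]), 40.0) == []

    def test_variable_frequency_tracks_generator_truth(self):
        model = FlightModel(
            frequency_hz=([0.0, 10.0], [4.0, 6.0]),  # linear 4→6 Hz chirp
            heave_amplitude_g=1.0, seed=7)
        trace, truth = make_flight_trace(model, rate=150.0, duration_s=10.0)
        dba = compute_dba(trace)
        peaks = detect_wingbeat_peaks(dba.dynamic_z, 150.0, band_hz=PIGEON_BAND)
        cycles = cycles_from_peaks(dba.dynamic_z, peaks, 150.0)
        true_freq = truth["cycle_frequency_hz"]
        est = np.array([c.frequency_hz for c in cycles])
        # compare overlapping cycles (detection may drop an edge cycle)
        m = min(est.size, true_freq.size)
        assert np.all(np.abs(est[:m] - true_freq[:m]) / true_freq[:m] < 0.05)


class TestCycleProfile:
    def test_peak_anchored_sinusoid_profile_geometry(self):
        trace = sinusoid_trace(freq=5.0, amp=1.0, rate=150.0, duration_s=10.0)
        peaks = detect_wingbeat_peaks(trace.az, 150.0, band_hz=PIGEON_BAND)
        prof = mean_cycle_profile(trace, peaks)
        hi = int(np.argmax(prof.mean_heave))
        lo = int(np.argmin(prof.mean_heave))
        assert hi in (0, 1, 99, 100)
        assert abs(lo - 50) <= 2

    def test_deterministic_for_identical_input(self):
        trace, _ = make_flight_trace(FlightModel(noise_sd=0.02, seed=5),
                                     rate=150.0, duration_s=10.0)
        peaks = detect_wingbeat_peaks(compute_dba(trace).dynamic_z, 150.0,
                                      band_hz=PIGEON_BAND)
        a = mean_cycle_profile(trace, peaks)
        b = mean_cycle_profile(trace, peaks)
        np.testing.assert_array_equal(a.mean_heave, b.mean_heave)
        np.testing.assert_array_equal(a.mean_surge, b.mean_surge)

    def test_matches_brute_force_grouping_oracle(self):
        trace, _ = make_flight_trace(FlightModel(noise_sd=0.02, seed=9),
                                     rate=150.0, duration_s=10.0)
        peaks = detect_wingbeat_peaks(compute_dba(trace).dynamic_z, 150.0,
                                      band_hz=PIGEON_BAND)
        prof = mean_cycle_profile(trace, peaks, n_cycles=10, smooth=False)
        for role in ("heave", "surge", "sway"):
            series = trace.role(role)
            buckets = {p: [] for p in range(101)}
            for c in range(10):
                p0, p1 = peaks[c], peaks[c + 1]
                for i in range(p0, p1):
                    pct = int(np.floor(100.0 * (i - p0) / (p1 - p0)))
                    buckets[pct].append(series[i])
                buckets[100].append(series[p1])
            for p in range(101):
                if buckets[p]:
                    assert prof.axis(role)[p] == pytest.approx(
                        np.mean(buckets[p]), abs=1e-12)

    def test_too_few_cycles_error_reports_count(self):
        trace = sinusoid_trace(freq=5.0, amp=1.0, rate=150.0, duration_s=1.0)
        peaks = detect_wingbeat_peaks(trace.az, 150.0, band_hz=PIGEON_BAND)
        with pytest.raises(ValueError, match="cycles"):
            mean_cycle_profile(trace, peaks, n_cycles=10)


class TestProfileRegression:
    def make_profile(self, seed=0, scale=1.0):
        # peak samples land on sample centres at 150/32 Hz, so detection
        # is tie-free and the scaled copy keeps identical peak indices
        trace, _ = make_flight_trace(FlightModel(seed=seed,
                                                 frequency_hz=4.6875),
                                     rate=150.0, duration_s=10.0)
        if scale != 1.0:
            g = 1.0  # gravity baseline on z
            trace = AccelTrace(sampling_rate=150.0, ax=trace.ax * scale,
                               ay=trace.ay * scale,
                               az=g + (trace.az - g) * scale,
                               altitude=trace.altitude)
        peaks = detect_wingbeat_peaks(compute_dba(trace).dynamic_z, 150.0,
                                      band_hz=PIGEON_BAND)
        return mean_cycle_profile(trace, peaks)

    def test_profile_vs_itself(self):
        prof = self.make_profile()
        reg = regress_profiles(prof, prof, "heave")
        assert reg.slope == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.r_squared == pytest.approx(1.0)

    def test_scaled_profile_recovers_scale(self):
        base = self.make_profile()
        scaled = self.make_profile(scale=1.2)
        reg = regress_profiles(scaled, base, "heave")
        assert reg.slope == pytest.approx(1.2, abs=1e-6)
        assert reg.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_paired_tags_recover_placement_ratios(self):
        a, b, truth = make_paired_tags(
            FlightModel(frequency_hz=6.0, heave_amplitude_g=1.0),
            placement_ratio_heave=1.2, placement_ratio_surge=0.76,
            independent_noise_sd=0.01, rate=150.0, duration_s=10.0)
        profs = {}
        for tag, trace in (("a", a), ("b", b)):
            peaks = detect_wingbeat_peaks(compute_dba(trace).dynamic_z, 150.0,
                                          band_hz=PIGEON_BAND)
            profs[tag] = mean_cycle_profile(trace, peaks)
        heave = regress_profiles(profs["b"], profs["a"], "heave")
        surge = regress_profiles(profs["b"], profs["a"], "surge")
        assert heave.slope == pytest.approx(1.2, rel=0.05)
        assert surge.slope == pytest.approx(0.76, rel=0.05)

    def test_noisy_surge_ratio_within_ten_percent(self):
        a, b, _ = make_paired_tags(
            FlightModel(frequency_hz=6.0, heave_amplitude_g=1.0),
            placement_ratio_surge=0.76, independent_noise_sd=0.1,
            rate=150.0, duration_s=10.0)
        profs = []
        for trace in (a, b):
            peaks = detect_wingbeat_peaks(compute_dba(trace).dynamic_z, 150.0,
                                          band_hz=PIGEON_BAND)
            profs.append(mean_cycle_profile(trace, peaks))
        reg = regress_profiles(profs[1], profs[0], "surge")
        assert reg.slope == pytest.approx(0.76, rel=0.10)
        assert reg.r_squared < 1.0

    def test_zero_variance_reference_is_error(self):
        prof = self.make_profile()
        import dataclasses
        flat = dataclasses.replace(prof, mean_heave=np.ones(101))
        with pytest.raises(ValueError, match="variance"):
            regress_profiles(prof, flat, "heave")


class TestCalibrationInvariance:
    """Sensor offset/gain errors must not move wingbeat peak times, and
    amplitude must scale exactly with a heave gain — the core reason
    frequency is trusted on uncalibrated archives while amplitude is not."""

    def test_frequency_invariant_under_sensor_corruption(self):
        trace, _ = make_flight_trace(FlightModel(seed=3, frequency_hz=4.6875), rate=150.0,
                                     duration_s=10.0)
        model = SensorErrorModel(offset={"x": 0.04, "y": -0.02, "z": 0.03},
                                 gain={"x": 1.05, "y": 0.95, "z": 1.04})
        xyz = model.corrupt(trace.xyz())
        corrupted = AccelTrace(sampling_rate=150.0, ax=xyz[:, 0],
                               ay=xyz[:, 1], az=xyz[:, 2])
        freqs = {}
        for label, tr in (("clean", trace), ("corrupted", corrupted)):
            dyn = compute_dba(tr).dynamic_z
            peaks = detect_wingbeat_peaks(dyn, 150.0, band_hz=PIGEON_BAND)
            freqs[label] = [c.frequency_hz
                            for c in cycles_from_peaks(dyn, peaks, 150.0)]
        assert freqs["clean"] == freqs["corrupted"]

    def test_amplitude_scales_linearly_with_heave_gain(self):
        trace, _ = make_flight_trace(FlightModel(seed=3, frequency_hz=4.6875), rate=150.0,
                                     duration_s=10.0)
        gain = 1.3
        scaled = AccelTrace(sampling_rate=150.0, ax=trace.ax, ay=trace.ay,
                            az=trace.az * gain)
        amps = {}
        for label, tr in (("base", trace), ("scaled", scaled)):
            dyn = compute_dba(tr).dynamic_z
            peaks = detect_wingbeat_peaks(dyn, 150.0, band_hz=PIGEON_BAND)
            amps[label] = np.array([c.amplitude_g for c in
                                    cycles_from_peaks(dyn, peaks, 150.0)])
        np.testing.assert_allclose(amps["scaled"], gain * amps["base"],
                                   atol=1e-12)

    def test_profile_regression_recovers_applied_gain(self):
        trace, _ = make_flight_trace(FlightModel(seed=3, frequency_hz=4.6875), rate=150.0,
                                     duration_s=10.0)
        gain = 1.17
        cal = CalibrationModel(offset=dict.fromkeys("xyz", 0.0),
                               gain={"x": 1.0, "y": 1.0, "z": gain})
        scaled = apply_calibration(trace, cal)
        peaks = detect_wingbeat_peaks(compute_dba(trace).dynamic_z, 150.0,
                                      band_hz=PIGEON_BAND)
        prof_a = mean_cycle_profile(scaled, peaks)
        prof_b = mean_cycle_profile(trace, peaks)
        reg = regress_profiles(prof_a, prof_b, "heave")
        assert reg.slope == pytest.approx(gain, abs=1e-9)


class TestArcDisplacement:
    def test_full_circle(self):
        assert float(arc_displacement(1.0, 360.0)) == pytest.approx(2 * np.pi)

    def test_zero_radius(self):
        assert float(arc_displacement(0.0, 10.0)) == 0.0

    def test_tag_spacing_at_ten_degrees(self):
        # 4 cm between two back-mounted tags, 10° pitch excursion
        assert float(arc_displacement(0.04, 10.0)) == pytest.approx(
            2 * np.pi * 0.04 / 36.0)

    def test_linear_in_radius_and_pitch(self):
        base = float(arc_displacement(0.02, 15.0))
        assert float(arc_displacement(0.04, 15.0)) == pytest.approx(2 * base)
        assert float(arc_displacement(0.02, 30.0)) == pytest.approx(2 * base)

    def test_nonpositive_pitch_rejected(self):
        with pytest.raises(ValueError):
            arc_displacement(0.1, 0.0)
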