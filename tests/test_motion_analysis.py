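"""Running segmentation and flapping analysis."""
import numpy as np
import pytest
from scipy import signal as sg

from takeoffkit import (AccelSeries, GnssSeries, ParameterError,
                        count_flaps, cruising_direction, detect_running,
                        flap_frequency, hf_variance_series,
                        running_kinematics)
from takeoffkit.motion_analysis import FlappingBout, RunningPhase

FS = 100.0


def _accel(a_lat=None, a_dv=None, dur=120.0):
    t = np.arange(0, dur, 1 / FS)
    zeros = np.zeros(t.size)
    return AccelSeries(t, zeros if a_lat is None else a_lat,
                       zeros.copy(), zeros if a_dv is None else a_dv,
                       rate_hz=FS)


def _filtfilt_power_gain(band, fs):
    """In-band power gain of the zero-phase band-pass (frequency-domain)."""
    sos = sg.butter(4, band, btype="bandpass", fs=fs, output="sos")
    f, h = sg.sosfreqz(sos, worN=8192, fs=fs)
    return np.trapezoid(np.abs(h) ** 4, f) / (fs / 2)


class TestHfVariance:
    def test_white_noise_matches_inband_power(self, rng):
        x = rng.normal(0, 1, int(600 * FS))
        acc = _accel(a_lat=x, dur=600.0)
        var = hf_variance_series(acc)
        expected = _filtfilt_power_gain((5, 20), FS)  # sigma^2 = 1
        assert np.mean(var) == pytest.approx(expected, rel=0.2)

    def test_flap_band_tone_rejected(self):
        t = np.arange(0, 120, 1 / FS)
        tone = 2.0 * np.sin(2 * np.pi * 2.86 * t)  # 0.35 s flap period
        var = hf_variance_series(_accel(a_lat=tone))
        assert np.mean(var[2000:-2000]) < 0.01 * 2.0**2 / 2

    def test_inband_tone_closed_form(self):
        t = np.arange(0, 120, 1 / FS)
        tone = 2.0 * np.sin(2 * np.pi * 10.0 * t)
        var = hf_variance_series(_accel(a_lat=tone))
        assert np.median(var) == pytest.approx(2.0**2 / 2, rel=0.05)

    def test_infeasible_band_rejected(self):
        with pytest.raises(ParameterError):
            hf_variance_series(_accel(), band=(5.0, 60.0))


def _burst_accel(bounds_list, noise_sd=0.3, dur=120.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(0, dur, 1 / FS)
    a_lat = rng.normal(0, noise_sd, t.size)
    for (b0, b1) in bounds_list:
        m = (t >= b0) & (t < b1)
        n = int(m.sum())
        w = rng.normal(0, 1, n)
        sos = sg.butter(4, (6, 15), btype="bandpass", fs=FS, output="sos")
        burst = sg.sosfiltfilt(sos, w)
        a_lat[m] += 3.0 * burst / np.std(burst)
    return _accel(a_lat=a_lat, dur=dur)


class TestDetectRunning:
    def test_eight_second_burst_duration(self):
        acc = _burst_accel([(60.0, 68.0)])
        var = hf_variance_series(acc)
        ph = detect_running(acc, var, t_takeoff=63.0)
        assert ph.duration == pytest.approx(8.0, abs=0.6)

    def test_interior_gap_ends_the_phase(self):
        acc = _burst_accel([(60.0, 64.0), (66.0, 70.0)])
        var = hf_variance_series(acc)
        ph = detect_running(acc, var, t_takeoff=62.0)
        assert ph.t_end < 65.0  # second burst not annexed

    def test_flat_noise_gives_no_running(self):
        acc = _burst_accel([])
        var = hf_variance_series(acc)
        assert detect_running(acc, var, t_takeoff=60.0) is None

    def test_invariant_to_uniform_scaling(self):
        acc = _burst_accel([(60.0, 65.0)])
        var = hf_variance_series(acc)
        ph1 = detect_running(acc, var, 62.0)
        scaled = AccelSeries(acc.t, 7.5 * acc.a_lat, acc.a_long, acc.a_dv,
                             rate_hz=FS)
        ph2 = detect_running(scaled, hf_variance_series(scaled), 62.0)
        assert ph1.t_start == pytest.approx(ph2.t_start, abs=1e-9)
        assert ph1.t_end == pytest.approx(ph2.t_end, abs=1e-9)


class TestRunningKinematics:
    def _gnss(self, ve, vn, rate=5.0):
        ve, vn = np.asarray(ve, float), np.asarray(vn, float)
        t = np.arange(ve.size) / rate
        return GnssSeries(t, np.zeros_like(t), np.zeros_like(t), ve, vn,
                          np.zeros_like(t), rate_hz=rate)

    def test_constant_velocity(self):
        g = self._gnss(np.full(50, 3.0), np.full(50, 4.0))
        vr, theta = running_kinematics(g, RunningPhase(0.0, 5.0))
        assert vr == pytest.approx(5.0)
        assert theta == pytest.approx(np.arctan2(3, 4))

    def test_vector_mean_not_angle_mean(self):
        ve = np.array([1.0, 0.0])
        vn = np.array([0.0, 1.0])
        g = self._gnss(ve, vn)
        _, theta = running_kinematics(g, RunningPhase(0.0, 0.3))
        assert theta == pytest.approx(np.pi / 4)

    def test_ramp_end_speed(self):
        rate = 5.0
        tau = np.arange(0, 5.2, 1 / rate)
        v = 1.23 * tau
        g = self._gnss(v, np.zeros_like(v))
        vr, _ = running_kinematics(g, RunningPhase(0.0, 5.1))
        assert vr == pytest.approx(1.23 * 5.1, abs=0.15)


class TestCruisingDirection:
    def _track(self, bearing_deg, speed=10.0, dur=320.0, rate=5.0):
        t = np.arange(0, dur, 1 / rate)
        b = np.radians(bearing_deg)
        ve = np.full_like(t, speed * np.sin(b))
        vn = np.full_like(t, speed * np.cos(b))
        lat = -46.0 + np.cumsum(vn) / rate / 111194.9
        lon = 52.0 + np.cumsum(ve) / rate / (111194.9 *
                                             np.cos(np.radians(-46.0)))
        return GnssSeries(t, lat, lon, ve, vn, np.zeros_like(t),
                          rate_hz=rate)

    @pytest.mark.parametrize("bearing", [0.0, 90.0])
    def test_cardinal_directions(self, bearing):
        g = self._track(bearing)
        cd = cruising_direction(g, t_takeoff=5.0)
        assert np.degrees(cd) == pytest.approx(bearing, abs=1.0)

    def test_diagonal_matches_planar_oracle(self, rng):
        g = self._track(135.0)
        # jitter the velocities but keep the net drift
        cd = cruising_direction(g, t_takeoff=5.0)
        assert np.degrees(cd) == pytest.approx(135.0, abs=1.5)

    def test_insufficient_data_is_missing(self):
        g = self._track(0.0, dur=100.0)
        assert cruising_direction(g, t_takeoff=5.0) is None


def _flap_accel(count, freq, pause_after=None, pause_len=0.6,
                amp=3.0, noise_sd=0.3, seed=0, t_run_end=60.0):
    rng = np.random.default_rng(seed)
    t = np.arange(0, 120.0, 1 / FS)
    a_dv = rng.normal(0, noise_sd, t.size)
    chunks = [(count, 0.0)] if pause_after is None else [
        (pause_after, 0.0), (count - pause_after, pause_len)]
    t0 = t_run_end
    for n_cyc, gap in chunks:
        t0 += gap
        dur = n_cyc / freq
        m = (t >= t0) & (t < t0 + dur)
        a_dv[m] += amp * np.sin(2 * np.pi * freq * (t[m] - t0))
        t0 += dur
    return _accel(a_dv=a_dv)


class TestCountFlaps:
    def test_ten_cycles_counted_exactly(self):
        acc = _flap_accel(10, 2.5)
        assert count_flaps(acc, 60.0).count == 10

    def test_pure_noise_counts_zero(self):
        acc = _flap_accel(0, 2.5)
        assert count_flaps(acc, 60.0).count == 0

    def test_gap_rule_stops_at_pause(self):
        acc = _flap_accel(25, 2.7, pause_after=15, pause_len=0.6)
        assert count_flaps(acc, 60.0).count == 15

    def test_invariant_to_sign_flip(self):
        acc = _flap_accel(12, 2.5)
        flipped = AccelSeries(acc.t, acc.a_lat, acc.a_long, -acc.a_dv,
                              rate_hz=FS)
        assert count_flaps(acc, 60.0).count == \
            count_flaps(flipped, 60.0).count


class TestFlapFrequency:
    def test_known_tone_within_tenth_hz(self):
        acc = _flap_accel(10, 2.5)
        bout = count_flaps(acc, 60.0)
        bout = flap_frequency(acc, bout)
        assert bout.frequency == pytest.approx(2.5, abs=0.1)
        assert bout.freq_in_range

    def test_out_of_band_tone_flagged(self):
        t = np.arange(0, 120.0, 1 / FS)
        a_dv = 3.0 * np.sin(2 * np.pi * 1.0 * np.clip(t - 60.0, 0, 8))
        acc = _accel(a_dv=a_dv)
        bout = FlappingBout(count=8,
                            flap_times=list(60.25 + np.arange(8) / 1.0))
        bout = flap_frequency(acc, bout)
        assert bout.frequency == pytest.approx(1.0, abs=0.15)
        assert not bout.freq_in_range

    def test_tiny_bout_has_no_frequency(self):
        acc = _flap_accel(1, 2.5)
        bout = FlappingBout(count=1, flap_times=[60.1])
        bout = flap_frequency(acc, bout)
        assert bout.frequency is None and not bout.freq_in_range


def test_trip_motion_recovery(default_trip):
    from takeoffkit import detect_takeoffs, smooth_speed
    cfg, dep, truth = default_trip
    ev = detect_takeoffs(smooth_speed(dep.gnss), dep.gnss)[0]
    var = hf_variance_series(dep.accel)
    ph = detect_running(dep.accel, var, ev.t_takeoff)
    assert ph.duration == pytest.approx(cfg.run_duration, abs=0.6)
    vr, theta = running_kinematics(dep.gnss, ph)
    assert vr == pytest.approx(truth.iloc[0].run_end_speed, abs=0.8)
    bout = count_flaps(dep.accel, ph.t_end)
    assert bout.count == cfg.flap_count
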