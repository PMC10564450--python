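"""Running-phase segmentation and flapping analysis from acceleration.

Sea-surface running drives the legs asymmetrically, so it shows up as a
high-frequency (sub-0.2 s period) burst in the lateral acceleration —
distinct from the 0.25-0.4 s wing-flap component that can leak into the
lateral channel when a logger sits slightly tilted. The running detector
therefore band-passes the lateral channel to 5-20 Hz, takes a sliding
0.6 s variance, and thresholds at 2% of the local peak; the contiguous
above-threshold stretch containing the take-off moment is the running
phase, and any interior quiet gap ends it.

Because a centred sliding variance of a sharp burst crosses a 2%-of-peak
level about (0.5 - 0.02) * window outside each true edge, the reported
bounds are pulled inward by that amount (``edge_correction``); without it
durations carry a systematic +0.58 s bias.

Flapping after the running phase is read from the dorsoventral channel
band-passed to 1.8-4.0 Hz: flaps are peaks with prominence at least 6x
the floating-baseline median absolute deviation, counted until the
inter-flap interval first exceeds 0.5 s. Flap frequency is the peak of
the time-averaged continuous-wavelet power over 1-5 Hz; values outside
the 1.8-4.0 Hz detection band are flagged out-of-range.
"""
from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal
from scipy.ndimage import uniform_filter1d

from ._utils import DataError, ParameterError, azimuth, initial_bearing
from .io_logger import AccelSeries, GnssSeries

__all__ = ["RunningPhase", "FlappingBout", "hf_variance_series",
           "detect_running", "running_kinematics", "cruising_direction",
           "count_flaps", "flap_frequency"]

RUN_BAND = (5.0, 20.0)
VAR_WINDOW_S = 0.6
RUN_FRAC = 0.02
RUN_SEARCH_S = (-20.0, 20.0)
FLAP_BAND = (1.8, 4.0)
FLAP_GAP_S = 0.5
FLAP_PROMINENCE_MADS = 6.0


@dataclass
class RunningPhase:
    """Bounds and GNSS kinematics of one sea-surface run."""

    t_start: float
    t_end: float
    Vr: float | None = None          # speed at the end of the run, m/s
    takeoff_dir: float | None = None  # vector-mean direction, rad
    cruising_dir: float | None = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class FlappingBout:
    """Post-running flapping: count, flap times, spectral frequency."""

    count: int
    flap_times: list = field(default_factory=list)
    frequency: float | None = None
    freq_in_range: bool = False


def _bandpass(x, fs, band):
    lo, hi = band
    if hi >= fs / 2:
        raise ParameterError(
            f"band upper edge {hi} Hz infeasible at fs={fs} Hz"
        )
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def hf_variance_series(accel: AccelSeries, band=RUN_BAND,
                       var_window: float = VAR_WINDOW_S) -> np.ndarray:
    """Sliding variance of the band-passed lateral channel.

    Zero-phase band-pass then a centred moving variance over
    ``var_window`` seconds, aligned to the acceleration timestamps.
    """
    fs = accel.rate_hz
    if fs < 2 * band[1]:
        raise ParameterError(
            f"sampling rate {fs} Hz below 2x band upper edge {band[1]} Hz"
        )
    x = _bandpass(accel.a_lat, fs, band)
    k = max(2, int(round(var_window * fs)))
    m1 = uniform_filter1d(x, k, mode="nearest")
    m2 = uniform_filter1d(x * x, k, mode="nearest")
    return np.clip(m2 - m1 * m1, 0.0, None)


def detect_running(accel: AccelSeries, var_series: np.ndarray,
                   t_takeoff: float, search=RUN_SEARCH_S,
                   frac: float = RUN_FRAC,
                   var_window: float = VAR_WINDOW_S,
                   edge_correction: bool = True,
                   min_peak_ratio: float = 5.0) -> RunningPhase | None:
    """Locate the running phase around ``t_takeoff``.

    Thresholds the variance series at ``frac`` of its peak within
    ``t_takeoff + search`` and returns the contiguous above-threshold
    stretch containing (or nearest preceding) the take-off moment, with
    the window-induced edge bias removed. A relative threshold alone
    cannot say "no burst" — on flat noise 2% of the peak is below every
    sample — so the peak must also stand ``min_peak_ratio`` above the
    window's median variance; otherwise the no-running flag (None) is
    returned.
    """
    t = accel.t
    w = (t >= t_takeoff + search[0]) & (t <= t_takeoff + search[1])
    idx = np.flatnonzero(w)
    if idx.size == 0:
        return None
    v = var_series[idx]
    peak = v.max()
    if peak <= 0 or peak < min_peak_ratio * np.median(v):
        return None
    thr = frac * peak
    above = v >= thr
    from ._utils import contiguous_runs
    runs = contiguous_runs(above)
    if not runs:
        return None
    tw = t[idx]
    chosen = None
    for s, e in runs:
        if tw[s] <= t_takeoff <= tw[e - 1]:
            chosen = (s, e)
            break
    if chosen is None:
        preceding = [(s, e) for s, e in runs if tw[s] <= t_takeoff]
        if not preceding:
            return None
        chosen = preceding[-1]
    s, e = chosen
    t0, t1 = float(tw[s]), float(tw[e - 1])
    if edge_correction:
        corr = (0.5 - frac) * var_window
        t0, t1 = t0 + corr, t1 - corr
        if t1 <= t0:  # degenerate very short burst: keep midpoint width
            mid = 0.5 * (t0 + t1)
            t0, t1 = mid - 0.05, mid + 0.05
    return RunningPhase(t_start=t0, t_end=t1)


def running_kinematics(gnss: GnssSeries, phase: RunningPhase):
    """(Vr, takeoff_dir) from GNSS velocity over the running phase.

    Vr is the horizontal speed at the sample nearest the end of the run;
    the take-off direction is the azimuth of the vector-mean velocity
    (not the mean of angles).
    """
    m = (gnss.t >= phase.t_start) & (gnss.t <= phase.t_end)
    if not np.any(m):
        raise DataError("no GNSS samples within the running phase")
    i_end = int(np.argmin(np.abs(gnss.t - phase.t_end)))
    vr = float(gnss.speed[i_end])
    theta_t = float(azimuth(np.mean(gnss.v_east[m]),
                            np.mean(gnss.v_north[m])))
    return vr, theta_t


def cruising_direction(gnss: GnssSeries, t_takeoff: float,
                       lag: float = 300.0,
                       tol: float = 2.0) -> float | None:
    """Azimuth of the displacement from take-off to ``lag`` seconds later.

    Great-circle initial bearing between the GNSS positions nearest the
    two instants; None when either endpoint is missing (beyond ``tol``
    seconds from any sample).
    """
    i0 = int(np.argmin(np.abs(gnss.t - t_takeoff)))
    i1 = int(np.argmin(np.abs(gnss.t - (t_takeoff + lag))))
    if (abs(gnss.t[i0] - t_takeoff) > tol
            or abs(gnss.t[i1] - (t_takeoff + lag)) > tol or i1 <= i0):
        return None
    return float(initial_bearing(gnss.lat[i0], gnss.lon[i0],
                                 gnss.lat[i1], gnss.lon[i1]))


def count_flaps(accel: AccelSeries, t_run_end: float, band=FLAP_BAND,
                gap: float = FLAP_GAP_S, lead: float = 0.2,
                prominence_mads: float = FLAP_PROMINENCE_MADS,
                baseline_window: tuple[float, float] | None = None,
                max_window: float = 30.0) -> FlappingBout:
    """Count continuous flaps after the running phase.

    Band-passes the dorsoventral channel to ``band`` and finds peaks with
    prominence >= ``prominence_mads`` x the baseline MAD (baseline:
    floating, default 80-20 s before the run end). Counting starts just
    before ``t_run_end`` (``lead`` absorbs segmentation jitter) and stops
    at the first inter-flap interval exceeding ``gap``. A zero count is a
    valid outcome. Both signal polarities are searched and the richer
    peak chain is used, so a logger mounted upside-down (sign-flipped
    dorsoventral axis) yields the same count.
    """
    fs = accel.rate_hz
    x = _bandpass(accel.a_dv, fs, band)
    if baseline_window is None:
        baseline_window = (t_run_end - 80.0, t_run_end - 20.0)
    b0, b1 = baseline_window
    bm = (accel.t >= max(b0, accel.t[0])) & (accel.t < b1)
    base = x[bm] if np.any(bm) else x[: int(10 * fs)]
    mad = float(np.median(np.abs(base - np.median(base))))
    prom = prominence_mads * mad if mad > 0 else prominence_mads * 1e-12

    m = accel.t >= (t_run_end - lead)
    seg = x[m]
    tseg = accel.t[m]
    if seg.size < 3:
        return FlappingBout(count=0)
    # a lone noise excursion must not register as a single flap
    min_height = max(prom, 10.0 * mad) if mad > 0 else prom
    # search both polarities; a tilted or inverted mount flips the sign
    chains = []
    for sign in (1.0, -1.0):
        peaks, _ = signal.find_peaks(sign * seg, prominence=prom,
                                     height=min_height)
        chains.append(_chain_flaps(tseg, sign * seg, peaks,
                                   t_run_end - lead, gap, lead,
                                   max_window))
    times = max(chains, key=len)
    return FlappingBout(count=len(times), flap_times=times)


def _chain_flaps(tseg, seg, peaks, t0, gap, lead, max_window,
                 ring_frac=0.45):
    """Chain candidate peaks from ``t0`` under the inter-flap gap rule.

    The band-pass filter rings at the edges of a flap train, producing
    spurious peaks at roughly 30-40% of the flap amplitude and at flap
    spacing, which the gap rule alone cannot reject (genuine edge flaps
    sit above ~60%). Candidates are therefore gated at ``ring_frac`` of
    a robust flap-amplitude reference (the median height of the strong
    peaks in the first two seconds) before chaining.
    """
    if peaks.size == 0:
        return []
    tp = tseg[peaks]
    hp = seg[peaks]
    keep = tp <= t0 + max_window
    tp, hp = tp[keep], hp[keep]
    if tp.size == 0:
        return []
    early = hp[tp <= t0 + 2.0]
    if early.size:
        strong = early[early >= 0.6 * early.max()]
        ref = float(np.median(strong))
        ok = hp >= ring_frac * ref
        tp, hp = tp[ok], hp[ok]
    if tp.size == 0 or tp[0] - t0 > gap + lead:
        return []
    times = [float(tp[0])]
    for tpk in tp[1:]:
        if tpk - times[-1] > gap:
            break
        times.append(float(tpk))
    return times


def flap_frequency(accel: AccelSeries, bout: FlappingBout,
                   freq_range=(1.0, 5.0), valid_band=FLAP_BAND,
                   n_freqs: int = 161) -> FlappingBout:
    """Dominant flapping frequency of a bout via the CWT spectral peak.

    Computes a Morlet continuous wavelet transform of the dorsoventral
    acceleration over the bout, averages power over time, and takes the
    frequency of the maximum over 1-5 Hz. Bouts with fewer than 3 flaps
    get no frequency; frequencies outside ``valid_band`` are flagged
    out-of-range (and excluded from downstream statistics).
    """
    if bout.count < 3 or not bout.flap_times:
        bout.frequency = None
        bout.freq_in_range = False
        return bout
    fs = accel.rate_hz
    pad = 0.2
    t0, t1 = bout.flap_times[0] - pad, bout.flap_times[-1] + pad
    m = (accel.t >= t0) & (accel.t <= t1)
    x = accel.a_dv[m] - np.mean(accel.a_dv[m])
    freqs = np.linspace(freq_range[0], freq_range[1], n_freqs)
    wavelet = "morl"
    scales = pywt.frequency2scale(wavelet, freqs / fs)
    coeffs, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs)
    power = np.mean(np.abs(coeffs) ** 2, axis=1)
    f_peak = float(freqs[int(np.argmax(power))])
    bout.frequency = f_peak
    bout.freq_in_range = bool(valid_band[0] <= f_peak <= valid_band[1])
    return bout
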