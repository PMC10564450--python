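"""Significant wave height from pre-take-off floating motion.

While a bird sits on the sea surface its GNSS vertical displacement
tracks the surface elevation. The estimator:

1. resamples the floating window to a uniform grid and high-pass filters
   it at 0.07 Hz (zero-phase, 4th-order recursive) to strip GNSS drift;
2. splits the filtered elevation into individual waves at consecutive
   upward zero crossings (crossing times refined by linear
   interpolation; a sample exactly at zero counts as non-negative);
3. reports the significant wave height Hs as the mean height (crest-to-
   trough max - min) of the highest third of individual waves.

Estimates require at least 15 min of floating (the last 10 s before the
take-off are excluded) and at least 30 individual waves.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from ._utils import EligibilityError
from .io_logger import GnssSeries
from .takeoff_detect import TakeoffEvent

__all__ = ["IndividualWave", "WaveEstimate", "resample_uniform",
           "highpass_z", "zero_up_cross_waves", "significant_wave_height",
           "estimate_wave"]

MIN_WAVES = 30
DEFAULT_FC = 0.07
MIN_FLOAT_S = 900.0
TAIL_SKIP_S = 10.0


@dataclass
class IndividualWave:
    """One zero-up-crossing wave: bounds, crest-to-trough height, period."""

    t_start: float
    t_end: float
    height: float

    @property
    def period(self) -> float:
        return self.t_end - self.t_start


@dataclass
class WaveEstimate:
    """Significant wave height with its supporting wave statistics."""

    Hs: float
    n_waves: int
    mean_period: float
    window: tuple[float, float]

    def as_record(self) -> dict:
        return {"Hs": self.Hs, "n_waves": self.n_waves,
                "mean_period": self.mean_period,
                "window_start": self.window[0],
                "window_end": self.window[1]}


def resample_uniform(t, z, rate):
    """Linear interpolation of (t, z) onto a uniform grid at ``rate`` Hz."""
    t = np.asarray(t, dtype=float)
    z = np.asarray(z, dtype=float)
    tu = np.arange(t[0], t[-1], 1.0 / rate)
    return tu, np.interp(tu, t, z)


def highpass_z(z, fs, fc: float = DEFAULT_FC):
    """Zero-phase 4th-order high-pass at ``fc`` Hz (forward-backward).

    Requires at least 10/fc seconds of uniformly sampled input so the
    stopband (DC, GNSS drift) is meaningfully attenuated.
    """
    z = np.asarray(z, dtype=float)
    if z.size / fs < 10.0 / fc:
        raise EligibilityError(
            f"record of {z.size / fs:.0f} s too short for a {fc} Hz high-pass"
        )
    sos = signal.butter(4, fc, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, z)


def zero_up_cross_waves(z, t) -> list[IndividualWave]:
    """Individual waves delimited by consecutive upward zero crossings.

    An upward crossing occurs where z goes from < 0 to >= 0; incomplete
    leading/trailing segments are discarded. Crossing times are linearly
    interpolated between the bracketing samples; heights are max - min of
    the samples within the segment.
    """
    z = np.asarray(z, dtype=float)
    t = np.asarray(t, dtype=float)
    up = np.flatnonzero((z[:-1] < 0) & (z[1:] >= 0))
    if up.size < 2:
        return []
    # interpolated crossing times
    tc = t[up] + (t[up + 1] - t[up]) * (-z[up]) / (z[up + 1] - z[up])
    waves = []
    for k in range(up.size - 1):
        i0, i1 = up[k] + 1, up[k + 1] + 1
        seg = z[i0:i1]
        waves.append(IndividualWave(
            t_start=float(tc[k]), t_end=float(tc[k + 1]),
            height=float(seg.max() - seg.min()),
        ))
    return waves


def significant_wave_height(waves: list[IndividualWave],
                            min_waves: int = MIN_WAVES) -> WaveEstimate:
    """Hs = mean height of the highest third (ceil(n/3)) of waves."""
    n = len(waves)
    if n < min_waves:
        raise EligibilityError(
            f"only {n} individual waves; need >= {min_waves}"
        )
    heights = np.array([w.height for w in waves])
    top = math.ceil(n / 3)
    hs = float(np.mean(np.sort(heights)[-top:]))
    return WaveEstimate(
        Hs=hs, n_waves=n,
        mean_period=float(np.mean([w.period for w in waves])),
        window=(waves[0].t_start, waves[-1].t_end),
    )


def estimate_wave(gnss: GnssSeries, event: TakeoffEvent,
                  min_float: float = MIN_FLOAT_S,
                  tail_skip: float = TAIL_SKIP_S,
                  fc: float = DEFAULT_FC, use_last: float | None = None,
                  min_waves: int = MIN_WAVES) -> WaveEstimate:
    """Wave estimate from the floating window before one take-off.

    Uses z over [t_takeoff - floating_duration, t_takeoff - tail_skip].
    If a GNSS gap interrupts the window, only the last gap-free stretch is
    used, and the stretch must still cover ``min_float - tail_skip``.
    ``use_last`` optionally restricts to the final N seconds (default:
    full bout).
    """
    if event.floating_duration < min_float:
        raise EligibilityError(
            f"floating lasted {event.floating_duration:.0f} s "
            f"< {min_float:.0f} s"
        )
    t0 = event.floating_window[0]
    t1 = event.t_takeoff - tail_skip
    if use_last is not None:
        t0 = max(t0, t1 - use_last)
    sub = gnss.slice_time(t0, t1)
    segs = sub.segments()
    if not segs:
        raise EligibilityError("no GNSS samples in the floating window")
    a, b = segs[-1]  # last gap-free stretch before the take-off
    t, z = sub.t[a:b], sub.z[a:b]
    if t[-1] - t[0] < min_float - tail_skip:
        raise EligibilityError(
            f"gap-free floating stretch of {t[-1] - t[0]:.0f} s "
            f"< {min_float - tail_skip:.0f} s"
        )
    tu, zu = resample_uniform(t, z, sub.rate_hz)
    zf = highpass_z(zu, sub.rate_hz, fc=fc)
    waves = zero_up_cross_waves(zf, tu)
    return significant_wave_height(waves, min_waves=min_waves)
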