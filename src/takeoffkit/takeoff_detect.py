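"""Take-off detection from smoothed GNSS horizontal speed.

A take-off is the moment the smoothed horizontal speed rises through
4 m/s, provided the bird floated (speed below the threshold) for at least
30 s before and then flew (speed at or above it, short dips tolerated)
for at least 30 s after. Crossings failing either context rule are the
"very short flights" and are discarded. Detection runs independently
within each gap-free GNSS segment, so no event spans a data gap.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import DataError, contiguous_runs
from .io_logger import GnssSeries

__all__ = ["TakeoffEvent", "smooth_speed", "detect_takeoffs"]

WIND_MIN_FLIGHT_S = 300.0   # flight needed for a wind estimate
WAVE_MIN_FLOAT_S = 900.0    # floating needed for a wave estimate


@dataclass
class TakeoffEvent:
    """One detected take-off with floating and flight context windows."""

    t_takeoff: float
    floating_window: tuple[float, float]
    flight_window: tuple[float, float]

    @property
    def floating_duration(self) -> float:
        return self.floating_window[1] - self.floating_window[0]

    @property
    def flight_duration(self) -> float:
        return self.flight_window[1] - self.flight_window[0]

    @property
    def eligible_wind(self) -> bool:
        return self.flight_duration >= WIND_MIN_FLIGHT_S

    @property
    def eligible_wave(self) -> bool:
        return self.floating_duration >= WAVE_MIN_FLOAT_S

    def as_record(self) -> dict:
        return {
            "t_takeoff": self.t_takeoff,
            "float_start": self.floating_window[0],
            "flight_end": self.flight_window[1],
            "floating_duration": self.floating_duration,
            "flight_duration": self.flight_duration,
            "eligible_wind": self.eligible_wind,
            "eligible_wave": self.eligible_wave,
        }


def smooth_speed(gnss: GnssSeries, window_s: float = 0.4) -> np.ndarray:
    """Centred moving average of horizontal speed over ``window_s`` seconds.

    The window length in samples is derived from the native rate; edges use
    shrunken windows, so output length equals input length. Smoothing is
    applied per gap-free segment.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    if len(gnss) == 0:
        raise DataError("smooth_speed: empty GNSS series")
    speed = gnss.speed
    k = max(1, int(round(window_s * gnss.rate_hz)))
    out = np.empty_like(speed)
    for a, b in gnss.segments():
        seg = pd.Series(speed[a:b])
        out[a:b] = seg.rolling(k, center=True, min_periods=1).mean().to_numpy()
    return out


def detect_takeoffs(smoothed: np.ndarray, gnss: GnssSeries,
                    threshold: float = 4.0, min_floating: float = 30.0,
                    min_flight: float = 30.0,
                    dip_tolerance: float = 5.0) -> list[TakeoffEvent]:
    """Find take-offs as qualified upward crossings of ``threshold``.

    Within each gap-free segment, samples at or above the threshold are
    grouped into flight bouts; below-threshold dips shorter than
    ``dip_tolerance`` inside a flight do not split it (soaring briefly
    drops below the line). A bout qualifies as a take-off when the
    below-threshold stretch before it lasts at least ``min_floating``
    and the bout itself at least ``min_flight``. The flight window runs to
    the landing (start of the next qualified below stretch) or the end of
    the segment; the floating window runs back to the previous landing or
    the start of the segment.
    """
    if smoothed.shape != gnss.t.shape:
        raise ValueError("smoothed speed must align with GNSS timestamps")
    events: list[TakeoffEvent] = []
    for a, b in gnss.segments():
        t = gnss.t[a:b]
        above = smoothed[a:b] >= threshold
        if t.size < 2:
            continue
        bouts = _merge_bouts(above, t, dip_tolerance)
        for i0, i1 in bouts:
            t_cross = t[i0]
            float_start = t[0] if i0 == 0 else None
            # floating extends back to the end of the previous bout
            prev = [bb for bb in bouts if bb[1] <= i0]
            if prev:
                float_start = t[prev[-1][1] - 1]
            elif float_start is None:
                float_start = t[0]
            flight_end = t[i1 - 1]
            if i0 == 0:
                continue  # record starts airborne: no observed floating
            if t_cross - float_start < min_floating:
                continue
            if flight_end - t_cross < min_flight:
                continue
            events.append(TakeoffEvent(
                t_takeoff=float(t_cross),
                floating_window=(float(float_start), float(t_cross)),
                flight_window=(float(t_cross), float(flight_end)),
            ))
    events.sort(key=lambda e: e.t_takeoff)
    return events


def _merge_bouts(above: np.ndarray, t: np.ndarray, dip_tolerance: float):
    """Above-threshold runs with sub-tolerance interior dips merged."""
    runs = contiguous_runs(above)
    if not runs:
        return []
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        gap = t[s] - t[merged[-1][1] - 1]
        if gap < dip_tolerance:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(int(s), int(e)) for s, e in merged]


def events_table(events: list[TakeoffEvent]) -> pd.DataFrame:
    cols = ["t_takeoff", "float_start", "flight_end", "floating_duration",
            "flight_duration", "eligible_wind", "eligible_wave"]
    return pd.DataFrame([e.as_record() for e in events], columns=cols)
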