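"""Shared helpers: angle conventions, great-circle geometry, error types.

Angles are azimuths in radians, clockwise from geographic north, kept in
[0, 2pi). Wind directions use the meteorological "coming-from" convention
at every public boundary.
"""
from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


class SchemaError(ValueError):
    """A column-mapping config does not match the file contents."""


class DataError(ValueError):
    """A stream violates a structural invariant (e.g. non-monotone time)."""


class ParameterError(ValueError):
    """An operation was called with an out-of-domain parameter."""


class EligibilityError(ValueError):
    """An event does not meet the data requirements of an estimator."""


def wrap_2pi(a):
    """Wrap angle(s) to [0, 2pi)."""
    return np.mod(a, 2.0 * np.pi)


def wrap_pi(a):
    """Wrap signed angular difference(s) to (-pi, pi]; +pi at the boundary."""
    r = np.mod(np.asarray(a, dtype=float), 2.0 * np.pi)
    out = np.where(r > np.pi, r - 2.0 * np.pi, r)
    return float(out) if np.isscalar(a) or np.ndim(a) == 0 else out


def azimuth(v_east, v_north):
    """Azimuth (clockwise from north) of a velocity vector, in [0, 2pi)."""
    return wrap_2pi(np.arctan2(v_east, v_north))


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def initial_bearing(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, rad in [0, 2pi)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2) - np.radians(lon1)
    y = np.sin(dl) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl)
    return wrap_2pi(np.arctan2(y, x))


def circular_mean(angles):
    """Vector-mean direction of angles, rad in [0, 2pi)."""
    a = np.asarray(angles, dtype=float)
    return wrap_2pi(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a))))


def angular_span(angles):
    """Azimuthal coverage of a set of angles: 2pi minus the largest gap.

    Returns 0 for fewer than 2 distinct angles.
    """
    a = np.unique(wrap_2pi(np.asarray(angles, dtype=float)))
    if a.size < 2:
        return 0.0
    gaps = np.diff(a)
    wrap_gap = 2.0 * np.pi - (a[-1] - a[0])
    return float(2.0 * np.pi - max(gaps.max(), wrap_gap))


def contiguous_runs(mask):
    """(start, stop) index pairs (half-open) of True runs in a boolean array."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(m.size)
    return list(zip(starts, stops))
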