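"""Wind speed and direction from post-take-off flight tracks.

A bird's ground speed V along flight direction theta is, to first order,

    V(theta) = Va + Vw * cos(theta - dir_toward)

where Va is the air speed, Vw the wind speed and dir_toward the azimuth
the wind blows toward: ground speed peaks in tailwind and bottoms out in
headwind. Fitting this sinusoid over the 5 minutes of flight after a
take-off (first 10 s excluded) yields (Va, Vw, direction). The model is
linear in (a, b, c) under V = a + b cos(theta) + c sin(theta), so the fit
is exact linear least squares: Vw = sqrt(b^2 + c^2) >= 0 by construction
and dir_toward = atan2(c, b).

Reliability is gated by AIC: the sinusoid must beat the best constant-V
fit by at least 2 (Gaussian likelihood, AIC = n ln(RSS/n) + 2k with k = 4
vs 2). Public outputs report ``dir_from = dir_toward + pi`` — the
meteorological coming-from convention.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import EligibilityError, angular_span, azimuth, wrap_2pi
from .io_logger import GnssSeries
from .takeoff_detect import TakeoffEvent

__all__ = ["WindEstimate", "flight_samples", "fit_wind_sinusoid",
           "estimate_wind", "aic_ls"]

MIN_SAMPLES = 30
MIN_COVERAGE_RAD = np.pi / 2
RELIABLE_DELTA_AIC = 2.0


@dataclass
class WindEstimate:
    """Fitted wind parameters for one flight window."""

    Va: float
    Vw: float
    dir_from: float
    delta_aic: float
    n_samples: int
    coverage_rad: float
    coverage_ok: bool
    reliable: bool

    def as_record(self) -> dict:
        return {
            "Va": self.Va, "Vw": self.Vw,
            "dir_from": self.dir_from,
            "dir_from_deg": np.degrees(self.dir_from),
            "delta_aic": self.delta_aic, "n_samples": self.n_samples,
            "coverage_ok": self.coverage_ok, "reliable": self.reliable,
        }


def aic_ls(rss: float, n: int, k: int) -> float:
    """Least-squares AIC with unknown Gaussian noise: n ln(RSS/n) + 2k."""
    return n * np.log(rss / n) + 2 * k


def flight_samples(gnss: GnssSeries, event: TakeoffEvent,
                   skip_head: float = 10.0, window: float = 300.0,
                   min_speed: float = 0.5):
    """(theta, V) samples over [t_takeoff + skip_head, t_takeoff + window).

    Direction is atan2(v_east, v_north) (azimuth from north); samples
    slower than ``min_speed`` are dropped — their direction is undefined.
    """
    if event.flight_duration < window:
        raise EligibilityError(
            f"flight lasts {event.flight_duration:.0f} s < {window:.0f} s"
        )
    t0 = event.t_takeoff + skip_head
    t1 = event.t_takeoff + window
    m = (gnss.t >= t0) & (gnss.t < t1)
    ve, vn = gnss.v_east[m], gnss.v_north[m]
    v = np.hypot(ve, vn)
    ok = v >= min_speed
    return azimuth(ve[ok], vn[ok]), v[ok]


def fit_wind_sinusoid(theta, V) -> WindEstimate:
    """Exact least-squares fit of the ground-speed sinusoid.

    Returns an estimate flagged unreliable when azimuthal coverage is
    below 90 deg or the AIC margin over the constant model is below 2.
    """
    theta = np.asarray(theta, dtype=float)
    V = np.asarray(V, dtype=float)
    n = theta.size
    if n < MIN_SAMPLES:
        raise EligibilityError(f"need >= {MIN_SAMPLES} samples, got {n}")
    X = np.column_stack([np.ones(n), np.cos(theta), np.sin(theta)])
    coef, _, _, _ = np.linalg.lstsq(X, V, rcond=None)
    a, b, c = coef
    resid = V - X @ coef
    rss_sin = float(resid @ resid)
    rss_const = float(np.sum((V - V.mean()) ** 2))
    # guard the log for an exact fit
    eps = np.finfo(float).tiny
    delta = aic_ls(max(rss_const, eps), n, 2) - aic_ls(max(rss_sin, eps), n, 4)
    Vw = float(np.hypot(b, c))
    dir_toward = np.arctan2(c, b)
    dir_from = float(wrap_2pi(dir_toward + np.pi))
    span = angular_span(theta)
    coverage_ok = span >= MIN_COVERAGE_RAD
    return WindEstimate(
        Va=float(a), Vw=Vw, dir_from=dir_from, delta_aic=float(delta),
        n_samples=int(n), coverage_rad=float(span),
        coverage_ok=bool(coverage_ok),
        reliable=bool(coverage_ok and delta >= RELIABLE_DELTA_AIC),
    )


def estimate_wind(gnss: GnssSeries, event: TakeoffEvent,
                  skip_head: float = 10.0, window: float = 300.0
                  ) -> WindEstimate:
    """Wind estimate for one take-off's flight window."""
    theta, V = flight_samples(gnss, event, skip_head=skip_head,
                              window=window)
    return fit_wind_sinusoid(theta, V)
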