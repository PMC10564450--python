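"""Logger stream containers and I/O.

A deployment pairs two streams recorded by one back-mounted logger:

* GNSS at a nominal 5 Hz: position, Doppler horizontal velocity
  (east/north components) and vertical displacement;
* triaxial body-frame acceleration at a nominal 100 Hz
  (lateral, longitudinal, dorsoventral).

Everything in the core is SI (m, s, m/s, m/s^2); degrees and g appear only
at the file boundary, converted according to a column-mapping schema.
Timestamps are seconds since deployment start and must be strictly
increasing; a gap larger than ``gap_factor`` (default 3) times the nominal
interval splits a stream into segments, and no downstream event may span a
segment boundary.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import DataError, SchemaError, haversine_km

__all__ = [
    "GnssSeries",
    "AccelSeries",
    "Deployment",
    "read_gnss_csv",
    "read_accel_csv",
    "read_logger_csv",
    "mask_colony",
    "write_summary_table",
    "read_summary_table",
]

_G = 9.81  # conversion used for accelerations declared in units of g

_UNIT_FACTORS = {
    "m/s": 1.0,
    "km/h": 1.0 / 3.6,
    "m/s2": 1.0,
    "m/s^2": 1.0,
    "g": _G,
    "m": 1.0,
}


def _check_monotone(t, what):
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise DataError(
            f"{what}: timestamps not strictly increasing at index {bad[0] + 1}"
        )


def _check_finite(name, x, what):
    if not np.all(np.isfinite(x)):
        i = int(np.flatnonzero(~np.isfinite(x))[0])
        raise DataError(f"{what}: non-finite value in column '{name}' at index {i}")


@dataclass
class GnssSeries:
    """GNSS stream: time, position, horizontal velocity, vertical displacement."""

    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    v_east: np.ndarray
    v_north: np.ndarray
    z: np.ndarray
    rate_hz: float | None = None

    def __post_init__(self):
        for name in ("t", "lat", "lon", "v_east", "v_north", "z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        for name in ("lat", "lon", "v_east", "v_north", "z"):
            if getattr(self, name).size != n:
                raise DataError(f"GnssSeries: column '{name}' length != t length")
        if n:
            _check_monotone(self.t, "GnssSeries")
            for name in ("v_east", "v_north"):
                _check_finite(name, getattr(self, name), "GnssSeries")
        if self.rate_hz is None and n > 1:
            self.rate_hz = float(1.0 / np.median(np.diff(self.t)))

    def __len__(self):
        return self.t.size

    @property
    def speed(self):
        """Horizontal ground speed, m/s."""
        return np.hypot(self.v_east, self.v_north)

    @property
    def nominal_dt(self):
        return 1.0 / self.rate_hz if self.rate_hz else np.nan

    def segments(self, gap_factor: float = 3.0):
        """Half-open index ranges of gap-free stretches.

        A step larger than ``gap_factor`` times the nominal interval starts a
        new segment.
        """
        if len(self) == 0:
            return []
        if len(self) == 1:
            return [(0, 1)]
        gap = np.diff(self.t) > gap_factor * self.nominal_dt
        cuts = np.flatnonzero(gap) + 1
        bounds = np.concatenate([[0], cuts, [len(self)]])
        return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]

    def slice_time(self, t0: float, t1: float) -> "GnssSeries":
        """Samples with t in [t0, t1)."""
        m = (self.t >= t0) & (self.t < t1)
        return GnssSeries(
            self.t[m], self.lat[m], self.lon[m], self.v_east[m],
            self.v_north[m], self.z[m], rate_hz=self.rate_hz,
        )


@dataclass
class AccelSeries:
    """Triaxial body-frame acceleration: lateral, longitudinal, dorsoventral."""

    t: np.ndarray
    a_lat: np.ndarray
    a_long: np.ndarray
    a_dv: np.ndarray
    rate_hz: float | None = None

    def __post_init__(self):
        for name in ("t", "a_lat", "a_long", "a_dv"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        for name in ("a_lat", "a_long", "a_dv"):
            if getattr(self, name).size != n:
                raise DataError(f"AccelSeries: column '{name}' length != t length")
        if n:
            _check_monotone(self.t, "AccelSeries")
            for name in ("a_lat", "a_long", "a_dv"):
                _check_finite(name, getattr(self, name), "AccelSeries")
        if n > 1:
            med_rate = float(1.0 / np.median(np.diff(self.t)))
            if self.rate_hz is None:
                self.rate_hz = med_rate
            elif abs(self.rate_hz - med_rate) > 0.01 * self.rate_hz:
                raise DataError(
                    f"AccelSeries: declared rate {self.rate_hz} Hz differs from "
                    f"median rate {med_rate:.3f} Hz by more than 1%"
                )

    def __len__(self):
        return self.t.size

    def slice_time(self, t0: float, t1: float) -> "AccelSeries":
        m = (self.t >= t0) & (self.t < t1)
        return AccelSeries(
            self.t[m], self.a_lat[m], self.a_long[m], self.a_dv[m],
            rate_hz=self.rate_hz,
        )


@dataclass
class Deployment:
    """One bird, one logger record: paired GNSS and acceleration streams."""

    bird_id: str
    gnss: GnssSeries
    accel: AccelSeries
    sex: str = "unknown"
    year: int | None = None
    recorder_type: str | None = None

    def __post_init__(self):
        if self.sex not in ("M", "F", "unknown"):
            raise DataError(f"Deployment: sex must be M/F/unknown, got {self.sex!r}")
        if len(self.gnss) and len(self.accel):
            overlap = min(self.gnss.t[-1], self.accel.t[-1]) - max(
                self.gnss.t[0], self.accel.t[0]
            )
            if overlap <= 0:
                raise DataError(
                    f"Deployment {self.bird_id}: GNSS and accel streams do not overlap"
                )


def _factor(units: dict, key: str, default: str) -> float:
    u = (units or {}).get(key, default)
    try:
        return _UNIT_FACTORS[u]
    except KeyError:
        raise SchemaError(f"unknown unit {u!r} for {key!r}") from None


def _load_columns(df: pd.DataFrame, columns: dict, what: str) -> dict:
    out = {}
    for field_name, col in columns.items():
        if col not in df.columns:
            raise SchemaError(f"{what}: column {col!r} (for field {field_name!r}) "
                              f"missing from file")
        out[field_name] = df[col].to_numpy(dtype=float)
    return out


def read_gnss_csv(path, columns: dict, units: dict | None = None,
                  rate_hz: float | None = None) -> GnssSeries:
    """Read a GNSS CSV given a field->column mapping.

    Required fields: t, lat, lon, v_east, v_north, z. ``units`` may declare
    ``velocity`` ('m/s' or 'km/h') and ``z`` ('m').
    """
    df = pd.read_csv(path)
    cols = _load_columns(df, columns, "gnss")
    missing = {"t", "lat", "lon", "v_east", "v_north", "z"} - set(cols)
    if missing:
        raise SchemaError(f"gnss: schema missing field mappings {sorted(missing)}")
    fv = _factor(units, "velocity", "m/s")
    fz = _factor(units, "z", "m")
    return GnssSeries(
        cols["t"], cols["lat"], cols["lon"],
        cols["v_east"] * fv, cols["v_north"] * fv, cols["z"] * fz,
        rate_hz=rate_hz,
    )


def read_accel_csv(path, columns: dict, units: dict | None = None,
                   rate_hz: float | None = None) -> AccelSeries:
    """Read an acceleration CSV; ``units['accel']`` may be 'm/s2' or 'g'."""
    df = pd.read_csv(path)
    cols = _load_columns(df, columns, "accel")
    missing = {"t", "a_lat", "a_long", "a_dv"} - set(cols)
    if missing:
        raise SchemaError(f"accel: schema missing field mappings {sorted(missing)}")
    fa = _factor(units, "accel", "m/s2")
    return AccelSeries(
        cols["t"], cols["a_lat"] * fa, cols["a_long"] * fa, cols["a_dv"] * fa,
        rate_hz=rate_hz,
    )


def read_logger_csv(path, schema) -> Deployment:
    """Read one deployment from CSV files described by a mapping schema.

    ``path`` is the deployment directory; ``schema`` is a dict (or a path to
    a YAML file) with ``gnss:`` and ``accel:`` sections, each declaring
    ``file``, ``columns`` (field -> column name), optional ``units`` and
    ``rate_hz``, plus top-level metadata (bird_id, sex, year, recorder_type).
    """
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    base = Path(path)
    try:
        g, a = schema["gnss"], schema["accel"]
    except KeyError as e:
        raise SchemaError(f"schema missing section {e.args[0]!r}") from None
    gnss = read_gnss_csv(base / g["file"], g["columns"], g.get("units"),
                         g.get("rate_hz"))
    accel = read_accel_csv(base / a["file"], a["columns"], a.get("units"),
                           a.get("rate_hz"))
    return Deployment(
        bird_id=str(schema.get("bird_id", base.name)),
        gnss=gnss,
        accel=accel,
        sex=schema.get("sex", "unknown"),
        year=schema.get("year"),
        recorder_type=schema.get("recorder_type"),
    )


def mask_colony(dep: Deployment, colony_lat: float, colony_lon: float,
                radius_km: float) -> Deployment:
    """Drop GNSS samples within ``radius_km`` of the colony (great-circle).

    Acceleration samples outside the retained GNSS time span are dropped too.
    Removing an interior block leaves a time gap, which the gap policy then
    treats as a segment boundary.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be > 0")
    g = dep.gnss
    keep = haversine_km(g.lat, g.lon, colony_lat, colony_lon) > radius_km
    gnss = GnssSeries(g.t[keep], g.lat[keep], g.lon[keep], g.v_east[keep],
                      g.v_north[keep], g.z[keep], rate_hz=g.rate_hz)
    if len(gnss) == 0:
        warnings.warn(
            f"deployment {dep.bird_id}: all GNSS samples inside the colony disc",
            stacklevel=2,
        )
        accel = AccelSeries(np.empty(0), np.empty(0), np.empty(0), np.empty(0),
                            rate_hz=dep.accel.rate_hz)
    else:
        accel = dep.accel.slice_time(gnss.t[0], np.nextafter(gnss.t[-1], np.inf))
    return replace(dep, gnss=gnss, accel=accel)


def write_summary_table(rows, path) -> None:
    """Write a results table as CSV, round-trip safe to 1e-9 on floats."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.12g")


def read_summary_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
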