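"""Station climate normals: CSV I/O and expansion of monthly normals to weeks.

The station database is a flat CSV, one station per row::

    station_id,name,lat,lon,elev,tmin01..tmin12,tmax01..tmax12,rain01..rain12[,rh01..rh12]

with temperatures in degC, monthly rainfall totals in mm, and optional
relative-humidity columns in percent. This is the portable stand-in for the
proprietary ``.loc/.met`` station databases used by desktop ecoclimatic
modelling tools.

The model runs on a fixed 52-week year (52 x 7 = 364 days). Monthly
temperature normals are placed at the day-centre of each civil month
(365-day year, rescaled onto the 364-day grid) and interpolated periodically
to week mid-points; monthly rainfall is apportioned to weeks by day overlap,
which conserves the annual total exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StationClimate",
    "WeeklySeries",
    "StationValidationError",
    "StationParseError",
    "read_stations",
    "write_stations",
    "monthly_to_weekly",
    "WEEKS_PER_YEAR",
    "DAYS_PER_WEEK",
]

WEEKS_PER_YEAR = 52
DAYS_PER_WEEK = 7
_YEAR_DAYS = WEEKS_PER_YEAR * DAYS_PER_WEEK  # 364
_MONTH_LEN = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)


class StationValidationError(ValueError):
    """Climate normals violate a physical constraint (tmin > tmax, negative rain...)."""


class StationParseError(ValueError):
    """A station CSV row could not be parsed."""


@dataclass(frozen=True)
class StationClimate:
    """One station's coordinates and 12-month climate normals."""

    station_id: str
    name: str
    lat: float          # degrees N
    lon: float          # degrees E
    elevation: float    # m
    tmin: np.ndarray    # degC, 12 monthly mean daily minima
    tmax: np.ndarray    # degC, 12 monthly mean daily maxima
    rain: np.ndarray    # mm, 12 monthly totals
    rh: np.ndarray | None = None  # %, optional

    def __post_init__(self) -> None:
        for attr in ("tmin", "tmax", "rain"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != (12,):
                raise StationValidationError(
                    f"station {self.station_id}: {attr} must have 12 monthly values")
            object.__setattr__(self, attr, arr)
        if self.rh is not None:
            rh = np.asarray(self.rh, dtype=float)
            if rh.shape != (12,):
                raise StationValidationError(
                    f"station {self.station_id}: rh must have 12 monthly values")
            object.__setattr__(self, "rh", rh)
        if not (-90.0 <= self.lat <= 90.0):
            raise StationValidationError(f"station {self.station_id}: lat {self.lat} out of range")
        if not (-180.0 <= self.lon <= 180.0):
            raise StationValidationError(f"station {self.station_id}: lon {self.lon} out of range")
        bad = np.nonzero(self.tmin > self.tmax)[0]
        if bad.size:
            raise StationValidationError(
                f"station {self.station_id}: tmin > tmax in month {bad[0] + 1}")
        bad = np.nonzero(self.rain < 0)[0]
        if bad.size:
            raise StationValidationError(
                f"station {self.station_id}: negative rainfall in month {bad[0] + 1}")
        if self.rh is not None and (np.any(self.rh < 0) or np.any(self.rh > 100)):
            raise StationValidationError(f"station {self.station_id}: rh outside 0-100%")


@dataclass(frozen=True)
class WeeklySeries:
    """52-week temperature and rainfall series derived from monthly normals."""

    station_id: str
    tmin_w: np.ndarray   # degC
    tmax_w: np.ndarray   # degC
    tmean_w: np.ndarray  # degC, (tmin_w + tmax_w) / 2
    rain_w: np.ndarray   # mm per week

    def __post_init__(self) -> None:
        for attr in ("tmin_w", "tmax_w", "tmean_w", "rain_w"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != (WEEKS_PER_YEAR,):
                raise ValueError(f"{attr} must have exactly {WEEKS_PER_YEAR} weeks")
            object.__setattr__(self, attr, arr)


def _columns(with_rh: bool) -> list[str]:
    cols = ["station_id", "name", "lat", "lon", "elev"]
    for prefix in ("tmin", "tmax", "rain") + (("rh",) if with_rh else ()):
        cols += [f"{prefix}{m:02d}" for m in range(1, 13)]
    return cols


def read_stations(path) -> list[StationClimate]:
    """Read a station CSV into validated :class:`StationClimate` records.

    Row order is preserved; the station count is reported via logging.
    """
    try:
        df = pd.read_csv(path, dtype={"station_id": str, "name": str},
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise StationParseError(f"could not parse station CSV {path}: {exc}") from exc
    with_rh = any(c.startswith("rh") for c in df.columns)
    expected = _columns(with_rh)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise StationParseError(f"{path}: missing column(s): {', '.join(missing)}")
    stations: list[StationClimate] = []
    for i, row in df.iterrows():
        try:
            stations.append(StationClimate(
                station_id=str(row["station_id"]),
                name=str(row["name"]),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                elevation=float(row["elev"]),
                tmin=row[[f"tmin{m:02d}" for m in range(1, 13)]].to_numpy(dtype=float),
                tmax=row[[f"tmax{m:02d}" for m in range(1, 13)]].to_numpy(dtype=float),
                rain=row[[f"rain{m:02d}" for m in range(1, 13)]].to_numpy(dtype=float),
                rh=(row[[f"rh{m:02d}" for m in range(1, 13)]].to_numpy(dtype=float)
                    if with_rh else None),
            ))
        except StationValidationError:
            raise
        except (TypeError, ValueError) as exc:
            raise StationParseError(f"{path}: malformed row {i + 2}: {exc}") from exc
    logger.info("read %d station(s) from %s", len(stations), path)
    return stations


def write_stations(stations: list[StationClimate], path) -> None:
    """Write stations in the same CSV dialect (finite values round-trip exactly)."""
    with_rh = all(st.rh is not None for st in stations) and len(stations) > 0
    rows = []
    for st in stations:
        row: dict = {"station_id": st.station_id, "name": st.name,
                     "lat": st.lat, "lon": st.lon, "elev": st.elevation}
        for prefix, arr in (("tmin", st.tmin), ("tmax", st.tmax), ("rain", st.rain)):
            row.update({f"{prefix}{m:02d}": arr[m - 1] for m in range(1, 13)})
        if with_rh:
            row.update({f"rh{m:02d}": st.rh[m - 1] for m in range(1, 13)})
        rows.append(row)
    pd.DataFrame(rows, columns=_columns(with_rh)).to_csv(
        path, index=False, float_format="%.17g")


def _month_midpoints_364() -> np.ndarray:
    """Civil-month day-centres rescaled onto the 364-day model year."""
    ends = np.cumsum(_MONTH_LEN)
    mids_365 = ends - _MONTH_LEN / 2.0
    return mids_365 * _YEAR_DAYS / 365.0


def _month_bounds_364() -> np.ndarray:
    """13 month-boundary days on the 364-day model year (0 .. 364)."""
    return np.concatenate([[0.0], np.cumsum(_MONTH_LEN)]) * _YEAR_DAYS / 365.0


def _interp_periodic(week_days: np.ndarray, month_days: np.ndarray,
                     values: np.ndarray) -> np.ndarray:
    # pad one month on each side so the Dec->Jan transition interpolates smoothly
    x = np.concatenate([[month_days[-1] - _YEAR_DAYS], month_days, [month_days[0] + _YEAR_DAYS]])
    y = np.concatenate([[values[-1]], values, [values[0]]])
    return np.interp(week_days, x, y)


def monthly_to_weekly(st: StationClimate) -> WeeklySeries:
    """Expand monthly normals to a 52-week series.

    Temperatures are interpolated linearly (and periodically) from month
    mid-points to week mid-points; rainfall is spread uniformly within each
    month and summed over each week's day span, so the annual total is
    conserved to floating-point precision.
    """
    week_mids = np.arange(WEEKS_PER_YEAR) * DAYS_PER_WEEK + DAYS_PER_WEEK / 2.0
    month_mids = _month_midpoints_364()
    tmin_w = _interp_periodic(week_mids, month_mids, st.tmin)
    tmax_w = _interp_periodic(week_mids, month_mids, st.tmax)

    bounds = _month_bounds_364()
    density = st.rain / np.diff(bounds)  # mm per model-day, per month
    rain_w = np.zeros(WEEKS_PER_YEAR)
    for w in range(WEEKS_PER_YEAR):
        lo, hi = w * DAYS_PER_WEEK, (w + 1) * DAYS_PER_WEEK
        overlap = np.minimum(hi, bounds[1:]) - np.maximum(lo, bounds[:-1])
        rain_w[w] = np.sum(np.clip(overlap, 0.0, None) * density)

    return WeeklySeries(
        station_id=st.station_id,
        tmin_w=tmin_w,
        tmax_w=tmax_w,
        tmean_w=(tmin_w + tmax_w) / 2.0,
        rain_w=rain_w,
    )
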