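"""Station-to-raster interpolation of EI, boundary estimation, and writers.

Station EI values are interpolated onto a regular geographic grid (WGS84,
cell-centre registration, north-up rows) with either inverse-distance
weighting or ordinary kriging with an exponential variogram fitted by
weighted least squares to the empirical variogram. Distances are
great-circle kilometres; the study domains of interest span tens of degrees
of latitude, where planar degree distances distort badly.

Overwintering-band semantics: the northern edge of the band is the northern
limit of EI > 0, and its southern edge is the northern limit of the
EI >= 30 (perennial) region.

Outputs are ESRI ASCII grids (one file per band) and GeoJSON category
polygons; both are plain text and round-trip through the readers here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from shapely.geometry import box, mapping as shp_mapping
from shapely.ops import unary_union

from .engine import classify

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "SuitabilityRaster",
    "interpolate_ei",
    "boundary_latitudes",
    "overwintering_band",
    "write_raster",
    "read_ascii_grid",
    "write_categories_geojson",
    "great_circle_km",
]

EARTH_RADIUS_KM = 6371.0088
NODATA = -9999.0
_CATEGORY_CODE = {"unsuitable": 0, "overwintering": 1, "perennial": 2}


def great_circle_km(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance in km (vectorised)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (np.asarray(lat1, dtype=float),
                                              np.asarray(lon1, dtype=float),
                                              np.asarray(lat2, dtype=float),
                                              np.asarray(lon2, dtype=float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid, cell-centre registration, WGS84."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    cell_size: float  # degrees

    def __post_init__(self) -> None:
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError("grid bounds must satisfy min < max")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def lats(self) -> np.ndarray:
        """Cell-centre latitudes, south to north."""
        n = max(1, int(round((self.lat_max - self.lat_min) / self.cell_size)))
        return self.lat_min + self.cell_size / 2 + self.cell_size * np.arange(n)

    @property
    def lons(self) -> np.ndarray:
        """Cell-centre longitudes, west to east."""
        n = max(1, int(round((self.lon_max - self.lon_min) / self.cell_size)))
        return self.lon_min + self.cell_size / 2 + self.cell_size * np.arange(n)


@dataclass(frozen=True)
class SuitabilityRaster:
    """Gridded EI surface (rows = latitude, south to north in memory) with a
    category layer derived cell-wise from the EI values."""

    grid: GridSpec
    ei: np.ndarray        # 2-D (nlat, nlon), NaN = no-data
    category: np.ndarray  # 2-D object array of category names, '' = no-data
    method: str
    method_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        finite = self.ei[np.isfinite(self.ei)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 100.0):
            raise ValueError("finite EI values must lie in [0, 100]")


def _categorise(ei: np.ndarray) -> np.ndarray:
    cat = np.empty(ei.shape, dtype=object)
    for idx in np.ndindex(ei.shape):
        cat[idx] = classify(float(ei[idx])) if np.isfinite(ei[idx]) else ""
    return cat


def _idw_at(qlat, qlon, slat, slon, vals, power, cutoff_km):
    d = great_circle_km(qlat, qlon, slat, slon)
    hit = d < 1e-9
    if hit.any():
        return float(vals[hit][0])
    use = d <= cutoff_km
    if not use.any():
        return np.nan
    w = 1.0 / d[use] ** power
    return float(np.sum(w * vals[use]) / np.sum(w))


def _exp_variogram(h, nugget, psill, rng):
    g = np.where(np.asarray(h) > 0, nugget + psill * (1.0 - np.exp(-np.asarray(h) / rng)), 0.0)
    return g


def _fit_variogram(d, vals):
    """Fit nugget/partial-sill/range of an exponential variogram by WLS
    (bin-count weights) to the empirical variogram. Returns None when the
    field is essentially constant."""
    n = len(vals)
    iu = np.triu_indices(n, k=1)
    h = d[iu]
    g = 0.5 * (vals[iu[0]] - vals[iu[1]]) ** 2
    hmax = h.max() / 2.0
    if hmax <= 0 or np.allclose(g, 0.0):
        return None
    nbins = min(15, max(5, n // 2))
    edges = np.linspace(0.0, hmax, nbins + 1)
    which = np.digitize(h, edges[1:-1])
    hc, gc, wc = [], [], []
    for b in range(nbins):
        m = (which == b) & (h <= hmax)
        if m.sum() > 0:
            hc.append(h[m].mean())
            gc.append(g[m].mean())
            wc.append(m.sum())
    hc, gc, wc = map(np.asarray, (hc, gc, wc))
    if len(hc) < 3 or np.allclose(gc, 0.0):
        return None
    p0 = np.array([0.0, max(gc.max(), 1e-6), max(hc.max() / 2.0, 1e-3)])

    def resid(theta):
        return np.sqrt(wc) * (_exp_variogram(hc, *np.abs(theta)) - gc)

    sol = least_squares(resid, p0, method="lm", max_nfev=2000)
    nugget, psill, rng = np.abs(sol.x)
    if psill <= 1e-12:
        return None
    return float(nugget), float(psill), float(rng)


def _krige_at(qlat, qlon, slat, slon, vals, vparams, n_neighbors):
    d = great_circle_km(qlat, qlon, slat, slon)
    hit = d < 1e-9
    if hit.any():
        return float(vals[hit][0]), True
    order = np.argsort(d)[:n_neighbors]
    sl, so, v = slat[order], slon[order], vals[order]
    m = len(order)
    dij = great_circle_km(sl[:, None], so[:, None], sl[None, :], so[None, :])
    A = np.empty((m + 1, m + 1))
    A[:m, :m] = _exp_variogram(dij, *vparams)
    np.fill_diagonal(A[:m, :m], 0.0)
    A[m, :m] = 1.0
    A[:m, m] = 1.0
    A[m, m] = 0.0
    b = np.empty(m + 1)
    b[:m] = _exp_variogram(d[order], *vparams)
    b[m] = 1.0
    try:
        w = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.nan, False
    return float(np.dot(w[:m], v)), True


def interpolate_ei(stations: pd.DataFrame, grid: GridSpec, method: str = "idw",
                   power: float = 2.0, cutoff_km: float = 2000.0,
                   n_neighbors: int = 12) -> SuitabilityRaster:
    """Interpolate station EI values onto the grid.

    ``stations`` needs columns ``lat``, ``lon``, ``EI``. Both methods are
    exact at station-coincident cell centres; interpolated values are
    clamped to [0, 100]; cells farther than ``cutoff_km`` from every
    station are no-data. A singular or degenerate kriging system falls back
    to IDW with a logged warning.
    """
    for c in ("lat", "lon", "EI"):
        if c not in stations.columns:
            raise ValueError(f"stations frame must have a {c!r} column")
    slat = stations["lat"].to_numpy(dtype=float)
    slon = stations["lon"].to_numpy(dtype=float)
    vals = stations["EI"].to_numpy(dtype=float)
    if method == "idw":
        if len(vals) < 3:
            raise ValueError("idw needs at least 3 stations")
    elif method == "kriging":
        if len(vals) < 5:
            raise ValueError("kriging needs at least 5 stations")
    else:
        raise ValueError("method must be 'idw' or 'kriging'")

    vparams = None
    if method == "kriging":
        dmat = great_circle_km(slat[:, None], slon[:, None], slat[None, :], slon[None, :])
        vparams = _fit_variogram(dmat, vals)
        if vparams is None:
            logger.warning("degenerate variogram (constant or near-constant field); "
                           "falling back to idw")

    lats, lons = grid.lats, grid.lons
    ei = np.full((len(lats), len(lons)), np.nan)
    for i, qlat in enumerate(lats):
        for j, qlon in enumerate(lons):
            dmin = great_circle_km(qlat, qlon, slat, slon).min()
            if dmin > cutoff_km:
                continue
            if method == "kriging" and vparams is not None:
                val, ok = _krige_at(qlat, qlon, slat, slon, vals, vparams, n_neighbors)
                if not ok:
                    logger.warning("singular kriging system at (%.3f, %.3f); idw fallback",
                                   qlat, qlon)
                    val = _idw_at(qlat, qlon, slat, slon, vals, power, cutoff_km)
            else:
                val = _idw_at(qlat, qlon, slat, slon, vals, power, cutoff_km)
            if np.isfinite(val):
                ei[i, j] = min(100.0, max(0.0, val))
    mp = {"power": power, "cutoff_km": cutoff_km}
    if method == "kriging":
        mp.update(n_neighbors=n_neighbors,
                  variogram=(dict(zip(("nugget", "psill", "range_km"), vparams))
                             if vparams else "degenerate->idw"))
    return SuitabilityRaster(grid=grid, ei=ei, category=_categorise(ei),
                             method=method, method_params=mp)


def boundary_latitudes(r: SuitabilityRaster, predicate: str = "EI>0") -> pd.DataFrame:
    """Per-longitude-column southern/northern cell-centre latitudes where the
    predicate holds ('EI>0' or 'EI>=30'), plus column medians in ``.attrs``.

    Returns an empty frame (with a warning) if no cell qualifies.
    """
    if predicate == "EI>0":
        mask = np.isfinite(r.ei) & (r.ei > 0.0)
    elif predicate == "EI>=30":
        mask = np.isfinite(r.ei) & (r.ei >= 30.0)
    else:
        raise ValueError("predicate must be 'EI>0' or 'EI>=30'")
    lats, lons = r.grid.lats, r.grid.lons
    rows = []
    for j, lon in enumerate(lons):
        ii = np.nonzero(mask[:, j])[0]
        if ii.size:
            rows.append({"lon": lon, "south_lat": lats[ii.min()], "north_lat": lats[ii.max()]})
    df = pd.DataFrame(rows, columns=["lon", "south_lat", "north_lat"])
    if df.empty:
        logger.warning("no raster cell satisfies predicate %s", predicate)
        df.attrs.update(south_lat_median=np.nan, north_lat_median=np.nan)
    else:
        df.attrs.update(south_lat_median=float(df["south_lat"].median()),
                        north_lat_median=float(df["north_lat"].median()))
    return df


def overwintering_band(r: SuitabilityRaster) -> dict:
    """Median boundary latitudes of the overwintering band {0 < EI < 30}:
    its northern edge is the EI>0 northern limit, its southern edge the
    EI>=30 region's northern limit."""
    any_pos = boundary_latitudes(r, "EI>0")
    perennial = boundary_latitudes(r, "EI>=30")
    return {
        "north_boundary_lat": any_pos.attrs["north_lat_median"],
        "south_boundary_lat": perennial.attrs["north_lat_median"],
    }


def _write_ascii_band(path: Path, grid: GridSpec, band: np.ndarray, fmt: str) -> None:
    lats, lons = grid.lats, grid.lons
    header = (
        f"ncols {len(lons)}\n"
        f"nrows {len(lats)}\n"
        f"xllcenter {float(lons[0])!r}\n"
        f"yllcenter {float(lats[0])!r}\n"
        f"cellsize {float(grid.cell_size)!r}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    # ESRI ASCII rows run north -> south
    body = "\n".join(
        " ".join(fmt % v for v in row) for row in band[::-1]
    )
    path.write_text(header + body + "\n", encoding="utf-8")


def write_raster(r: SuitabilityRaster, path, fmt: str = "ascii-grid") -> None:
    """Write the EI band to ``path`` and the category-code band (0 unsuitable,
    1 overwintering, 2 perennial) next to it as ``<stem>_category.asc``."""
    if fmt != "ascii-grid":
        raise ValueError("supported raster format: 'ascii-grid'")
    path = Path(path)
    ei = np.where(np.isfinite(r.ei), r.ei, NODATA)
    _write_ascii_band(path, r.grid, ei, "%.6f")
    codes = np.full(r.ei.shape, NODATA)
    for name, code in _CATEGORY_CODE.items():
        codes[r.category == name] = code
    _write_ascii_band(path.with_name(path.stem + "_category.asc"), r.grid, codes, "%g")


def read_ascii_grid(path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid written by :func:`write_raster` (south-to-north
    row order restored; NODATA mapped to NaN)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
            "ncols", "nrows", "xllcenter", "yllcenter", "cellsize", "nodata_value"):
        k, v = lines[i].split(maxsplit=1)
        hdr[k.lower()] = float(v)
        i += 1
    data = np.loadtxt(lines[i:], dtype=float, ndmin=2)[::-1]
    data[data == hdr.get("nodata_value", NODATA)] = np.nan
    cs = hdr["cellsize"]
    grid = GridSpec(
        lat_min=hdr["yllcenter"] - cs / 2,
        lat_max=hdr["yllcenter"] - cs / 2 + cs * hdr["nrows"],
        lon_min=hdr["xllcenter"] - cs / 2,
        lon_max=hdr["xllcenter"] - cs / 2 + cs * hdr["ncols"],
        cell_size=cs,
    )
    return grid, data


def write_categories_geojson(r: SuitabilityRaster, path) -> None:
    """Dissolve cells into one polygon (multi-)feature per category and write
    GeoJSON (WGS84). Cell footprints are cell_size x cell_size boxes."""
    half = r.grid.cell_size / 2.0
    lats, lons = r.grid.lats, r.grid.lons
    features = []
    for name in _CATEGORY_CODE:
        cells = [box(lons[j] - half, lats[i] - half, lons[j] + half, lats[i] + half)
                 for i, j in zip(*np.nonzero(r.category == name))]
        if not cells:
            continue
        geom = unary_union(cells)
        features.append({
            "type": "Feature",
            "properties": {"category": name, "n_cells": len(cells)},
            "geometry": shp_mapping(geom),
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}), encoding="utf-8")
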