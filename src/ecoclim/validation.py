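"""Comparison of model categories against winter fieldwork observations.

Fourteen sites along a south-to-north transect (Sanya 18.14 degN to Beijing
39.92 degN) were surveyed during the winters of 2008-2010 for live eggs,
larvae, pupae and adults. Observed outcomes are 'perennial' (all stages
present year-round), 'overwinter' (live individuals found in winter) or
'none' (no individuals found). The module matches each site to the nearest
model result and reports a 3x3 confusion table with strict and lenient
agreement (lenient credits a 'perennial' prediction at an observed
overwintering site, since year-round persistence implies overwinter
survival). The investigation area of four northern sites was not recorded
and is stored as missing, never imputed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import AnnualResult
from .mapping import SuitabilityRaster, great_circle_km
from .stations import StationClimate

__all__ = [
    "FieldSite",
    "fieldwork_sites",
    "match_to_stations",
    "match_to_raster",
    "confusion",
    "OBSERVED_TO_CATEGORY",
]

OBSERVED_TO_CATEGORY = {"perennial": "perennial", "overwinter": "overwintering",
                        "none": "unsuitable"}
_OBSERVED = ("perennial", "overwinter", "none")
_PREDICTED = ("perennial", "overwintering", "unsuitable")


@dataclass(frozen=True)
class FieldSite:
    name: str
    lat: float
    lon: float
    observed: str           # 'perennial' | 'overwinter' | 'none'
    area_m2: float | None   # investigation area; None where not recorded
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.observed not in _OBSERVED:
            raise ValueError(f"observed must be one of {_OBSERVED}, got {self.observed!r}")


def fieldwork_sites() -> list[FieldSite]:
    """The packaged 14-site winter fieldwork table (printed coordinates):
    2 perennial, 5 overwinter, 7 none."""
    ref = importlib.resources.files("ecoclim.data").joinpath("fieldwork_sites.csv")
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p)
    sites = []
    for _, row in df.iterrows():
        area = row["area_m2"]
        sites.append(FieldSite(
            name=str(row["name"]), lat=float(row["lat"]), lon=float(row["lon"]),
            observed=str(row["observed"]),
            area_m2=None if pd.isna(area) else float(area),
            evidence=str(row["evidence"]),
        ))
    return sites


def match_to_stations(sites: list[FieldSite], stations: list[StationClimate],
                      results: list[AnnualResult]) -> pd.DataFrame:
    """Match each site to the nearest station's predicted category.

    Returns a frame with site, observed, predicted, match distance (km)."""
    if not sites:
        raise ValueError("need at least one field site")
    if len(stations) != len(results):
        raise ValueError("stations and results must have equal length")
    if not stations:
        raise ValueError("need at least one model result to match against")
    slat = np.array([s.lat for s in stations])
    slon = np.array([s.lon for s in stations])
    rows = []
    for site in sites:
        d = great_circle_km(site.lat, site.lon, slat, slon)
        k = int(np.argmin(d))
        rows.append({"site": site.name, "observed": site.observed,
                     "predicted": results[k].category, "EI": results[k].EI,
                     "match_km": float(d[k]), "matched_id": stations[k].station_id})
    return pd.DataFrame(rows)


def match_to_raster(sites: list[FieldSite], raster: SuitabilityRaster) -> pd.DataFrame:
    """Match each site to the nearest non-no-data raster cell centre."""
    if not sites:
        raise ValueError("need at least one field site")
    lats, lons = raster.grid.lats, raster.grid.lons
    ii, jj = np.nonzero(np.isfinite(raster.ei))
    if ii.size == 0:
        raise ValueError("raster has no data cells to match against")
    rows = []
    for site in sites:
        d = great_circle_km(site.lat, site.lon, lats[ii], lons[jj])
        k = int(np.argmin(d))
        rows.append({"site": site.name, "observed": site.observed,
                     "predicted": str(raster.category[ii[k], jj[k]]),
                     "EI": float(raster.ei[ii[k], jj[k]]),
                     "match_km": float(d[k]),
                     "matched_id": f"cell({lats[ii[k]]:.3f},{lons[jj[k]]:.3f})"})
    return pd.DataFrame(rows)


def confusion(matched: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """3x3 confusion table (rows observed, columns predicted), strict
    agreement = trace/total, and lenient agreement (observed 'overwinter'
    also credited when predicted 'perennial')."""
    if matched.empty:
        raise ValueError("need at least one matched site")
    if "predicted" not in matched.columns:
        raise ValueError("matched frame lacks a 'predicted' column")
    unmatched = matched[matched["predicted"].isna() | (matched["predicted"] == "")]
    if unmatched.shape[0]:
        raise ValueError("unmatched site(s): " + ", ".join(map(str, unmatched["site"])))
    table = pd.DataFrame(0, index=list(_OBSERVED), columns=list(_PREDICTED))
    for _, row in matched.iterrows():
        table.loc[row["observed"], row["predicted"]] += 1
    total = int(table.to_numpy().sum())
    strict_hits = sum(table.loc[obs, OBSERVED_TO_CATEGORY[obs]] for obs in _OBSERVED)
    lenient_hits = strict_hits + table.loc["overwinter", "perennial"]
    return table, strict_hits / total, lenient_hits / total
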