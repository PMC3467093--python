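"""Model core: weekly growth indices, soil-moisture bucket, stress
accumulators, degree-day gate and the Ecoclimatic Index.

The model assumes each location offers the species one season favourable
for population growth and one unfavourable (stress) season. Weekly
temperature and soil-moisture suitabilities are trapezoidal responses over
the species thresholds (DV0..DV3, SM0..SM3); their product, averaged over
the 52-week year and scaled to 0-100, is the annual Growth Index GI.
Four stresses (cold, heat, dry, wet) accumulate weekly exceedance beyond a
threshold at a fixed rate and are capped at 1 (lethal). A degree-day gate
requires enough thermal accumulation above DV0 (at least PDD degC-days) to
complete one generation per year. The Ecoclimatic Index is

    EI = GI * (1 - CS) * (1 - HS) * (1 - DS) * (1 - WS)    if the gate holds,
    EI = 0                                                 otherwise,

scaled 0-100. EI = 0 is unsuitable, 0 < EI < 30 marginal persistence
("overwintering"), EI >= 30 highly favourable ("perennial").

Weekly statistic assignments (an assumption the underlying model leaves
open): the weekly *mean* drives development (growth index, degree-days),
the weekly *minimum* drives cold stress and the weekly *maximum* heat
stress; dry/wet stress act on the soil-moisture fraction.

Soil hydrology is a transparent weekly bucket: rainfall in, evapotranspiration
proportional to above-zero mean temperature out, moisture clamped to
[0, sm_cap] (as a fraction of bucket capacity; values above 1 represent
waterlogging up to sm_cap). The bucket is run for two annual cycles and the
second is reported, so results are insensitive to the initial moisture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import SpeciesParams
from .stations import WEEKS_PER_YEAR, DAYS_PER_WEEK, StationClimate, WeeklySeries, monthly_to_weekly

__all__ = [
    "SoilParams",
    "AnnualResult",
    "CATEGORIES",
    "temperature_index",
    "moisture_index",
    "soil_moisture_series",
    "growth_index",
    "degree_days",
    "stress_index",
    "ecoclimatic_index",
    "classify",
    "run_station",
    "run_network",
    "results_to_frame",
]

CATEGORIES = ("unsuitable", "overwintering", "perennial")


@dataclass(frozen=True)
class SoilParams:
    """Weekly soil-moisture bucket constants.

    capacity_mm: bucket size; soil moisture is expressed as a fraction of it.
    et_coeff: evapotranspiration per degC of above-zero weekly mean
        temperature, mm degC^-1 week^-1.
    sm_init: initial moisture fraction; None means "use the species SM1".
    sm_cap: hard upper bound on the moisture fraction (waterlogging cap).
    """

    capacity_mm: float = 100.0
    et_coeff: float = 1.5
    sm_init: float | None = None
    sm_cap: float = 3.0

    def __post_init__(self) -> None:
        if self.capacity_mm <= 0:
            raise ValueError("capacity_mm must be > 0")
        if self.et_coeff < 0:
            raise ValueError("et_coeff must be >= 0")
        if self.sm_init is not None and not (0.0 <= self.sm_init <= self.sm_cap):
            raise ValueError("sm_init must lie in [0, sm_cap]")


@dataclass(frozen=True)
class AnnualResult:
    """Per-station annual outcome with all intermediate weekly series."""

    station_id: str
    TI_w: np.ndarray     # weekly temperature index, 0-1
    MI_w: np.ndarray     # weekly moisture index, 0-1
    GI_w: np.ndarray     # weekly growth index, 0-1
    SM_w: np.ndarray     # weekly soil-moisture fraction
    GI_annual: float     # 0-100
    CS: float            # cold stress, 0-1
    HS: float            # heat stress, 0-1
    DS: float            # dry stress, 0-1
    WS: float            # wet stress, 0-1
    DD_annual: float     # degC-days above DV0
    pdd_met: bool
    EI: float            # 0-100
    category: str


def _trapezoid(x, lo, opt_lo, opt_hi, hi):
    xp = np.array([lo, opt_lo, opt_hi, hi], dtype=float)
    fp = np.array([0.0, 1.0, 1.0, 0.0])
    return np.interp(np.asarray(x, dtype=float), xp, fp)


def temperature_index(tmean, p: SpeciesParams):
    """Weekly temperature suitability: 0 at/below DV0, 1 on [DV1, DV2], 0 at/above DV3."""
    return _trapezoid(tmean, p.DV0, p.DV1, p.DV2, p.DV3)


def moisture_index(sm, p: SpeciesParams):
    """Weekly moisture suitability: trapezoid over (SM0, SM1, SM2, SM3)."""
    return _trapezoid(sm, p.SM0, p.SM1, p.SM2, p.SM3)


def soil_moisture_series(ws: WeeklySeries, soil: SoilParams,
                         sm_init: float | None = None) -> np.ndarray:
    """Weekly soil-moisture fraction from the bucket recurrence.

    SM_{w+1} = clamp(SM_w + rain_w/capacity - et_coeff * max(0, tmean_w)/capacity,
                     0, sm_cap)

    Two annual cycles are run and the second reported (spin-up), so the
    result is insensitive to the initial moisture whenever the dynamics
    contract (any week that hits a clamp erases the initial condition).
    """
    if sm_init is None:
        sm_init = soil.sm_init if soil.sm_init is not None else 0.31
    inflow = ws.rain_w / soil.capacity_mm
    outflow = soil.et_coeff * np.maximum(0.0, ws.tmean_w) / soil.capacity_mm
    sm = float(sm_init)
    out = np.empty(WEEKS_PER_YEAR)
    for cycle in range(2):
        for w in range(WEEKS_PER_YEAR):
            if cycle == 1:
                out[w] = sm
            sm = min(max(sm + inflow[w] - outflow[w], 0.0), soil.sm_cap)
    return out


def growth_index(TI_w, MI_w) -> tuple[np.ndarray, float]:
    """Weekly growth index GI_w = TI_w * MI_w and annual GI = 100 * mean(GI_w)."""
    TI_w = np.asarray(TI_w, dtype=float)
    MI_w = np.asarray(MI_w, dtype=float)
    if TI_w.shape != (WEEKS_PER_YEAR,) or MI_w.shape != (WEEKS_PER_YEAR,):
        raise ValueError(f"TI_w and MI_w must both have length {WEEKS_PER_YEAR}")
    GI_w = TI_w * MI_w
    return GI_w, 100.0 * float(np.mean(GI_w))


def degree_days(ws: WeeklySeries, p: SpeciesParams) -> tuple[float, bool]:
    """Annual degree-days above DV0 and whether they reach PDD.

    DD = sum_w 7 * max(0, tmean_w - DV0); one generation requires DD >= PDD.
    """
    dd = float(DAYS_PER_WEEK * np.sum(np.maximum(0.0, ws.tmean_w - p.DV0)))
    return dd, dd >= p.PDD


def _spell_lengths_cyclic(stressed: np.ndarray) -> np.ndarray:
    """k_w = number of consecutive stressed weeks ending at w, wrapping the year
    boundary (a cold spell centred on New Year is one spell, not two)."""
    n = stressed.size
    k = np.zeros(n)
    if not stressed.any():
        return k
    if stressed.all():
        return np.arange(1.0, n + 1.0)
    start = int(np.argmin(stressed))  # an unstressed week to anchor the scan
    run = 0
    for i in range(n):
        idx = (start + i) % n
        run = run + 1 if stressed[idx] else 0
        k[idx] = run
    return k


def stress_index(series_w, threshold: float, rate: float, direction: str,
                 spell_weighting: bool = True) -> float:
    """Annual stress index in [0, 1] from weekly threshold exceedance.

    Weekly exceedance is max(0, threshold - x) for direction='below' (cold,
    dry) or max(0, x - threshold) for direction='above' (heat, wet). Raw
    stress is sum_w rate * e_w * k_w, where k_w is the length of the
    consecutive stress spell ending at week w — persistent stress is
    super-linearly worse than the same exceedance scattered through the
    year. With spell_weighting=False the plain sum (k_w = 1) is used; the
    two agree whenever every stressed week is isolated. The result is
    capped at 1 (lethal).
    """
    if rate < 0:
        raise ValueError("stress accumulation rate must be >= 0")
    x = np.asarray(series_w, dtype=float)
    if direction == "below":
        e = np.maximum(0.0, threshold - x)
    elif direction == "above":
        e = np.maximum(0.0, x - threshold)
    else:
        raise ValueError("direction must be 'below' or 'above'")
    k = _spell_lengths_cyclic(e > 0) if spell_weighting else (e > 0).astype(float)
    raw = rate * float(np.sum(e * k))
    return min(1.0, raw)


def ecoclimatic_index(gi_annual: float, CS: float, HS: float, DS: float, WS: float,
                      pdd_met: bool) -> float:
    """EI = GI * (1-CS)(1-HS)(1-DS)(1-WS) if the degree-day gate holds, else 0."""
    for name, s in (("CS", CS), ("HS", HS), ("DS", DS), ("WS", WS)):
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {s}")
    if not pdd_met:
        return 0.0
    ei = gi_annual * (1.0 - CS) * (1.0 - HS) * (1.0 - DS) * (1.0 - WS)
    return min(100.0, max(0.0, ei))


def classify(ei: float, unsuitable_cutoff: float = 0.0) -> str:
    """EI <= cutoff (default 0) -> unsuitable; < 30 -> overwintering; >= 30 -> perennial."""
    if ei <= unsuitable_cutoff:
        return "unsuitable"
    if ei < 30.0:
        return "overwintering"
    return "perennial"


def run_station(st: StationClimate, p: SpeciesParams,
                soil: SoilParams | None = None,
                spell_weighting: bool = True) -> AnnualResult:
    """Full pipeline for one station: weekly expansion, soil bucket, indices,
    stresses, degree-day gate, EI and category."""
    soil = soil or SoilParams()
    ws = monthly_to_weekly(st)
    sm_init = soil.sm_init if soil.sm_init is not None else p.SM1
    SM_w = soil_moisture_series(ws, soil, sm_init=sm_init)
    TI_w = temperature_index(ws.tmean_w, p)
    MI_w = moisture_index(SM_w, p)
    GI_w, gi_annual = growth_index(TI_w, MI_w)
    CS = stress_index(ws.tmin_w, p.TTCS, p.THCS, "below", spell_weighting)
    HS = stress_index(ws.tmax_w, p.TTHS, p.THHS, "above", spell_weighting)
    DS = stress_index(SM_w, p.SMDS, p.HDS, "below", spell_weighting)
    WS = stress_index(SM_w, p.SMWS, p.HWS, "above", spell_weighting)
    dd, pdd_met = degree_days(ws, p)
    ei = ecoclimatic_index(gi_annual, CS, HS, DS, WS, pdd_met)
    return AnnualResult(
        station_id=st.station_id,
        TI_w=TI_w, MI_w=MI_w, GI_w=GI_w, SM_w=SM_w,
        GI_annual=gi_annual,
        CS=CS, HS=HS, DS=DS, WS=WS,
        DD_annual=dd, pdd_met=pdd_met,
        EI=ei, category=classify(ei),
    )


def run_network(stations: list[StationClimate], p: SpeciesParams,
                soil: SoilParams | None = None,
                spell_weighting: bool = True) -> list[AnnualResult]:
    """Run the pipeline over a station list (order preserved)."""
    return [run_station(st, p, soil, spell_weighting) for st in stations]


def results_to_frame(stations: list[StationClimate],
                     results: list[AnnualResult]) -> pd.DataFrame:
    """Tabulate per-station results (station_id, lat, lon, GI, stresses, DD,
    EI, category); stress indices are also given as x100 percentages."""
    if len(stations) != len(results):
        raise ValueError("stations and results must have equal length")
    rows = []
    for st, r in zip(stations, results):
        rows.append({
            "station_id": st.station_id, "lat": st.lat, "lon": st.lon,
            "GI": r.GI_annual, "CS": r.CS, "HS": r.HS, "DS": r.DS, "WS": r.WS,
            "CS_pct": 100 * r.CS, "HS_pct": 100 * r.HS,
            "DS_pct": 100 * r.DS, "WS_pct": 100 * r.WS,
            "DD": r.DD_annual, "pdd_met": r.pdd_met,
            "EI": r.EI, "category": r.category,
        })
    return pd.DataFrame(rows)
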