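# Methods

## Model

The package implements a compare-locations ecoclimatic suitability model:
each location is assumed to offer the species one season favourable for
population growth and one unfavourable (stress) season, and the annual
balance of the two is summarised by the Ecoclimatic Index (EI, 0–100).

**Time base.** The model year is exactly 52 weeks × 7 days = 364 days.
Monthly temperature normals are placed at the day-centres of the civil
months (365-day calendar rescaled by 364/365) and interpolated linearly
and periodically to week mid-points, so December–January transitions are
smooth. Monthly rainfall is spread uniformly within each (rescaled) month
and summed over each week's day span; this apportionment conserves the
annual total to floating-point precision. The fixed 52-week grid keeps the
per-week stress rates and all accumulators aligned across stations and
hemispheres; southern-hemisphere stations need no special casing because
the seasonal cycle is whatever the monthly normals say.

**Growth.** Weekly temperature suitability TI and moisture suitability MI
are piecewise-linear trapezoids over the species thresholds (DV0, DV1,
DV2, DV3) and (SM0, SM1, SM2, SM3): zero at or outside the outer
thresholds, one between the inner pair, linear between. The trapezoid is
the simplest shape consistent with lower/optimum/upper threshold
semantics; nothing in the packaged parameter values depends on the ramp
curvature. GI_annual = 100 · mean(TI·MI).

**Which weekly statistic drives what.** The weekly *mean* temperature
drives development (TI and degree-days); the weekly *minimum* drives cold
stress and the weekly *maximum* heat stress. Stress thresholds describe
extremes, so feeding them the corresponding extreme statistic is the
conservative reading; it is an assumption of this implementation, not a
property forced by the parameter values.

**Soil moisture.** A transparent weekly bucket replaces the opaque
hydrology of desktop implementations: with capacity C (default 100 mm),

    SM_{w+1} = clamp(SM_w + rain_w/C − k·max(0, T_w)/C, 0, sm_cap)

where k is an evapotranspiration coefficient (default 1.5 mm per °C of
above-zero weekly mean temperature per week) and sm_cap (default 3.0, as a
fraction of capacity) allows waterlogging above field capacity. Moisture is
reported as a fraction of C so the SM0..SM3 and SMDS/SMWS thresholds are
dimensionless. The recurrence is run for two annual cycles and the second
is reported; any week that touches a clamp erases the initial condition,
so for all realistic forcing the spin-up removes the dependence on the
initial moisture (default: the species' SM1). All four constants live in
`SoilParams` and are echoed in output metadata.

**Stress accumulation.** Weekly exceedance e_w beyond a threshold (below
it for cold/dry, above it for heat/wet) accumulates as
`raw = Σ_w rate · e_w · k_w`, where k_w is the length of the run of
consecutive stressed weeks ending at week w, and the index is
`min(1, raw)`. The spell weighting makes persistent stress super-linearly
worse than the same exceedance scattered through the year, which matches
the biology motivating the cold-stress parameters (the species cannot
endure *persistent* low temperature). Spell runs are counted cyclically
across the week-52/week-1 boundary, because a northern-hemisphere cold
spell is centred on New Year and a linear scan would artificially split it
in two; when every week is stressed the run length caps at 52. A
plain-sum variant (`spell_weighting=False`) exists for cross-checking; the
two coincide exactly whenever every stressed week is isolated. All four
rates are stored as nonnegative magnitudes — the direction of accumulation
is part of the model, so signs printed inconsistently in source literature
cannot introduce sign bugs.

**Generation gate and EI.** Annual degree-days above DV0,
`DD = Σ_w 7·max(0, T_w − DV0)`, must reach PDD (265.6 °C·days for the
packaged species) for the location to support one generation per year; the
gate is binary — EI is zeroed when it fails, which treats thermal
insufficiency as a viability requirement rather than a graded penalty.
Otherwise `EI = GI·(1−CS)(1−HS)(1−DS)(1−WS)`, clamped to [0, 100].
Categories: EI ≤ 0 unsuitable, 0 < EI < 30 overwintering, EI ≥ 30
perennial. The unsuitable cutoff is exactly 0 by default and configurable,
since map legends sometimes use a small positive cutoff instead.

**Out of scope.** The four stress-interaction indices (cold–wet, cold–dry,
heat–wet, heat–dry), degree-day-based cold stress, irrigation scenarios,
and compare-years mode are deliberately not implemented: they are not
parameterised for the packaged species.

## Calibration

The historical fitting of the cold/heat stress parameters was a manual
map-matching loop. It is formalised here as minimisation of the
misclassification count of the persistence predicate `EI > 0` over labeled
stations (`present` = recorded to persist/overwinter). Optimisation is
coordinate descent over finite per-parameter grids with a deterministic
tie-break (prefer the value closest to the initial parameter, then the
smaller value), stopping at a fixed point or after `max_cycles` cycles;
the accepted objective is non-increasing, so the result is never worse
than the start, and on small grids it provably reaches the exhaustive-grid
minimum (checked in tests). False presences and false absences are
weighted equally by default, with weights exposed, because over-prediction
and under-prediction are both real failure modes. The count objective is
an explicit formalisation of "consistent with the known distribution",
not a uniquely forced choice.

## Mapping

Station EI values are interpolated onto a regular WGS84 grid (cell-centre
registration, rows south-to-north in memory, written north-up). Distances
are great-circle kilometres (haversine); the domains of interest span
>20° of latitude, where planar degree distances distort. IDW uses power 2
and a cutoff radius (cells farther than the cutoff from every station are
no-data). Ordinary kriging uses an exponential variogram
`γ(h) = nugget + psill·(1−exp(−h/range))` fitted by weighted least squares
(bin-count weights) to the empirical variogram, a nearest-12-station
neighbourhood, and γ(0) = 0 on the system diagonal so both methods honour
station values exactly; a singular or degenerate system (e.g. a constant
field) falls back to IDW with a logged warning. Interpolated values are
clamped to [0, 100], and the category layer is derived cell-wise from the
EI layer, so the two can never disagree.

Boundary estimation reports, per longitude column, the southern- and
northern-most cell-centre latitudes satisfying a predicate, and the median
across columns. The overwintering band {0 < EI < 30} has its northern
edge at the EI>0 northern limit and its southern edge at the northern
limit of the EI ≥ 30 region.

Outputs are plain text: ESRI ASCII grids (EI band plus a category-code
band: 0 unsuitable, 1 overwintering, 2 perennial) and GeoJSON polygons
dissolved per category.

## Synthetic climate generator

The generator emulates the first-order structure an ecoclimatic model
responds to, and only that: monthly mean temperature
`t_equator − lapse_lat·|lat| + (amp0 + amp_lat·|lat|)·cos(2π(m − m_peak)/12)`
with the phase peak in July north of the equator and January south of it;
tmin/tmax a fixed diurnal half-range below/above the mean; monthly
rainfall proportional to `exp(conc·cos(2π(m − peak)/12))` normalised to an
annual total; optional Gaussian noise on monthly temperatures only
(rainfall noise would couple into the bucket model and obscure what a test
is exercising). Noise streams are seeded from the spec seed plus the
station coordinates, so networks are bit-reproducible and insensitive to
generation order.

The "China-like transect" preset (18–40 °N) uses t_equator = 27.5 °C,
lapse 0.25 °C/°lat, amplitude 0.5 + 0.33·|lat| °C, diurnal half-range
5 °C, and 1300 mm/yr of rain concentrated on July (concentration 1.2).
These values were chosen once so the preset reproduces the qualitative
geography the packaged species' parameters respond to: mild winters
(weekly minima above 3.2 °C) near the Tropic of Cancer, winters several
degrees below that threshold at 40 °N, and rainfall in phase with the
warm season so that soil moisture passes through the favourable band
during the growing season. Under the final parameter set the transect
shows perennial conditions south of ≈ 22 °N, an overwintering band to
≈ 33.5 °N, and unsuitable stations beyond — a deliberately simplified
analogue of the real south-to-north gradient, not a reconstruction of
Chinese climatology.

What the generator does *not* emulate: interannual variability, monsoon
asymmetry (onset/retreat), elevation effects, coast–inland moisture
gradients, and observational error structure. Tests passing on synthetic
networks therefore demonstrate the internal correctness and qualitative
behaviour of the pipeline, not predictive skill on real station data.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use a 45-station noise-free
transect, a 45×5 station network kriged to a 0.5° grid, 20 seeded
calibration replicates with 0.6 °C monthly noise, and 100-station
randomised pools for composition/conservation checks; each component runs
in seconds at these sizes and scales linearly in stations × weeks.
Tolerances: closed-form index comparisons at 1e-12 (pure arithmetic),
rainfall conservation at 1e-6 mm, interpolation exactness at stations at
1e-6. Ties in the calibration grid break toward the initial value, then
the smaller value. Degenerate inputs: empty station lists, empty grids,
all-stressed and never-stressed weeks, constant interpolation fields and
single-cell rasters all have defined behaviour covered by tests.

## Known limitations

- The soil bucket is a deliberate simplification; its constants (capacity,
  ET coefficient, cap) shift the absolute EI values, so comparisons are
  meaningful within a fixed `SoilParams`, not across them.
- The weekly statistic assigned to each stress (min for cold, max for
  heat) is an assumption; with large diurnal ranges it is conservative.
- The EI ≥ 30 / EI > 0 category cutoffs are conventions inherited from
  the compare-locations literature, not fitted quantities.
- Kriging assumes second-order stationarity of the EI field; on strongly
  banded fields the fitted range absorbs the latitudinal trend rather
  than modelling it (no universal-kriging drift term is implemented).
- The 14 fieldwork sites carry point observations from specific winters;
  agreement statistics against them are indicative, not a validation of
  long-term climatology.
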