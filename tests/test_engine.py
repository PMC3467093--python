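"""Model core: index shapes, soil bucket, stress accumulation, EI pipeline."""

import numpy as np
import pytest

import ecoclim as ec
from ecoclim.engine import (SoilParams, classify, degree_days, ecoclimatic_index,
                            growth_index, moisture_index, run_station,
                            soil_moisture_series, stress_index, temperature_index)
from ecoclim.stations import WeeklySeries, monthly_to_weekly
from ecoclim.synthetic import ClimateFieldSpec


def weekly(tmean, rain=30.0, sid="W"):
    tmean = np.full(52, tmean, float) if np.isscalar(tmean) else np.asarray(tmean, float)
    rain = np.full(52, rain, float) if np.isscalar(rain) else np.asarray(rain, float)
    return WeeklySeries(station_id=sid, tmin_w=tmean - 5, tmax_w=tmean + 5,
                        tmean_w=tmean, rain_w=rain)


def ti_scalar(t, p):
    # independent direct evaluation of the stated trapezoid
    if t <= p.DV0 or t >= p.DV3:
        return 0.0
    if t < p.DV1:
        return (t - p.DV0) / (p.DV1 - p.DV0)
    if t <= p.DV2:
        return 1.0
    return (p.DV3 - t) / (p.DV3 - p.DV2)


class TestTemperatureIndex:
    def test_plateau_between_optima(self, final_params):
        assert temperature_index(27.0, final_params) == 1.0

    def test_zero_below_development_threshold(self, final_params):
        assert temperature_index(10.0, final_params) == 0.0

    def test_lower_ramp_value(self, final_params):
        expected = (20 - 15.06) / (26 - 15.06)
        assert temperature_index(20.0, final_params) == pytest.approx(expected, abs=1e-12)

    def test_matches_scalar_oracle_on_random_inputs(self, final_params, rng):
        t = rng.uniform(-10, 50, size=500)
        got = temperature_index(t, final_params)
        want = [ti_scalar(x, final_params) for x in t]
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestMoistureIndex:
    def test_examples(self, final_params):
        assert moisture_index(0.5, final_params) == 1.0
        assert moisture_index(0.01, final_params) == 0.0
        assert moisture_index(1.5, final_params) == pytest.approx(0.5, abs=1e-12)


class TestSoilMoisture:
    def test_drainage_only_limit_reaches_zero(self):
        sm = soil_moisture_series(weekly(20.0, rain=0.0), SoilParams())
        assert np.all(np.diff(sm) <= 1e-12)
        assert sm[-1] == 0.0

    def test_fill_only_limit_reaches_cap(self):
        soil = SoilParams(et_coeff=0.0)
        sm = soil_moisture_series(weekly(-5.0, rain=20.0), soil, sm_init=0.0)
        assert sm[-1] == soil.sm_cap
        # before the cap binds the rise is exactly rain/capacity per week
        rising = np.diff(sm)[sm[:-1] < soil.sm_cap - 0.2]
        np.testing.assert_allclose(rising, 0.2, atol=1e-12)

    def test_interior_fixed_point_matches_iterated_oracle(self):
        # constant forcing with an interior equilibrium: the second cycle
        # must sit at the fixed point found by iterating the recurrence
        soil = SoilParams()
        ws = weekly(20.0, rain=30.0)   # in 0.30/wk, out 0.30/wk: neutral drift
        sm = soil_moisture_series(ws, soil, sm_init=0.5)
        x = 0.5
        for _ in range(104):
            x = min(max(x + 30.0 / 100 - 1.5 * 20.0 / 100, 0.0), soil.sm_cap)
        assert sm[0] == pytest.approx(x, abs=1e-12)

    def test_spinup_insensitive_to_init_when_clamped(self):
        ws = weekly(25.0, rain=5.0)    # strongly draining: hits the 0 clamp
        a = soil_moisture_series(ws, SoilParams(), sm_init=0.0)
        b = soil_moisture_series(ws, SoilParams(), sm_init=2.5)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_bounds_always_hold(self, rng):
        from conftest import random_station
        for _ in range(20):
            ws = monthly_to_weekly(random_station(rng))
            sm = soil_moisture_series(ws, SoilParams())
            assert np.all(sm >= 0.0) and np.all(sm <= 3.0)


class TestGrowthIndex:
    def test_perfect_year(self):
        _, gi = growth_index(np.ones(52), np.ones(52))
        assert gi == 100.0

    def test_moisture_annihilation(self):
        _, gi = growth_index(np.ones(52), np.zeros(52))
        assert gi == 0.0

    def test_half_year(self):
        ti = np.zeros(52)
        ti[:26] = 1.0
        _, gi = growth_index(ti, np.ones(52))
        assert gi == pytest.approx(50.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            growth_index(np.ones(10), np.ones(52))


class TestDegreeDays:
    def test_boundary_temperature_accumulates_nothing(self, final_params):
        dd, met = degree_days(weekly(final_params.DV0), final_params)
        assert dd == 0.0 and not met

    def test_constant_twenty_degrees(self, final_params):
        dd, met = degree_days(weekly(20.0), final_params)
        assert dd == pytest.approx(364 * (20 - 15.06), rel=1e-12)
        assert met  # 1798 degC-days >> 265.6

    def test_marginally_warm_year_fails_gate(self, final_params):
        dd, met = degree_days(weekly(15.5), final_params)
        assert dd == pytest.approx(364 * 0.44, rel=1e-9)
        assert dd < final_params.PDD and not met


def plain_sum_oracle(series, threshold, rate, direction):
    """Independent spell-weighted sum via an explicit loop (cyclic)."""
    e = [max(0.0, threshold - x) if direction == "below" else max(0.0, x - threshold)
         for x in series]
    n = len(e)
    raw = 0.0
    for w in range(n):
        if e[w] <= 0:
            continue
        k = 0
        for back in range(n):
            if e[(w - back) % n] > 0:
                k += 1
            else:
                break
        raw += rate * e[w] * min(k, n)
    return min(1.0, raw)


class TestStressIndex:
    def test_safe_series_accumulates_nothing(self, final_params):
        assert stress_index(np.full(52, 10.0), final_params.TTCS, 0.2, "below") == 0.0

    def test_zero_rate_gives_zero_stress(self):
        assert stress_index(np.full(52, -20.0), 3.2, 0.0, "below") == 0.0

    def test_ten_week_cold_spell_is_lethal(self, final_params):
        tmin = np.full(52, 10.0)
        tmin[20:30] = final_params.TTCS - 1.0
        # raw = 0.2 * sum_{k=1..10} k = 11 -> capped at 1
        assert stress_index(tmin, final_params.TTCS, 0.20, "below") == 1.0

    def test_isolated_weeks_reduce_to_plain_sum(self):
        series = np.full(52, 10.0)
        series[::2] = 2.0          # alternating stress weeks, all spells length 1
        spell = stress_index(series, 3.0, 0.01, "below", spell_weighting=True)
        plain = stress_index(series, 3.0, 0.01, "below", spell_weighting=False)
        assert spell == pytest.approx(plain, abs=1e-15)

    def test_matches_explicit_loop_oracle(self, rng):
        for _ in range(50):
            series = rng.uniform(-5, 15, size=52)
            got = stress_index(series, 3.2, 0.02, "below")
            want = plain_sum_oracle(series, 3.2, 0.02, "below")
            assert got == pytest.approx(want, abs=1e-12)

    def test_cold_spell_across_year_boundary_counts_as_one_spell(self):
        tmin = np.full(52, 10.0)
        tmin[-5:] = 2.2            # 5 weeks at year end ...
        tmin[:5] = 2.2             # ... continuing into the new year
        wrapped = stress_index(tmin, 3.2, 0.01, "below")
        # oracle: one 10-week spell with exceedance 1
        assert wrapped == pytest.approx(min(1.0, 0.01 * 1.0 * sum(range(1, 11))), abs=1e-12)

    def test_above_direction(self):
        tmax = np.full(52, 30.0)
        tmax[10] = 40.0
        got = stress_index(tmax, 36.0, 0.1, "above")
        assert got == pytest.approx(0.1 * 4.0, abs=1e-12)


class TestEcoclimaticIndex:
    def test_lethal_cold_zeroes_ei(self):
        assert ecoclimatic_index(80.0, 1.0, 0, 0, 0, True) == 0.0

    def test_stress_free_perfect_year(self):
        assert ecoclimatic_index(100.0, 0, 0, 0, 0, True) == 100.0

    def test_single_stress_product(self):
        assert ecoclimatic_index(60.0, 0.5, 0, 0, 0, True) == pytest.approx(30.0, abs=1e-12)

    def test_failed_degree_day_gate_zeroes_ei(self):
        assert ecoclimatic_index(60.0, 0, 0, 0, 0, False) == 0.0

    def test_stress_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ecoclimatic_index(60.0, 1.5, 0, 0, 0, True)


class TestClassify:
    @pytest.mark.parametrize("ei,cat", [
        (0.0, "unsuitable"), (15.0, "overwintering"), (45.0, "perennial"),
        (29.999, "overwintering"), (30.0, "perennial"),
    ])
    def test_categories(self, ei, cat):
        assert classify(ei) == cat

    def test_configurable_cutoff(self):
        assert classify(0.5, unsuitable_cutoff=1.0) == "unsuitable"


def hand_composed(st, p, soil=None):
    """Brute-force composition of the individual operations."""
    soil = soil or SoilParams()
    ws = monthly_to_weekly(st)
    sm = soil_moisture_series(ws, soil, sm_init=p.SM1)
    ti = temperature_index(ws.tmean_w, p)
    mi = moisture_index(sm, p)
    _, gi = growth_index(ti, mi)
    cs = stress_index(ws.tmin_w, p.TTCS, p.THCS, "below")
    hs = stress_index(ws.tmax_w, p.TTHS, p.THHS, "above")
    ds = stress_index(sm, p.SMDS, p.HDS, "below")
    wsx = stress_index(sm, p.SMWS, p.HWS, "above")
    dd, met = degree_days(ws, p)
    ei = ecoclimatic_index(gi, cs, hs, ds, wsx, met)
    return ei, classify(ei)


class TestRunStation:
    def test_tropical_station_is_perennial(self, final_params):
        spec = ClimateFieldSpec(t_equator=27.5, lapse_lat=0.25, amp0=0.5,
                                amp_lat=0.33, diurnal=5.0, rain_annual=1300.0,
                                rain_season_peak_month=7, rain_concentration=1.2)
        st = ec.generate_station(18.0, 110.0, spec)
        r = run_station(st, final_params)
        assert r.category == "perennial" and r.EI >= 30

    def test_arctic_station_is_unsuitable(self, final_params):
        spec = ClimateFieldSpec(t_equator=5.0, lapse_lat=0.0, amp0=5.0,
                                amp_lat=0.0, diurnal=5.0, rain_annual=500.0)
        st = ec.generate_station(70.0, 20.0, spec)
        r = run_station(st, final_params)
        assert r.GI_annual == 0.0 and r.EI == 0.0 and r.category == "unsuitable"

    def test_temperate_sits_between_zero_and_tropical(self, final_params, transect):
        tropical = run_station(transect[0], final_params)     # 18N
        temperate = run_station(transect[22], final_params)   # 29N
        assert 0.0 < temperate.EI < tropical.EI

    def test_equals_hand_composition_bit_exactly(self, final_params, rng):
        from conftest import random_station
        for _ in range(25):
            st = random_station(rng)
            r = run_station(st, final_params)
            ei, cat = hand_composed(st, final_params)
            assert r.EI == ei and r.category == cat

    def test_ei_never_exceeds_gi(self, final_params, rng):
        from conftest import random_station
        for _ in range(25):
            r = run_station(random_station(rng), final_params)
            assert 0.0 <= r.EI <= r.GI_annual + 1e-12
            assert not r.pdd_met or r.DD_annual >= final_params.PDD
            assert r.pdd_met or r.EI == 0.0


class TestMonotonicity:
    def test_ei_monotone_in_stress_and_gi(self, rng):
        for _ in range(200):
            gi = rng.uniform(0, 100)
            s = rng.uniform(0, 1, size=4)
            base = ecoclimatic_index(gi, *s, True)
            bumped = np.minimum(s + 0.1, 1.0)
            assert ecoclimatic_index(gi, *bumped, True) <= base + 1e-12
            assert ecoclimatic_index(min(gi + 5, 100), *s, True) >= base - 1e-12

    def test_raising_cold_threshold_never_helps(self, initial_params, final_params, transect):
        # the iteration raised TTCS 0.73 -> 3.2 degC to shrink the
        # predicted range: CS may only rise, EI may only fall
        low = initial_params
        high = initial_params.replace(TTCS=final_params.TTCS)
        for st in transect[::4]:
            r_low, r_high = run_station(st, low), run_station(st, high)
            assert r_high.CS >= r_low.CS - 1e-12
            assert r_high.EI <= r_low.EI + 1e-12

    def test_transect_categories_latitudinally_monotone(self, final_params, transect):
        order = {"perennial": 0, "overwintering": 1, "unsuitable": 2}
        seq = [order[run_station(st, final_params).category] for st in transect]
        assert all(a <= b for a, b in zip(seq, seq[1:]))
        assert len(set(seq)) == 3   # all three bands present
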