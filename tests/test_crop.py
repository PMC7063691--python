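"""Crop model: elementary process operations, the season recurrence against
an independent straight-line oracle, and the model's physical invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wheatgap.crop import (
    CultivarParams,
    DEFAULT_CONFIG,
    Management,
    SoilProfile,
    StressParams,
    daily_thermal_time,
    drought_stress_gn_reduction,
    heat_stress_gn_reduction,
    photoperiod_factor,
    senescence_multiplier,
    simulate_multi_year,
    simulate_season,
    soil_water_step,
    yield_stats,
    SeasonResult,
)
from wheatgap.weather import WeatherSeries, site_preset

from conftest import constant_slice


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "tmin,tmax,t_base,expected",
    [(5, 15, 0, 10.0), (-10, -2, 0, 0.0), (-2, 10, 0, 4.0)],
)
def test_daily_thermal_time(tmin, tmax, t_base, expected):
    assert daily_thermal_time(tmin, tmax, t_base) == expected


def test_daily_thermal_time_rejects_inverted_range():
    with pytest.raises(ValueError):
        daily_thermal_time(15, 5, 0)


@pytest.mark.parametrize(
    "daylength,p_p,expected",
    [(16.0, 0.9, 1.0), (10.0, 0.0, 1.0), (10.0, 0.7, 0.5)],
)
def test_photoperiod_factor(daylength, p_p, expected):
    assert photoperiod_factor(daylength, p_p) == pytest.approx(expected)


def test_photoperiod_factor_floor():
    assert photoperiod_factor(6.0, 1.0) == DEFAULT_CONFIG.f_min


def test_soil_water_step_examples():
    stored, transp, drain, stress = soil_water_step(100, 0, 0, 0.1, 177)
    assert (stored, transp, drain, stress) == (100, 0, 0, 1.0)
    stored, transp, drain, stress = soil_water_step(50, 0, 10, 0.1, 177)
    assert transp == pytest.approx(5.0)
    assert stress == pytest.approx(0.5)
    stored, transp, drain, stress = soil_water_step(170, 20, 0, 0.1, 177)
    assert drain == pytest.approx(13.0)
    with pytest.raises(ValueError):
        soil_water_step(-1, 0, 0, 0.1, 177)


@settings(max_examples=200, derandomize=True)
@given(
    stored=st.floats(0, 177),
    precip=st.floats(0, 80),
    pot=st.floats(0, 12),
    r_u=st.floats(0.005, 0.3),
)
def test_soil_water_step_mass_balance(stored, precip, pot, r_u):
    new, transp, drain, stress = soil_water_step(stored, precip, pot, r_u, 177.0)
    assert abs((stored + precip) - (new + transp + drain)) < 1e-9
    assert 0.0 <= new <= 177.0
    assert transp >= 0 and drain >= 0
    assert 0.0 <= stress <= 1.0


def test_heat_stress_reduction():
    assert heat_stress_gn_reduction([20, 21, 22], 27, 0.05) == 0.0
    assert heat_stress_gn_reduction([32], 27, 0.04) == pytest.approx(0.20)
    assert heat_stress_gn_reduction([45] * 10, 27, 0.05) == 1.0
    with pytest.raises(ValueError):
        heat_stress_gn_reduction([], 27, 0.05)


def test_drought_stress_reduction():
    assert drought_stress_gn_reduction([0.9, 1.0], 0.6, 0.3, 0.9) == 0.0
    assert drought_stress_gn_reduction([0.1], 0.6, 0.3, 0.9) == pytest.approx(0.15)
    assert drought_stress_gn_reduction([0.0] * 20, 0.6, 0.3, 0.9) == 0.9
    with pytest.raises(ValueError):
        drought_stress_gn_reduction([], 0.6, 0.3, 0.9)


def test_senescence_multiplier():
    assert senescence_multiplier(1.0, 3.0) == 1.0
    assert senescence_multiplier(0.0, 3.0) == 3.0
    assert senescence_multiplier(0.5, 2.0) == 1.5
    with pytest.raises(ValueError):
        senescence_multiplier(0.5, 0.9)


# ---------------------------------------------------------------------------
# season simulation
# ---------------------------------------------------------------------------

BENIGN = dict(tmin=8.0, tmax=18.0, precip=5.0, rad=18.0)


def test_zero_radiation_season_produces_nothing(soil):
    cv = CultivarParams()
    w = constant_slice(8, 18, 5, 0.0)
    res = simulate_season(cv, w, soil, Management())
    assert res.yield_t_ha == 0.0
    assert res.biomass_t_ha == 0.0


def test_short_slice_rejected(soil):
    w = constant_slice(**BENIGN, n=200)
    with pytest.raises(ValueError):
        simulate_season(CultivarParams(), w, soil, Management())


def test_non_finite_weather_rejected(soil):
    w = constant_slice(**BENIGN)
    w.rad[100] = np.nan
    with pytest.raises(ValueError):
        simulate_season(CultivarParams(), w, soil, Management())


def _straight_line_oracle(cv: CultivarParams, tmin, tmax, precip, rad,
                          soil: SoilProfile, n=365):
    """Independent day-by-day recomputation of the season recurrence under
    constant forcing and no photoperiod sensitivity (p_p = 0), written
    directly from the documented model equations."""
    c = DEFAULT_CONFIG
    tt = max(0.0, (tmin + tmax) / 2.0 - cv.t_base)
    par = c.par_fraction * rad
    lai_max = c.lai_base + cv.a_max
    sen_dur = c.sen_base_tt * (1.0 + cv.s_g)

    biomass = 0.0
    grain = 0.0
    stored = soil.initial_fill * soil.awc
    lai = 0.0
    cum_tt = 0.0
    anth = None
    lai_a = 0.0
    labile = 0.0
    labile_left = 0.0
    fill = 0.0
    sink = math.inf
    gn_base = 0.0
    for i in range(n):
        if anth is None:
            cum_tt += tt  # p_p = 0 so the photoperiod factor is 1
            lai = lai_max * min(1.0, cum_tt / (c.n_leaf * cv.p_h))
        ipar = par * (1.0 - math.exp(-cv.k_ext * lai))
        pot = c.transp_per_ipar * ipar
        infil = min(stored + precip, soil.awc)
        transp = min(pot, cv.r_u * infil)
        stress = transp / pot if pot > 0 else 1.0
        stored = infil - transp
        biomass += cv.rue * cv.lue_multiplier * ipar * stress
        if anth is None and cum_tt >= (c.n_leaf + c.tt_offset_phyllochrons) * cv.p_h:
            anth = i
            lai_a = lai
            gn_base = cv.grains_per_g * biomass
            labile = cv.labile_frac * biomass
            labile_left = labile
        elif anth is not None and i > anth:
            lai = max(0.0, lai - lai_a * (tt / sen_dur)
                      * (1.0 + (cv.w_ss - 1.0) * (1.0 - stress)))
            fill += tt
            d = min(labile_left, labile * tt / cv.g_f)
            labile_left -= d
            grain = min(grain + cv.rue * cv.lue_multiplier * ipar * stress + d, sink)
            if i == anth + c.flowering_halfwidth:
                # constant benign forcing: tmax below the heat threshold and
                # the profile stays wet, so grain number is undamaged
                sink = gn_base * cv.max_grain_wt * 1e-3
                grain = min(grain, sink)
            if fill >= cv.g_f or lai <= 0.0:
                return grain * 0.01, biomass * 0.01, i
    return grain * 0.01, biomass * 0.01, n - 1


def test_constant_forcing_matches_straight_line_oracle(soil):
    """Under constant benign forcing the whole recurrence has a straight-line
    form; the simulator must match an independent recomputation to six
    significant figures."""
    cv = CultivarParams(p_p=0.0)
    w = constant_slice(**BENIGN)
    res = simulate_season(cv, w, soil, Management())
    y, b, mat = _straight_line_oracle(cv, **BENIGN, soil=soil)
    assert res.yield_t_ha == pytest.approx(y, rel=1e-6)
    assert res.biomass_t_ha == pytest.approx(b, rel=1e-6)
    assert res.maturity_das == mat
    assert 0 < res.anthesis_das < res.maturity_das


def test_flowering_heat_day_cuts_grain_number_by_the_closed_form(soil):
    """One flowering-window day at threshold + 5 degC must reduce grain
    number by exactly hsgnr * 5 in a sensitive cultivar, and reduce yield
    when grain number limits it."""
    cv = CultivarParams(p_p=0.0)  # iS stress set: hsgnt 27, hsgnr 0.05
    base = constant_slice(**BENIGN)
    ref = simulate_season(cv, base, soil, Management())
    hot = constant_slice(**BENIGN)
    hot.tmax[ref.anthesis_das + 2] = cv.stress.hsgnt + 5.0
    damaged = simulate_season(cv, hot, soil, Management())
    assert damaged.grain_number == pytest.approx(
        ref.grain_number * (1.0 - cv.stress.hsgnr * 5.0), rel=1e-9
    )
    assert damaged.yield_t_ha < ref.yield_t_ha


def test_raising_heat_threshold_never_decreases_yield(temperate_series, soil,
                                                      temperate_mgmt):
    sensitive = CultivarParams()
    tolerant = CultivarParams(
        stress=StressParams(hsgnt=32.0, hsgnr=sensitive.stress.hsgnr,
                            dsgnt=sensitive.stress.dsgnt,
                            dsgns=sensitive.stress.dsgns,
                            dsgnr_max=sensitive.stress.dsgnr_max)
    )
    for year in range(temperate_series.n_seasons()):
        w = temperate_series.season(year)
        y_s = simulate_season(sensitive, w, soil, temperate_mgmt).yield_t_ha
        y_t = simulate_season(tolerant, w, soil, temperate_mgmt).yield_t_ha
        assert y_t >= y_s - 1e-12


def test_raising_senescence_acceleration_never_increases_yield(soil):
    site = site_preset("hot_dry_SW")
    from wheatgap.weather import generate_weather
    series = generate_weather(site, 6, 17)
    mgmt = Management(sowing_doy=site.sowing_doy)
    for year in range(series.n_seasons(sowing_doy=mgmt.sowing_doy)):
        w = series.season(year, sowing_doy=mgmt.sowing_doy)
        y_lo = simulate_season(CultivarParams(w_ss=1.0), w, soil, mgmt).yield_t_ha
        y_hi = simulate_season(CultivarParams(w_ss=4.0), w, soil, mgmt).yield_t_ha
        assert y_hi <= y_lo + 1e-9


def test_ideotype_lue_gain_is_exactly_ten_percent(soil):
    """With no water stress and no sink limitation, the +10% light use
    efficiency must scale biomass and yield by exactly 1.10."""
    plain = CultivarParams(p_p=0.0, max_grain_wt=1e6)
    boosted = CultivarParams(p_p=0.0, max_grain_wt=1e6, lue_multiplier=1.10)
    w = constant_slice(tmin=8, tmax=18, precip=20, rad=18)
    res0 = simulate_season(plain, w, soil, Management())
    res1 = simulate_season(boosted, w, soil, Management())
    assert res1.biomass_t_ha == pytest.approx(1.10 * res0.biomass_t_ha, rel=1e-12)
    assert res1.yield_t_ha == pytest.approx(1.10 * res0.yield_t_ha, rel=1e-12)


def test_season_invariants_across_presets(soil):
    """HI <= 1, yield <= biomass and phenology ordering on every simulated
    season across the climate gradient."""
    from wheatgap.weather import generate_weather, preset_names
    for name in preset_names():
        site = site_preset(name)
        series = generate_weather(site, 4, 23)
        mgmt = Management(sowing_doy=site.sowing_doy)
        for year in range(series.n_seasons(sowing_doy=mgmt.sowing_doy)):
            res = simulate_season(
                CultivarParams(), series.season(year, sowing_doy=mgmt.sowing_doy),
                soil, mgmt,
            )
            assert 0.0 <= res.hi <= 1.0
            assert res.yield_t_ha <= res.biomass_t_ha + 1e-12
            if res.biomass_t_ha > 0 and res.yield_t_ha > 0:
                assert 0 < res.anthesis_das < res.maturity_das


# ---------------------------------------------------------------------------
# multi-year statistics
# ---------------------------------------------------------------------------

def _stub_season(y: float) -> SeasonResult:
    return SeasonResult(yield_t_ha=y, biomass_t_ha=2 * y, hi=0.5,
                        anthesis_das=200, maturity_das=250, grain_fill_days=50,
                        cum_ipar=600.0, grain_number=15000.0, grain_wt=40.0)


def test_yield_stats_hand_computed():
    stats = yield_stats([_stub_season(8.0), _stub_season(10.0), _stub_season(12.0)])
    assert stats.mean_yield == pytest.approx(10.0)
    assert stats.cv == pytest.approx(20.0)  # sample SD = 2
    assert stats.mean_hi == pytest.approx(0.5)


def test_yield_stats_needs_two_seasons():
    with pytest.raises(ValueError):
        yield_stats([_stub_season(8.0)])


def test_constant_weather_gives_zero_cv(temperate_site, soil):
    series = WeatherSeries(
        site=temperate_site, years=3, seed=0,
        tmin=np.full(3 * 365, 8.0), tmax=np.full(3 * 365, 18.0),
        precip=np.full(3 * 365, 5.0), rad=np.full(3 * 365, 15.0),
    )
    stats = simulate_multi_year(CultivarParams(), series, soil, Management())
    assert stats.cv == pytest.approx(0.0, abs=1e-9)


def test_multi_year_deterministic(temperate_series, soil, temperate_mgmt):
    a = simulate_multi_year(CultivarParams(), temperate_series, soil, temperate_mgmt)
    b = simulate_multi_year(CultivarParams(), temperate_series, soil, temperate_mgmt)
    assert a.mean_yield == b.mean_yield
    assert a.cv == b.cv
    assert [r.yield_t_ha for r in a.per_year] == [r.yield_t_ha for r in b.per_year]


def test_multi_year_requires_two_seasons(temperate_site, soil):
    from wheatgap.weather import generate_weather
    short = generate_weather(temperate_site, 1, 0)
    with pytest.raises(ValueError):
        simulate_multi_year(CultivarParams(), short, soil, Management())
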