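"""Daily process-based wheat growth and yield simulation.

The model follows the classic radiation-use-efficiency architecture: daily
biomass gain is intercepted photosynthetically active radiation (PAR,
Beer's-law canopy interception) times a radiation use efficiency, down-scaled
by water stress.  Phenology runs on photoperiod-modified thermal time paced by
the phyllochron; grain number is set around anthesis and can be cut down by
short spells of heat or drought in a flowering window; soil water is a single
bucket with an extractable-fraction root uptake rule; water stress also
accelerates post-anthesis canopy senescence; grain filling runs for a thermal
duration and draws on current assimilate plus a labile pre-anthesis reserve.

Units: biomass and grain are tracked internally in g m-2 and reported in
t ha-1 (1 g m-2 = 0.01 t ha-1); water in mm; radiation in MJ m-2 day-1;
thermal time in degC d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .weather import WeatherSeries, WeatherSlice, day_length

__all__ = [
    "CultivarParams",
    "SoilProfile",
    "Management",
    "SeasonResult",
    "YieldStats",
    "ModelConfig",
    "StressParams",
    "STRESS_SETS",
    "daily_thermal_time",
    "photoperiod_factor",
    "soil_water_step",
    "heat_stress_gn_reduction",
    "drought_stress_gn_reduction",
    "senescence_multiplier",
    "simulate_season",
    "simulate_multi_year",
]

G_PER_M2_TO_T_PER_HA = 0.01


@dataclass(frozen=True)
class StressParams:
    """Flowering-window heat/drought damage parameters.

    hsgnt: heat-stress grain-number threshold temperature (degC).
    hsgnr: grain-number reduction per degC above threshold per day.
    dsgnt: drought-stress-index threshold below which damage accrues.
    dsgns: grain-number reduction per unit stress deficit per day.
    dsgnr_max: cap on the total drought-induced grain-number reduction.
    """

    hsgnt: float
    hsgnr: float
    dsgnt: float
    dsgns: float
    dsgnr_max: float


#: Shipped sensitive (iS) and tolerant (iT) flowering-stress parameter sets.
#: These are calibration defaults expressing "sensitive" vs "tolerant", not
#: measurements; override them from cultivar config files when calibrations
#: are available.
STRESS_SETS: dict[str, StressParams] = {
    "iS": StressParams(hsgnt=27.0, hsgnr=0.05, dsgnt=0.6, dsgns=0.3, dsgnr_max=0.9),
    "iT": StressParams(hsgnt=32.0, hsgnr=0.01, dsgnt=0.4, dsgns=0.1, dsgnr_max=0.3),
}

#: Names of the seven optimizable traits, in canonical order.
TRAIT_NAMES = ("a_max", "s_g", "p_h", "p_p", "g_f", "r_u", "w_ss")


@dataclass(frozen=True)
class CultivarParams:
    """The cultivar description consumed by the simulator.

    Optimizable traits
    ------------------
    a_max : potential flag-leaf contribution to maximum leaf area index (LAI
        units); together with the basal canopy it sets peak LAI.
    s_g : stay-green factor (>= 0); scales the post-anthesis senescence
        thermal duration by (1 + s_g).
    p_h : phyllochron, thermal time per successive leaf (degC d).
    p_p : photoperiod sensitivity in [0, 1]; short days slow pre-anthesis
        development in proportion.
    g_f : grain-filling thermal duration (degC d).
    r_u : maximum fraction of the stored soil water extractable per day.
    w_ss : maximum multiplier (>= 1) on the senescence rate under full water
        stress.

    Flowering-stress parameters are held in ``stress`` (see StressParams);
    the remaining fields are fixed physiology.  ``lue_multiplier`` is 1.0 for
    cultivars and 1.10 for ideotypes (optimal-Rubisco assumption).
    """

    name: str = "reference"
    # optimizable traits
    a_max: float = 3.5
    s_g: float = 1.0
    p_h: float = 100.0
    p_p: float = 0.6
    g_f: float = 600.0
    r_u: float = 0.06
    w_ss: float = 2.0
    # flowering-window stress response
    stress: StressParams = field(default_factory=lambda: STRESS_SETS["iS"])
    # fixed physiology
    rue: float = 2.3              # g biomass per MJ intercepted PAR
    k_ext: float = 0.60           # canopy extinction coefficient
    t_base: float = 0.0           # base temperature, degC
    grains_per_g: float = 16.0    # potential grains per g anthesis biomass
    max_grain_wt: float = 50.0    # potential single-grain mass, mg
    labile_frac: float = 0.22     # anthesis biomass relocatable to grain
    lue_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.lue_multiplier not in (1.0, 1.10):
            raise ValueError("lue_multiplier must be 1.0 (cultivar) or 1.10 (ideotype)")
        if self.w_ss < 1.0:
            raise ValueError("w_ss must be >= 1")
        if not 0.0 < self.r_u <= 1.0:
            raise ValueError("r_u must lie in (0, 1]")
        if not 0.0 <= self.p_p <= 1.0:
            raise ValueError("p_p must lie in [0, 1]")

    @property
    def traits(self) -> np.ndarray:
        """The seven optimizable trait values in canonical order."""
        return np.array([getattr(self, t) for t in TRAIT_NAMES])

    def with_traits(self, genome: Sequence[float]) -> "CultivarParams":
        values = np.asarray(genome, dtype=float)
        if values.shape != (len(TRAIT_NAMES),):
            raise ValueError(f"genome must have {len(TRAIT_NAMES)} values")
        return replace(self, **dict(zip(TRAIT_NAMES, values.tolist())))

    def as_ideotype(self, mode: str) -> "CultivarParams":
        """Apply the iS/iT stress set and the +10% light use efficiency."""
        if mode not in STRESS_SETS:
            raise ValueError(f"stress mode must be one of {sorted(STRESS_SETS)}")
        return replace(self, stress=STRESS_SETS[mode], lue_multiplier=1.10)


@dataclass(frozen=True)
class SoilProfile:
    """Single-bucket soil: total available water capacity (mm) and the
    fraction of it present at sowing.  Default profile: 177 mm."""

    awc: float = 177.0
    initial_fill: float = 0.9

    def __post_init__(self) -> None:
        if self.awc <= 0:
            raise ValueError("awc must be > 0")
        if not 0.0 <= self.initial_fill <= 1.0:
            raise ValueError("initial_fill must lie in [0, 1]")


@dataclass(frozen=True)
class Management:
    """Crop management context: sowing day-of-year, CO2 (held at 364 ppm for
    this single-level analysis), rainfed water regime, non-limiting
    nutrients."""

    sowing_doy: int = 289
    co2_ppm: float = 364.0
    water_regime: str = "rainfed"
    nutrients: str = "non-limiting"

    def __post_init__(self) -> None:
        if self.water_regime not in ("rainfed",):
            raise ValueError("water_regime must be 'rainfed'")
        if self.nutrients not in ("non-limiting",):
            raise ValueError("nutrients must be 'non-limiting'")


@dataclass(frozen=True)
class ModelConfig:
    """Fixed model constants (calibration knobs, documented in the methods
    note)."""

    n_leaf: int = 9                 # final main-stem leaf number
    tt_offset_phyllochrons: float = 2.0  # booting-to-flowering, in phyllochrons
    lai_base: float = 2.0           # canopy LAI below the flag leaf
    sen_base_tt: float = 600.0      # senescence thermal duration at s_g = 0
    flowering_halfwidth: int = 4    # flowering window = anthesis +/- this, days
    par_fraction: float = 0.5       # PAR as a fraction of global radiation
    transp_per_ipar: float = 0.45   # potential transpiration, mm per MJ IPAR
    d_base: float = 8.0             # photoperiod response base day length, h
    d_sat: float = 15.0             # saturating day length, h
    f_min: float = 0.25             # floor of the photoperiod factor


DEFAULT_CONFIG = ModelConfig()


@dataclass(frozen=True)
class SeasonResult:
    """One season's outputs.  Yields in t ha-1, grain number per m2, grain
    mass in mg, cumulative intercepted PAR in MJ m-2, dates in days after
    sowing."""

    yield_t_ha: float
    biomass_t_ha: float
    hi: float
    anthesis_das: int
    maturity_das: int
    grain_fill_days: int
    cum_ipar: float
    grain_number: float
    grain_wt: float


@dataclass(frozen=True)
class YieldStats:
    """Across-year yield statistics used as optimization fitness and
    feasibility.  ``cv`` is in percent and uses the sample standard
    deviation (divisor n-1) so the stability filter is reproducible."""

    mean_yield: float
    cv: float
    mean_hi: float
    per_year: tuple[SeasonResult, ...]


# ---------------------------------------------------------------------------
# elementary process operations
# ---------------------------------------------------------------------------

def daily_thermal_time(tmin: float, tmax: float, t_base: float) -> float:
    """max(0, (tmin + tmax)/2 - t_base), degC d."""
    if tmax < tmin:
        raise ValueError("tmax must be >= tmin")
    return max(0.0, 0.5 * (tmin + tmax) - t_base)


def photoperiod_factor(daylength: float, p_p: float,
                       config: ModelConfig = DEFAULT_CONFIG) -> float:
    """Fractional development rate under short days.

    1 - p_p * (d_sat - daylength)/(d_sat - d_base) for daylength below the
    saturating day length, clamped to [f_min, 1].
    """
    if not 0.0 < daylength < 24.0:
        raise ValueError("daylength must lie in (0, 24) hours")
    if not 0.0 <= p_p <= 1.0:
        raise ValueError("p_p must lie in [0, 1]")
    deficit = max(0.0, config.d_sat - daylength) / (config.d_sat - config.d_base)
    return min(1.0, max(config.f_min, 1.0 - p_p * deficit))


def soil_water_step(stored: float, precip: float, pot_transp: float,
                    r_u: float, awc: float):
    """One day of the single-bucket water balance.

    Rain infiltrates; storage above capacity drains; uptake is limited both by
    demand and by the extractable fraction ``r_u`` of current storage.
    Returns (new_stored, actual_transp, drainage, stress_index) with exact
    mass balance: stored + precip = new_stored + actual_transp + drainage.
    """
    if min(stored, precip, pot_transp, r_u, awc) < 0:
        raise ValueError("soil_water_step inputs must be >= 0")
    if stored > awc:
        raise ValueError("stored must be <= awc")
    after_infiltration = stored + precip
    drainage = max(0.0, after_infiltration - awc)
    after_infiltration -= drainage
    actual = min(pot_transp, r_u * after_infiltration)
    stress = actual / pot_transp if pot_transp > 0 else 1.0
    return after_infiltration - actual, actual, drainage, stress


def heat_stress_gn_reduction(window_tmax: Sequence[float], hsgnt: float,
                             hsgnr: float) -> float:
    """Fractional grain-number loss from heat in the flowering window:
    sum over days of hsgnr * max(0, tmax - hsgnt), capped at 1."""
    if len(window_tmax) == 0:
        raise ValueError("flowering window must be non-empty")
    total = sum(hsgnr * max(0.0, t - hsgnt) for t in window_tmax)
    return min(1.0, total)


def drought_stress_gn_reduction(window_stress: Sequence[float], dsgnt: float,
                                dsgns: float, dsgnr_max: float) -> float:
    """Fractional grain-number loss from drought in the flowering window:
    sum over days of dsgns * max(0, dsgnt - stress_index), capped at
    dsgnr_max."""
    if len(window_stress) == 0:
        raise ValueError("flowering window must be non-empty")
    total = sum(dsgns * max(0.0, dsgnt - s) for s in window_stress)
    return min(dsgnr_max, total)


def senescence_multiplier(stress_index: float, w_ss: float) -> float:
    """Acceleration of canopy senescence under water stress:
    1 + (w_ss - 1) * (1 - stress_index)."""
    if w_ss < 1.0:
        raise ValueError("w_ss must be >= 1")
    if not 0.0 <= stress_index <= 1.0:
        raise ValueError("stress_index must lie in [0, 1]")
    return 1.0 + (w_ss - 1.0) * (1.0 - stress_index)


# ---------------------------------------------------------------------------
# season simulation
# ---------------------------------------------------------------------------

def simulate_season(cv: CultivarParams, weather: WeatherSlice,
                    soil: SoilProfile, mgmt: Management,
                    config: ModelConfig = DEFAULT_CONFIG,
                    daily_log: list | None = None) -> SeasonResult:
    """Simulate one crop season; day 0 of ``weather`` is the sowing day.

    The slice must cover at least 365 days so any admissible phenology fits.
    If ``daily_log`` is a list, a per-day dict of state variables is appended
    to it (diagnostic output).
    """
    n = len(weather)
    if n < 365:
        raise ValueError("weather slice must cover at least 365 days from sowing")
    tmin = np.asarray(weather.tmin, dtype=float)
    tmax = np.asarray(weather.tmax, dtype=float)
    if not (np.all(np.isfinite(tmin)) and np.all(np.isfinite(tmax))
            and np.all(np.isfinite(weather.precip))
            and np.all(np.isfinite(weather.rad))):
        raise ValueError("weather contains non-finite values")
    if np.any(tmax < tmin):
        raise ValueError("weather has days with tmax < tmin")

    # precomputed per-day forcing
    doy = (weather.start_day_index + np.arange(n)) % 365 + 1
    dl = day_length(weather.latitude, doy)
    deficit = np.maximum(0.0, config.d_sat - dl) / (config.d_sat - config.d_base)
    ppf = np.clip(1.0 - cv.p_p * deficit, config.f_min, 1.0)
    tt = np.maximum(0.0, 0.5 * (tmin + tmax) - cv.t_base)
    mod_tt = (tt * ppf).tolist()
    tt = tt.tolist()
    par = (config.par_fraction * np.asarray(weather.rad, dtype=float)).tolist()
    precip = np.asarray(weather.precip, dtype=float).tolist()
    tmax_l = tmax.tolist()

    lai_max = config.lai_base + cv.a_max
    canopy_tt = config.n_leaf * cv.p_h
    anth_tt = (config.n_leaf + config.tt_offset_phyllochrons) * cv.p_h
    sen_duration = config.sen_base_tt * (1.0 + cv.s_g)
    half_w = config.flowering_halfwidth
    rue = cv.rue * cv.lue_multiplier
    k_ext = cv.k_ext
    r_u = cv.r_u
    awc = soil.awc
    per_mj = config.transp_per_ipar

    cum_mod = 0.0
    lai = 0.0
    lai_at_anth = 0.0
    biomass = 0.0
    stored = soil.initial_fill * awc
    cum_ipar = 0.0
    fill_tt = 0.0
    grain = 0.0
    labile_pool = 0.0
    labile_left = 0.0
    anthesis_day = -1
    maturity_day = -1
    gn_base = 0.0
    grain_number = 0.0
    sink_cap = math.inf
    stress_history: list[float] = []

    for i in range(n):
        pre_anthesis = anthesis_day < 0
        if pre_anthesis:
            cum_mod += mod_tt[i]
            lai = lai_max * min(1.0, cum_mod / canopy_tt)

        ipar = par[i] * (1.0 - math.exp(-k_ext * lai))
        pot_t = per_mj * ipar
        stored, transp, drain, stress = soil_water_step(
            stored, precip[i], pot_t, r_u, awc
        )
        stress_history.append(stress)
        gain = rue * ipar * stress
        biomass += gain
        cum_ipar += ipar

        if pre_anthesis and cum_mod >= anth_tt:
            # grain number set from biomass at anthesis; damage applied at
            # the end of the +/- half_w day flowering window
            anthesis_day = i
            lai_at_anth = lai
            gn_base = cv.grains_per_g * biomass
            labile_pool = cv.labile_frac * biomass
            labile_left = labile_pool
        elif not pre_anthesis:
            # stress-accelerated senescence of the post-anthesis canopy
            sen = senescence_multiplier(stress, cv.w_ss)
            lai = max(0.0, lai - lai_at_anth * (tt[i] / sen_duration) * sen)
            # grain filling: current assimilate plus labile reserve
            fill_tt += tt[i]
            deliver = min(labile_left, labile_pool * tt[i] / cv.g_f)
            labile_left -= deliver
            grain = min(grain + gain + deliver, sink_cap)

            if i == anthesis_day + half_w:
                lo = max(0, anthesis_day - half_w)
                heat = heat_stress_gn_reduction(
                    tmax_l[lo:i + 1], cv.stress.hsgnt, cv.stress.hsgnr
                )
                drought = drought_stress_gn_reduction(
                    stress_history[lo:i + 1], cv.stress.dsgnt,
                    cv.stress.dsgns, cv.stress.dsgnr_max
                )
                grain_number = gn_base * (1.0 - heat) * (1.0 - drought)
                sink_cap = grain_number * cv.max_grain_wt * 1e-3  # mg -> g m-2
                grain = min(grain, sink_cap)

        if daily_log is not None:
            daily_log.append(
                dict(day=i, doy=int(doy[i]), lai=lai, biomass=biomass,
                     stored=stored, stress=stress, ipar=ipar, grain=grain,
                     transp=transp, drain=drain)
            )

        if not pre_anthesis and anthesis_day != i and (
                fill_tt >= cv.g_f or lai <= 0.0):
            maturity_day = i
            break

    if maturity_day < 0:
        maturity_day = n - 1
    if anthesis_day < 0:
        # crop failure: anthesis never reached within the slice
        return SeasonResult(
            yield_t_ha=0.0, biomass_t_ha=biomass * G_PER_M2_TO_T_PER_HA,
            hi=0.0, anthesis_das=n - 1, maturity_das=n - 1, grain_fill_days=0,
            cum_ipar=cum_ipar, grain_number=0.0, grain_wt=0.0,
        )
    if math.isinf(sink_cap):
        # season ended inside the flowering window; finalize grain number
        lo = max(0, anthesis_day - half_w)
        heat = heat_stress_gn_reduction(
            tmax_l[lo:maturity_day + 1], cv.stress.hsgnt, cv.stress.hsgnr
        )
        drought = drought_stress_gn_reduction(
            stress_history[lo:maturity_day + 1], cv.stress.dsgnt,
            cv.stress.dsgns, cv.stress.dsgnr_max
        )
        grain_number = gn_base * (1.0 - heat) * (1.0 - drought)
        grain = min(grain, grain_number * cv.max_grain_wt * 1e-3)

    yield_g = min(grain, biomass)
    hi = yield_g / biomass if biomass > 0 else 0.0
    grain_wt = yield_g / grain_number * 1e3 if grain_number > 0 else 0.0
    return SeasonResult(
        yield_t_ha=yield_g * G_PER_M2_TO_T_PER_HA,
        biomass_t_ha=biomass * G_PER_M2_TO_T_PER_HA,
        hi=hi,
        anthesis_das=anthesis_day,
        maturity_das=maturity_day,
        grain_fill_days=maturity_day - anthesis_day,
        cum_ipar=cum_ipar,
        grain_number=grain_number,
        grain_wt=grain_wt,
    )


def yield_stats(results: Sequence[SeasonResult]) -> YieldStats:
    """Across-year mean yield, sample-SD coefficient of variation (%)
    and mean harvest index."""
    if len(results) < 2:
        raise ValueError("need at least 2 seasons for yield statistics")
    yields = np.array([r.yield_t_ha for r in results])
    mean = float(yields.mean())
    sd = float(yields.std(ddof=1))  # sample convention, divisor n-1
    cv_pct = 100.0 * sd / mean if mean > 0 else math.inf
    return YieldStats(
        mean_yield=mean,
        cv=cv_pct,
        mean_hi=float(np.mean([r.hi for r in results])),
        per_year=tuple(results),
    )


def simulate_multi_year(cv: CultivarParams, series: WeatherSeries,
                        soil: SoilProfile, mgmt: Management,
                        config: ModelConfig = DEFAULT_CONFIG) -> YieldStats:
    """Simulate every complete season in a weather series.

    Each season is sown at ``mgmt.sowing_doy`` of successive calendar years
    and simulated independently with the soil refilled to its initial state
    (independent-years design).  A series of N calendar years hosts N - 1
    complete 365-day seasons.
    """
    n_seasons = series.n_seasons(sowing_doy=mgmt.sowing_doy)
    if n_seasons < 2:
        raise ValueError(
            "weather series too short: at least 2 complete seasons required "
            "(CV of yield is undefined otherwise)"
        )
    results = [
        simulate_season(
            cv, series.season(year, sowing_doy=mgmt.sowing_doy), soil, mgmt, config
        )
        for year in range(n_seasons)
    ]
    return yield_stats(results)
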