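"""Seeded synthetic daily weather with the statistical structure a wheat
simulator needs: seasonal temperature and radiation cycles, wet/dry-day
persistence, skewed wet-day rainfall amounts and inter-annual variability.

The generator is a WGEN-style scheme: a monthly two-state Markov chain for
rainfall occurrence, exponential wet-day amounts, an AR(1) residual on daily
mean temperature around a smooth annual harmonic, and radiation around its
monthly means reduced on wet (cloudy) days.  Years are 365 days, no leap days.

Site presets are synthetic archetypes spanning the European climate gradient
(annual mean temperature roughly 7-19 degC, precipitation roughly 340-810 mm
per year, mean daily global radiation roughly 9.6-17.1 MJ m-2 day-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SiteClimateParams",
    "DailyWeather",
    "WeatherSlice",
    "WeatherSeries",
    "ClimateSummary",
    "site_preset",
    "preset_names",
    "generate_weather",
    "summarize_climate",
    "day_length",
]

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_OF_DOY = np.repeat(np.arange(12), MONTH_LENGTHS)  # 0-based month per doy-1
_MONTH_MIDPOINT_DOY = np.cumsum(MONTH_LENGTHS) - MONTH_LENGTHS / 2.0

#: day-to-day lag-1 autocorrelation of the temperature residual
TEMP_AR1 = 0.65
#: multiplier applied to radiation on wet (cloudy) days
WET_RAD_FACTOR = 0.75
#: multiplier applied to the diurnal temperature range on wet days
WET_RANGE_FACTOR = 0.8
#: lognormal-ish multiplicative noise scale for daily radiation
RAD_NOISE_SD = 0.15


@dataclass(frozen=True)
class SiteClimateParams:
    """Monthly climate statistics plus latitude defining a synthetic site.

    All monthly arrays have 12 entries, January first.  Probabilities are the
    two-state Markov chain transition probabilities of rainfall occurrence:
    ``p_wet_given_wet`` is P(wet today | wet yesterday).
    """

    site_id: str
    latitude: float
    monthly_tmin_mean: np.ndarray
    monthly_tmax_mean: np.ndarray
    monthly_t_sd: np.ndarray
    monthly_rad_mean: np.ndarray
    p_wet_given_wet: np.ndarray
    p_wet_given_dry: np.ndarray
    wet_day_precip_mean: np.ndarray
    sowing_doy: int

    def __post_init__(self) -> None:
        for name in (
            "monthly_tmin_mean",
            "monthly_tmax_mean",
            "monthly_t_sd",
            "monthly_rad_mean",
            "p_wet_given_wet",
            "p_wet_given_dry",
            "wet_day_precip_mean",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise ValueError(f"{name} must have 12 monthly values")
            object.__setattr__(self, name, arr)
        if not (-67.0 <= self.latitude <= 67.0):
            raise ValueError("latitude must lie in [-67, 67] degrees")
        if np.any(self.monthly_tmax_mean < self.monthly_tmin_mean):
            raise ValueError("monthly_tmax_mean must be >= monthly_tmin_mean")
        for name in ("p_wet_given_wet", "p_wet_given_dry"):
            p = getattr(self, name)
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(self.wet_day_precip_mean < 0):
            raise ValueError("wet_day_precip_mean must be >= 0")
        if np.any(self.monthly_rad_mean <= 0):
            raise ValueError("monthly_rad_mean must be > 0")
        if not 1 <= int(self.sowing_doy) <= 365:
            raise ValueError("sowing_doy must lie in [1, 365]")

    # ------------------------------------------------------------------
    # implied (configured) annual statistics, independent of any realization
    # ------------------------------------------------------------------
    @property
    def stationary_wet_prob(self) -> np.ndarray:
        """Stationary wet-day probability of the monthly Markov chain."""
        p11 = self.p_wet_given_wet
        p01 = self.p_wet_given_dry
        denom = 1.0 - p11 + p01
        out = np.where(denom > 0, p01 / np.where(denom > 0, denom, 1.0), 1.0)
        return np.clip(out, 0.0, 1.0)

    @property
    def implied_annual_temperature(self) -> float:
        """Day-weighted annual mean of (tmin+tmax)/2, degC."""
        tmean = 0.5 * (self.monthly_tmin_mean + self.monthly_tmax_mean)
        return float(np.sum(tmean * MONTH_LENGTHS) / 365.0)

    @property
    def implied_annual_precip(self) -> float:
        """Expected annual precipitation total, mm."""
        return float(
            np.sum(MONTH_LENGTHS * self.stationary_wet_prob * self.wet_day_precip_mean)
        )

    @property
    def implied_mean_radiation(self) -> float:
        """Day-weighted annual mean daily global radiation, MJ m-2 day-1."""
        return float(np.sum(self.monthly_rad_mean * MONTH_LENGTHS) / 365.0)


@dataclass(frozen=True)
class DailyWeather:
    """One day of weather: temperatures (degC), rain (mm), radiation (MJ m-2)."""

    day_index: int
    tmin: float
    tmax: float
    precip: float
    rad: float


@dataclass(frozen=True)
class WeatherSlice:
    """A contiguous run of daily weather handed to the crop simulator.

    ``start_day_index`` anchors the slice in the 365-day calendar (day-of-year
    = day_index % 365 + 1); ``latitude`` drives day length.
    """

    tmin: np.ndarray
    tmax: np.ndarray
    precip: np.ndarray
    rad: np.ndarray
    start_day_index: int
    latitude: float

    def __len__(self) -> int:
        return len(self.tmin)


@dataclass(frozen=True)
class WeatherSeries:
    """A multi-year synthetic daily series for one site (years x 365 days)."""

    site: SiteClimateParams
    years: int
    seed: int
    tmin: np.ndarray
    tmax: np.ndarray
    precip: np.ndarray
    rad: np.ndarray

    def __len__(self) -> int:
        return len(self.tmin)

    def day(self, i: int) -> DailyWeather:
        return DailyWeather(
            day_index=i,
            tmin=float(self.tmin[i]),
            tmax=float(self.tmax[i]),
            precip=float(self.precip[i]),
            rad=float(self.rad[i]),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self.day(i)

    def slice(self, start: int, length: int) -> WeatherSlice:
        if start < 0 or start + length > len(self):
            raise ValueError(
                f"slice [{start}, {start + length}) outside series of "
                f"{len(self)} days"
            )
        sl = slice(start, start + length)
        return WeatherSlice(
            tmin=self.tmin[sl],
            tmax=self.tmax[sl],
            precip=self.precip[sl],
            rad=self.rad[sl],
            start_day_index=start,
            latitude=self.site.latitude,
        )

    def season(self, year: int, sowing_doy: int | None = None,
               length: int = 365) -> WeatherSlice:
        """Weather from the sowing day of ``year`` (0-based) onward."""
        doy = self.site.sowing_doy if sowing_doy is None else sowing_doy
        start = year * 365 + (doy - 1)
        return self.slice(start, length)

    def n_seasons(self, sowing_doy: int | None = None, length: int = 365) -> int:
        """Number of complete crop seasons the series can host."""
        doy = self.site.sowing_doy if sowing_doy is None else sowing_doy
        n = 0
        while n * 365 + (doy - 1) + length <= len(self):
            n += 1
        return n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": np.arange(len(self)),
                "tmin": self.tmin,
                "tmax": self.tmax,
                "precip": self.precip,
                "rad": self.rad,
            }
        )

    def to_csv(self, path) -> None:
        """Write `day,tmin,tmax,precip,rad` (degC, degC, mm, MJ m-2 day-1)."""
        self.to_frame().to_csv(path, index=False, float_format="%.4f")


def weather_slice_from_csv(path, start_day_index: int = 0,
                           latitude: float = 52.0) -> WeatherSlice:
    """Read a `day,tmin,tmax,precip,rad` CSV into a WeatherSlice."""
    df = pd.read_csv(path)
    required = {"tmin", "tmax", "precip", "rad"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns: {sorted(missing)}")
    return WeatherSlice(
        tmin=df["tmin"].to_numpy(float),
        tmax=df["tmax"].to_numpy(float),
        precip=df["precip"].to_numpy(float),
        rad=df["rad"].to_numpy(float),
        start_day_index=start_day_index,
        latitude=latitude,
    )


# ---------------------------------------------------------------------------
# solar geometry
# ---------------------------------------------------------------------------

def day_length(latitude: float, doy) -> float | np.ndarray:
    """Day length in hours from standard solar-declination geometry.

    Valid for |latitude| <= 67 degrees so day length is defined year round.
    """
    if abs(latitude) > 67.0:
        raise ValueError("day_length requires |latitude| <= 67 degrees")
    doy_arr = np.asarray(doy, dtype=float)
    decl = -23.44 * np.cos(2.0 * math.pi * (doy_arr + 10.0) / 365.0)
    cos_h = -math.tan(math.radians(latitude)) * np.tan(np.radians(decl))
    cos_h = np.clip(cos_h, -1.0, 1.0)
    hours = 24.0 / math.pi * np.arccos(cos_h)
    hours = np.clip(hours, 1e-6, 24.0 - 1e-6)
    if np.isscalar(doy) or doy_arr.ndim == 0:
        return float(hours)
    return hours


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _annual_harmonic(monthly: np.ndarray) -> np.ndarray:
    """Fit a single annual harmonic through 12 monthly values and evaluate it
    for every day of the 365-day year.  The fitted intercept equals the mean
    of the monthly values, so annual means are preserved."""
    t = 2.0 * math.pi * _MONTH_MIDPOINT_DOY / 365.0
    basis = np.column_stack([np.ones(12), np.cos(t), np.sin(t)])
    coef, *_ = np.linalg.lstsq(basis, np.asarray(monthly, dtype=float), rcond=None)
    doy = np.arange(1, 366, dtype=float)
    td = 2.0 * math.pi * (doy - 0.5) / 365.0
    return coef[0] + coef[1] * np.cos(td) + coef[2] * np.sin(td)


def generate_weather(params: SiteClimateParams, years: int, seed: int) -> WeatherSeries:
    """Generate ``years`` x 365 days of synthetic weather for one site.

    Identical (params, years, seed) give bitwise-identical output.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    n = years * 365

    month = np.tile(_MONTH_OF_DOY, years)  # 0-based month per day
    tmean_smooth = np.tile(
        _annual_harmonic(0.5 * (params.monthly_tmin_mean + params.monthly_tmax_mean)),
        years,
    )
    trange_smooth = np.tile(
        np.maximum(
            0.5, _annual_harmonic(params.monthly_tmax_mean - params.monthly_tmin_mean)
        ),
        years,
    )
    rad_smooth = np.tile(
        np.maximum(0.1, _annual_harmonic(params.monthly_rad_mean)), years
    )

    # --- rainfall occurrence: monthly two-state Markov chain --------------
    p11 = params.p_wet_given_wet[month]
    p01 = params.p_wet_given_dry[month]
    u = rng.random(n)
    wet = np.empty(n, dtype=bool)
    prev = False
    for i in range(n):
        p = p11[i] if prev else p01[i]
        prev = u[i] < p
        wet[i] = prev

    # --- wet-day amounts: exponential with the configured monthly mean ---
    amounts = rng.exponential(1.0, size=n) * params.wet_day_precip_mean[month]
    precip = np.where(wet, amounts, 0.0)

    # --- temperature: smooth seasonal mean + AR(1) residual ----------------
    sd = params.monthly_t_sd[month]
    eps = rng.standard_normal(n)
    resid = np.empty(n)
    innov_scale = math.sqrt(1.0 - TEMP_AR1 ** 2)
    r = 0.0
    for i in range(n):
        r = TEMP_AR1 * r + innov_scale * eps[i]
        resid[i] = r * sd[i]
    tmean = tmean_smooth + resid
    trange = trange_smooth * np.where(wet, WET_RANGE_FACTOR, 1.0)
    tmin = tmean - 0.5 * trange
    tmax = tmean + 0.5 * trange

    # --- radiation: seasonal mean, cloud-reduced on wet days, mild noise --
    noise = np.maximum(0.05, 1.0 + RAD_NOISE_SD * rng.standard_normal(n))
    rad = rad_smooth * np.where(wet, WET_RAD_FACTOR, 1.0) * noise

    return WeatherSeries(
        site=params,
        years=years,
        seed=seed,
        tmin=tmin,
        tmax=tmax,
        precip=precip,
        rad=rad,
    )


@dataclass(frozen=True)
class ClimateSummary:
    """Whole-series climate summary used to validate generator fidelity."""

    mean_annual_t: float
    annual_precip: float
    mean_daily_rad: float
    wet_day_fraction: float


def summarize_climate(series: WeatherSeries | WeatherSlice) -> ClimateSummary:
    """Mean annual temperature (degC), mean annual precipitation total (mm),
    mean daily radiation (MJ m-2 day-1) and wet-day fraction of a series."""
    n = len(series)
    if n == 0:
        raise ValueError("cannot summarize an empty series")
    tmean = 0.5 * (np.asarray(series.tmin) + np.asarray(series.tmax))
    precip = np.asarray(series.precip)
    return ClimateSummary(
        mean_annual_t=float(tmean.mean()),
        annual_precip=float(precip.sum() * 365.0 / n),
        mean_daily_rad=float(np.asarray(series.rad).mean()),
        wet_day_fraction=float((precip > 0).mean()),
    )


# ---------------------------------------------------------------------------
# site presets
# ---------------------------------------------------------------------------

def _seasonal(mean: float, amplitude: float, peak_month: int = 7) -> np.ndarray:
    """12 monthly values: mean + amplitude * cos centered on ``peak_month``."""
    m = np.arange(1, 13, dtype=float)
    return mean + amplitude * np.cos(2.0 * math.pi * (m - peak_month) / 12.0)


def _occurrence(pi_monthly: np.ndarray, persistence: float = 0.3):
    """Markov transition probabilities with the given stationary wet
    probability per month and extra wet-after-wet persistence."""
    pi = np.asarray(pi_monthly, dtype=float)
    p11 = pi + (1.0 - pi) * persistence
    p01 = pi * (1.0 - persistence)
    return np.clip(p11, 0, 1), np.clip(p01, 0, 1)


def _amounts_for_annual_total(pi_monthly: np.ndarray, shape: np.ndarray,
                              annual_total: float) -> np.ndarray:
    """Scale a monthly wet-day-amount shape so the implied annual total of
    the occurrence process matches ``annual_total`` mm."""
    shape = np.asarray(shape, dtype=float)
    implied = np.sum(MONTH_LENGTHS * np.asarray(pi_monthly) * shape)
    return shape * (annual_total / implied)


def _build_preset(site_id: str, latitude: float, t_mean: float, t_amp: float,
                  t_range: float, t_sd: float, rad_mean: float, rad_amp: float,
                  pi_wet: np.ndarray, annual_precip: float,
                  precip_shape: np.ndarray, sowing_doy: int) -> SiteClimateParams:
    tmean_m = _seasonal(t_mean, t_amp)
    p11, p01 = _occurrence(pi_wet)
    wet_mean = _amounts_for_annual_total(pi_wet, precip_shape, annual_precip)
    return SiteClimateParams(
        site_id=site_id,
        latitude=latitude,
        monthly_tmin_mean=tmean_m - 0.5 * t_range,
        monthly_tmax_mean=tmean_m + 0.5 * t_range,
        monthly_t_sd=np.full(12, t_sd),
        monthly_rad_mean=_seasonal(rad_mean, rad_amp),
        p_wet_given_wet=p11,
        p_wet_given_dry=p01,
        wet_day_precip_mean=wet_mean,
        sowing_doy=sowing_doy,
    )


_FLAT = np.full(12, 1.0)
# winter-peaked rainfall shape for the Mediterranean archetype
_WINTER_WET = np.clip(_seasonal(1.0, 0.7, peak_month=1), 0.15, None)

_PRESET_BUILDERS = {
    # maritime north-west: coolest annual mean, wettest
    "cool_wet_NW": dict(
        latitude=53.5, t_mean=7.0, t_amp=5.5, t_range=7.0, t_sd=2.0,
        rad_mean=10.2, rad_amp=6.8, pi_wet=np.full(12, 0.52),
        annual_precip=810.0, precip_shape=_FLAT, sowing_doy=289,
    ),
    # temperate central-west
    "temperate_CW": dict(
        latitude=49.0, t_mean=10.4, t_amp=7.0, t_range=8.0, t_sd=2.2,
        rad_mean=11.8, rad_amp=7.5, pi_wet=np.full(12, 0.42),
        annual_precip=650.0, precip_shape=_FLAT, sowing_doy=289,
    ),
    # continental central-east: larger seasonal swing, drier
    "continental_CE": dict(
        latitude=47.0, t_mean=11.0, t_amp=9.5, t_range=9.0, t_sd=2.5,
        rad_mean=13.0, rad_amp=8.0, pi_wet=np.full(12, 0.35),
        annual_precip=560.0, precip_shape=_FLAT, sowing_doy=289,
    ),
    # cold north-east: lowest radiation
    "cold_NE": dict(
        latitude=59.0, t_mean=7.4, t_amp=10.0, t_range=8.0, t_sd=2.5,
        rad_mean=9.6, rad_amp=6.6, pi_wet=np.full(12, 0.45),
        annual_precip=520.0, precip_shape=_FLAT, sowing_doy=260,
    ),
    # Mediterranean south-west: hottest, driest, sunniest, autumn sowing
    "hot_dry_SW": dict(
        latitude=37.5, t_mean=19.3, t_amp=8.0, t_range=13.0, t_sd=4.0,
        rad_mean=17.1, rad_amp=8.0, pi_wet=np.full(12, 0.22),
        annual_precip=340.0, precip_shape=_WINTER_WET, sowing_doy=319,
    ),
}


def preset_names() -> list[str]:
    return sorted(_PRESET_BUILDERS)


def site_preset(name: str) -> SiteClimateParams:
    """Return one of the shipped synthetic site archetypes by name."""
    try:
        kwargs = _PRESET_BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown site preset {name!r}; available presets: "
            + ", ".join(preset_names())
        ) from None
    return _build_preset(site_id=name, **kwargs)
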