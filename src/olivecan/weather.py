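"""Daily weather forcing: reading, validation, synthesis and sub-daily disaggregation.

The simulator runs most processes on a daily step but resolves root water
uptake, photosynthesis, maintenance respiration and chilling over the diurnal
course.  Daily records (Tmax, Tmin, ea, solar radiation, wind, rain) are
therefore disaggregated into ``N`` equal sub-daily steps with a sine/decay
temperature curve anchored at Tmin (sunrise) and Tmax (14:00) and radiation
distributed in proportion to solar elevation, which makes the daily energy
closure exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date as _date
from datetime import timedelta

import numpy as np
import pandas as pd

__all__ = [
    "DailyWeather",
    "SubDailyStep",
    "SolarGeometry",
    "ClimateParams",
    "WeatherError",
    "WeatherFormatError",
    "WeatherValidationError",
    "read_weather_table",
    "write_weather_table",
    "solar_geometry",
    "solar_elevation",
    "disaggregate_day",
    "generate_synthetic_weather",
    "saturation_vapor_pressure",
]

SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1
#: mol photons per MJ of PAR (McCree); used for W m-2 PAR -> umol m-2 s-1
PAR_UMOL_PER_J = 4.57
#: PAR fraction of global shortwave radiation (configurable per call)
DEFAULT_PAR_FRACTION = 0.45

WEATHER_COLUMNS = ["date", "tmax", "tmin", "ea", "srad", "wind", "rain"]


class WeatherError(ValueError):
    """Base class for weather input problems."""


class WeatherFormatError(WeatherError):
    """Malformed weather table (missing column, unparseable field)."""


class WeatherValidationError(WeatherError):
    """A physically inconsistent record (Tmax < Tmin, negative rain, date gap)."""


@dataclass(frozen=True)
class DailyWeather:
    """One day of meteorological forcing.

    Units: temperatures degC, vapor pressure kPa, radiation MJ m-2 d-1,
    wind m s-1, precipitation mm d-1, CO2 umol mol-1.
    """

    date: _date
    tmax: float
    tmin: float
    ea: float
    srad: float
    wind: float
    rain: float
    ca: float | None = None

    def validate(self, latitude: float | None = None) -> None:
        if self.tmax < self.tmin:
            raise WeatherValidationError(
                f"{self.date}: Tmax ({self.tmax}) < Tmin ({self.tmin})"
            )
        for name in ("ea", "srad", "wind", "rain"):
            if getattr(self, name) < 0:
                raise WeatherValidationError(
                    f"{self.date}: negative {name} ({getattr(self, name)})"
                )
        if latitude is not None:
            ra = solar_geometry(latitude, self.date.timetuple().tm_yday).ra
            # Allow a small margin for instrument/rounding noise.
            if self.srad > 1.05 * ra and self.srad > ra + 0.5:
                raise WeatherValidationError(
                    f"{self.date}: srad {self.srad} exceeds extraterrestrial {ra:.1f}"
                )

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmax + self.tmin)


@dataclass(frozen=True)
class SubDailyStep:
    """One of the N equal fractions of a 24-h day."""

    time: float  # fractional time of day (0-1), step midpoint
    dt: float  # step length, fraction of a day
    temp: float  # degC
    vpd: float  # kPa
    radiation: float  # global shortwave, W m-2
    par_beam: float  # umol m-2 s-1 on the horizontal
    par_diffuse: float  # umol m-2 s-1
    elevation: float  # solar elevation, rad (<= 0 at night)
    azimuth: float  # solar azimuth from south, rad


@dataclass(frozen=True)
class SolarGeometry:
    latitude: float  # rad
    declination: float  # rad
    daylength: float  # h
    ra: float  # extraterrestrial radiation, MJ m-2 d-1


def saturation_vapor_pressure(t: float) -> float:
    """Tetens saturated vapor pressure (kPa) at air temperature t (degC)."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def solar_declination(day_of_year: int) -> float:
    return 0.409 * math.sin(2.0 * math.pi * day_of_year / 365.0 - 1.39)


def solar_geometry(latitude_deg: float, day_of_year: int) -> SolarGeometry:
    """Declination, daylength and extraterrestrial radiation for one day.

    ``latitude_deg`` in degrees; polar latitudes (|lat| >= 66.5) are rejected
    because day-long night/day handling is out of scope.
    """
    if abs(latitude_deg) >= 66.5:
        raise ValueError(f"unsupported polar latitude: {latitude_deg}")
    lat = math.radians(latitude_deg)
    dec = solar_declination(day_of_year)
    x = -math.tan(lat) * math.tan(dec)
    x = min(1.0, max(-1.0, x))
    ws = math.acos(x)  # sunset hour angle, rad
    daylength = 24.0 * ws / math.pi
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * day_of_year / 365.0)
    ra = (
        (24.0 * 60.0 / math.pi)
        * SOLAR_CONSTANT
        * dr
        * (
            ws * math.sin(lat) * math.sin(dec)
            + math.cos(lat) * math.cos(dec) * math.sin(ws)
        )
    )
    return SolarGeometry(lat, dec, daylength, max(ra, 0.0))


def solar_elevation(
    latitude_deg: float, day_of_year: int, hour: float
) -> tuple[float, float]:
    """Solar elevation and azimuth (rad) at local solar ``hour`` (0-24)."""
    lat = math.radians(latitude_deg)
    dec = solar_declination(day_of_year)
    w = math.pi * (hour - 12.0) / 12.0
    sin_b = math.sin(lat) * math.sin(dec) + math.cos(lat) * math.cos(dec) * math.cos(w)
    beta = math.asin(min(1.0, max(-1.0, sin_b)))
    cos_b = math.cos(beta)
    if cos_b < 1e-9:
        az = 0.0
    else:
        sin_az = math.cos(dec) * math.sin(w) / cos_b
        az = math.asin(min(1.0, max(-1.0, sin_az)))
    return beta, az


def diffuse_fraction(clearness_index: float) -> float:
    """Daily diffuse fraction of global radiation from the clearness index.

    Piecewise daily correlation (Spitters-type); any documented split would
    do, so the value can be overridden through ``disaggregate_day``.
    """
    kt = clearness_index
    if kt <= 0.07:
        return 1.0
    if kt < 0.35:
        return 1.0 - 2.3 * (kt - 0.07) ** 2
    if kt < 0.75:
        return 1.33 - 1.46 * kt
    return 0.23


def _diurnal_temperature(
    hours: np.ndarray, tmin: float, tmax: float, sunrise: float, daylength: float
) -> np.ndarray:
    """Sine day-course (Tmin at sunrise, Tmax at 14:00), exponential night decay."""
    if tmax <= tmin:
        return np.full_like(hours, tmin)
    sunset = sunrise + daylength
    t_peak = 14.0
    # Temperature at sunset from the day curve
    amp = tmax - tmin
    denom = max(t_peak - sunrise, 0.5)

    def day_curve(h):
        return tmin + amp * np.sin(0.5 * math.pi * (h - sunrise) / denom)

    t_sunset = float(day_curve(np.array([sunset]))[0]) if sunset > sunrise else tmin
    night_len = 24.0 - daylength
    k = 4.0 / max(night_len, 1.0)  # decay so that ~Tmin is reached by sunrise

    out = np.empty_like(hours)
    for i, h in enumerate(hours):
        if sunrise <= h <= sunset:
            out[i] = day_curve(np.array([h]))[0]
        else:
            since = h - sunset if h > sunset else h + 24.0 - sunset
            out[i] = tmin + (t_sunset - tmin) * math.exp(-k * since)
    return out


def disaggregate_day(
    day: DailyWeather,
    n: int,
    latitude_deg: float,
    par_fraction: float = DEFAULT_PAR_FRACTION,
    diffuse_frac: float | None = None,
) -> list[SubDailyStep]:
    """Split one daily record into ``n`` equal sub-daily steps.

    Radiation is distributed proportionally to ``max(sin(elevation), 0)`` and
    renormalised, so the sum of step radiation times step length reproduces
    the daily total exactly.  ea and wind are held constant over the day.
    """
    if n < 1:
        raise ValueError(f"number of sub-daily steps must be >= 1, got {n}")
    doy = day.date.timetuple().tm_yday
    geom = solar_geometry(latitude_deg, doy)
    hours = (np.arange(n) + 0.5) * 24.0 / n
    dt_day = 1.0 / n

    elev = np.empty(n)
    azim = np.empty(n)
    for i, h in enumerate(hours):
        elev[i], azim[i] = solar_elevation(latitude_deg, doy, h)

    if n == 1:
        temps = np.array([day.tmean])
    else:
        sunrise = 12.0 - geom.daylength / 2.0
        temps = _diurnal_temperature(hours, day.tmin, day.tmax, sunrise, geom.daylength)

    weights = np.maximum(np.sin(elev), 0.0)
    wsum = weights.sum()
    if wsum <= 0.0:
        weights = np.ones(n)
        wsum = float(n)
    # MJ m-2 per step -> W m-2 over the step length
    rad_mj = day.srad * weights / wsum
    rad_wm2 = rad_mj * 1e6 / (dt_day * 86400.0)

    kt = day.srad / geom.ra if geom.ra > 0 else 0.0
    fd = diffuse_fraction(kt) if diffuse_frac is None else diffuse_frac

    steps = []
    for i in range(n):
        par_wm2 = par_fraction * rad_wm2[i]
        par_umol = par_wm2 * PAR_UMOL_PER_J
        vpd = max(saturation_vapor_pressure(float(temps[i])) - day.ea, 0.0)
        steps.append(
            SubDailyStep(
                time=float(hours[i] / 24.0),
                dt=dt_day,
                temp=float(temps[i]),
                vpd=vpd,
                radiation=float(rad_wm2[i]),
                par_beam=float(par_umol * (1.0 - fd)),
                par_diffuse=float(par_umol * fd),
                elevation=float(elev[i]),
                azimuth=float(azim[i]),
            )
        )
    return steps


# ---------------------------------------------------------------------------
# Table IO


def read_weather_table(path, ca: float | None = None) -> list[DailyWeather]:
    """Read a CSV weather table (columns date,tmax,tmin,ea,srad,wind,rain).

    Dates must be contiguous calendar days.  Violated physical invariants
    raise :class:`WeatherValidationError` naming the offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise WeatherFormatError(f"missing column(s): {', '.join(missing)}")
    try:
        dates = pd.to_datetime(df["date"]).dt.date
    except (ValueError, TypeError) as exc:
        raise WeatherFormatError(f"unparseable date column: {exc}") from None
    records = []
    prev = None
    for i, row in enumerate(df.itertuples(index=False)):
        d = dates.iloc[i]
        if prev is not None and (d - prev) != timedelta(days=1):
            raise WeatherValidationError(f"row {i}: date gap between {prev} and {d}")
        prev = d
        rec = DailyWeather(
            date=d,
            tmax=float(row.tmax),
            tmin=float(row.tmin),
            ea=float(row.ea),
            srad=float(row.srad),
            wind=float(row.wind),
            rain=float(row.rain),
            ca=ca,
        )
        try:
            rec.validate()
        except WeatherValidationError as exc:
            raise WeatherValidationError(f"row {i}: {exc}") from None
        records.append(rec)
    return records


def write_weather_table(records, path) -> None:
    df = pd.DataFrame(
        {
            "date": [r.date.isoformat() for r in records],
            "tmax": [r.tmax for r in records],
            "tmin": [r.tmin for r in records],
            "ea": [r.ea for r in records],
            "srad": [r.srad for r in records],
            "wind": [r.wind for r in records],
            "rain": [r.rain for r in records],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synthetic Mediterranean weather


@dataclass(frozen=True)
class ClimateParams:
    """Parameters of the synthetic weather generator.

    Defaults emulate a semi-arid Mediterranean site (Guadalquivir valley
    type): hot dry summers, mild wet winters, about 600 mm mean annual
    rainfall concentrated outside summer.
    """

    latitude: float = 37.8
    tmean_annual: float = 18.0  # degC
    tmean_amplitude: float = 9.0  # degC, annual sinusoid semi-amplitude
    warmest_doy: int = 197  # mid July
    trange_mean: float = 12.0  # diurnal range, degC
    trange_amplitude: float = 4.0
    temp_sigma: float = 1.6  # day-to-day AR(1) noise s.d.
    temp_rho: float = 0.7
    rain_p_base: float = 0.04  # daily wet probability, dry-season floor
    rain_p_amplitude: float = 0.28  # seasonal modulation (wettest mid winter)
    wettest_doy: int = 10
    rain_shape: float = 0.8  # gamma shape of daily amounts
    rain_mean: float = 9.0  # mm per wet day
    clear_sky_frac: float = 0.72  # fraction of extraterrestrial on clear days
    overcast_frac: float = 0.30  # on rain days
    rad_sigma: float = 0.06
    wind_mean: float = 2.0  # m s-1
    wind_sigma: float = 0.6  # lognormal sigma
    ca: float = 400.0  # umol mol-1


def generate_synthetic_weather(
    seed: int, years: int, params: ClimateParams | None = None, start_year: int = 2001
) -> list[DailyWeather]:
    """Deterministic (seeded) multi-year synthetic daily weather series."""
    if years < 1:
        raise ValueError("years must be >= 1")
    p = params or ClimateParams()
    rng = np.random.default_rng(seed)

    start = _date(start_year, 1, 1)
    end = _date(start_year + years, 1, 1)
    ndays = (end - start).days

    records = []
    noise = 0.0
    for i in range(ndays):
        d = start + timedelta(days=i)
        doy = d.timetuple().tm_yday
        w = 0.5 * (1.0 + math.cos(2.0 * math.pi * (doy - p.wettest_doy) / 365.25))
        p_wet = p.rain_p_base + p.rain_p_amplitude * w
        wet = rng.random() < p_wet
        rain = (
            float(rng.gamma(p.rain_shape, p.rain_mean / p.rain_shape)) if wet else 0.0
        )

        noise = p.temp_rho * noise + rng.normal(
            0.0, p.temp_sigma * math.sqrt(1.0 - p.temp_rho**2)
        )
        seas = math.cos(2.0 * math.pi * (doy - p.warmest_doy) / 365.25)
        tmean = p.tmean_annual + p.tmean_amplitude * seas + noise
        trange = max(p.trange_mean + p.trange_amplitude * seas, 2.0)
        if wet:
            trange *= 0.6
        tmax = tmean + trange / 2.0
        tmin = tmean - trange / 2.0

        ra = solar_geometry(p.latitude, doy).ra
        frac = p.overcast_frac if wet else p.clear_sky_frac
        frac = min(max(frac + rng.normal(0.0, p.rad_sigma), 0.10), 0.78)
        srad = frac * ra

        ea = max(0.95 * saturation_vapor_pressure(tmin), 0.05)
        wind = float(
            min(
                math.exp(rng.normal(math.log(p.wind_mean), p.wind_sigma)),
                15.0,
            )
        )
        records.append(
            DailyWeather(
                date=d,
                tmax=tmax,
                tmin=tmin,
                ea=ea,
                srad=srad,
                wind=wind,
                rain=rain,
                ca=p.ca,
            )
        )
    return records
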