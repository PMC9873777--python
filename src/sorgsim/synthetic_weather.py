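"""Stochastic daily weather generation for semi-arid East African climates.

A WGEN-family generator: rainfall occurrence follows a first-order two-state
Markov chain whose monthly transition probabilities are calibrated so the
expected number of wet days matches the monthly normals; wet-day amounts are
Gamma-distributed with a fixed shape; temperatures are monthly means,
smoothly interpolated through the year, plus an AR(1) daily anomaly, with
wet days cooler; radiation follows the extraterrestrial (clear-sky)
seasonal envelope for the site latitude scaled to the monthly normal, and
is reduced on wet days.

Bundled presets capture the two characteristic rainfall regimes of the
Ethiopian dry lowlands — a unimodal single Jun-Sep wet season (Tigray-like)
and a bimodal Mar-Apr plus Jul-Sep pattern (eastern Oromia-like) — plus the
two experimental sites. Preset normals are authored structural
approximations for testing, not station records.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, InvalidWeatherError

__all__ = [
    "ClimateNormals",
    "WeatherSeries",
    "generate",
    "preset",
    "PRESET_NAMES",
    "read_weather",
    "write_weather",
]

GAMMA_SHAPE = 0.8
AR1_SIGMA = 1.5  # deg C daily anomaly s.d.
AR1_RHO = 0.6
WET_DAY_TMAX_DEPRESSION = 2.0  # deg C
WET_DAY_RADN_FACTOR = 0.75
RADN_FLOOR = 3.0  # MJ m^-2


@dataclass(frozen=True)
class ClimateNormals:
    """Monthly climate normals (index 0 = January)."""

    site: str
    latitude: float
    rain_total: tuple[float, ...]  # mm per month
    rain_days: tuple[float, ...]  # wet days per month
    tmax_mean: tuple[float, ...]  # deg C
    tmin_mean: tuple[float, ...]  # deg C
    radn_mean: tuple[float, ...]  # MJ m^-2 day^-1

    def __post_init__(self) -> None:
        for name in ("rain_total", "rain_days", "tmax_mean", "tmin_mean", "radn_mean"):
            if len(getattr(self, name)) != 12:
                raise InputError(f"{name} needs 12 monthly values")
        if any(r < 0 for r in self.rain_total):
            raise InputError("rain totals must be non-negative")
        if any(not (0 <= d <= 31) for d in self.rain_days):
            raise InputError("rain days must lie in [0, 31]")
        if any(tx <= tn for tx, tn in zip(self.tmax_mean, self.tmin_mean)):
            raise InputError("tmax_mean must exceed tmin_mean in every month")

    @property
    def annual_rain(self) -> float:
        return sum(self.rain_total)


class WeatherSeries:
    """Contiguous daily weather: date, tmax, tmin, radn, rain.

    Thin wrapper over a pandas DataFrame indexed by calendar date that
    enforces the physical invariants on construction.
    """

    COLUMNS = ["date", "radn", "tmax", "tmin", "rain"]

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        df["date"] = pd.to_datetime(df["date"])
        df = df.sort_values("date").reset_index(drop=True)
        dates = df["date"]
        if len(df) > 1:
            gaps = dates.diff().dt.days.iloc[1:]
            if (gaps != 1).any():
                where = dates.iloc[1:][gaps != 1].dt.date.tolist()
                raise InvalidWeatherError(f"missing days before: {where[:10]}")
        bad = df.index[df["tmax"] < df["tmin"]].tolist()
        if bad:
            raise InvalidWeatherError(f"tmax < tmin at rows {bad[:10]}")
        if (df["rain"] < 0).any() or (df["radn"] < 0).any():
            raise InvalidWeatherError("rain and radiation must be non-negative")
        self.frame = df[self.COLUMNS]

    def __len__(self) -> int:
        return len(self.frame)

    def year(self, y: int) -> "WeatherSeries":
        sub = self.frame[self.frame["date"].dt.year == y]
        if sub.empty:
            raise InputError(f"no weather for year {y}")
        return WeatherSeries(sub)

    def years(self) -> list[int]:
        return sorted(self.frame["date"].dt.year.unique().tolist())

    def monthly_rain(self) -> pd.Series:
        g = self.frame.groupby([self.frame["date"].dt.year, self.frame["date"].dt.month])
        return g["rain"].sum()


def _markov_probs(rain_days: float, ndays: int) -> tuple[float, float]:
    """Monthly (p01, p11) so the stationary wet fraction matches rain_days.

    Shape rule p11 = min(0.8, 2 * p01) gives realistic wet-spell clustering.
    """
    pi = min(0.95, rain_days / ndays)
    if pi <= 0:
        return 0.0, 0.0
    # With p11 = 2*p01 the stationary equation gives p01 = pi / (1 + pi).
    p01 = pi / (1.0 + pi)
    p11 = 2.0 * p01
    if p11 > 0.8:
        p11 = 0.8
        p01 = (1.0 - p11) * pi / (1.0 - pi) if pi < 1 else 0.8
    return p01, p11


def _extraterrestrial_radn(lat_deg: float, doy: int) -> float:
    """Daily extraterrestrial radiation (MJ m^-2), FAO-56 formulation."""
    lat = math.radians(lat_deg)
    dr = 1.0 + 0.033 * math.cos(2 * math.pi * doy / 365.0)
    decl = 0.409 * math.sin(2 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(lat) * math.tan(decl)
    ws = math.acos(min(1.0, max(-1.0, x)))
    return (
        24 * 60 / math.pi
        * 0.0820
        * dr
        * (ws * math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * math.sin(ws))
    )


def _monthly_interp(values: tuple[float, ...], doy: int, year: int) -> float:
    """Smooth within-year interpolation between month-midpoint values."""
    ndays = 366 if calendar.isleap(year) else 365
    mids = []
    acc = 0
    for m in range(12):
        dim = calendar.monthrange(year, m + 1)[1]
        mids.append(acc + dim / 2.0)
        acc += dim
    # wrap-around periodic interpolation
    xs = [mids[-1] - ndays] + mids + [mids[0] + ndays]
    ys = [values[-1]] + list(values) + [values[0]]
    return float(np.interp(doy, xs, ys))


def generate(normals: ClimateNormals, n_years: int, seed: int, start_year: int = 2001) -> WeatherSeries:
    """Generate ``n_years`` of daily weather from monthly normals.

    All stochastic streams (occurrence, amounts, temperature anomalies) come
    from one seeded NumPy generator, so equal seeds give identical series.
    """
    if n_years < 1:
        raise InputError("n_years must be at least 1")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    wet_prev = False
    anom = 0.0
    innov_sd = AR1_SIGMA * math.sqrt(1.0 - AR1_RHO**2)
    for year in range(start_year, start_year + n_years):
        doy = 0
        for month in range(12):
            dim = calendar.monthrange(year, month + 1)[1]
            p01, p11 = _markov_probs(normals.rain_days[month], dim)
            wet_frac = min(0.95, normals.rain_days[month] / dim)
            mean_amount = (
                normals.rain_total[month] / normals.rain_days[month]
                if normals.rain_days[month] > 0
                else 0.0
            )
            scale = mean_amount / GAMMA_SHAPE if mean_amount > 0 else 0.0
            for day in range(1, dim + 1):
                doy += 1
                # First day of each month draws from the month's stationary
                # wet probability: keeps expected wet days unbiased when
                # adjacent months differ strongly in wetness.
                if day == 1:
                    p_wet = min(0.95, normals.rain_days[month] / dim)
                else:
                    p_wet = p11 if wet_prev else p01
                wet = scale > 0 and rng.random() < p_wet
                rain = float(rng.gamma(GAMMA_SHAPE, scale)) if wet else 0.0
                anom = AR1_RHO * anom + rng.normal(0.0, innov_sd)
                tmax_base = _monthly_interp(normals.tmax_mean, doy, year)
                tmin_base = _monthly_interp(normals.tmin_mean, doy, year)
                # Wet-day cooling is mean-compensated so long-run monthly
                # means converge to the normals.
                tmax = (
                    tmax_base
                    + anom
                    + WET_DAY_TMAX_DEPRESSION * wet_frac
                    - (WET_DAY_TMAX_DEPRESSION if wet else 0.0)
                )
                tmin = tmin_base + anom
                if tmax < tmin + 0.5:
                    tmax = tmin + 0.5
                ra = _extraterrestrial_radn(normals.latitude, doy)
                ra_mid = _extraterrestrial_radn(normals.latitude, _mid_doy(year, month))
                radn = normals.radn_mean[month] * (ra / ra_mid if ra_mid > 0 else 1.0)
                if wet:
                    radn *= WET_DAY_RADN_FACTOR
                radn = max(RADN_FLOOR, radn)
                rows.append(
                    {
                        "date": pd.Timestamp(year=year, month=month + 1, day=day),
                        "radn": radn,
                        "tmax": tmax,
                        "tmin": tmin,
                        "rain": rain,
                    }
                )
                wet_prev = wet
    return WeatherSeries(pd.DataFrame(rows))


def _mid_doy(year: int, month: int) -> int:
    acc = sum(calendar.monthrange(year, m + 1)[1] for m in range(month))
    return acc + calendar.monthrange(year, month + 1)[1] // 2


# ---------------------------------------------------------------------------
# Presets: authored structural approximations of dry-lowland climates.

_PRESETS: dict[str, ClimateNormals] = {
    "unimodal_shiraro_like": ClimateNormals(
        site="unimodal_shiraro_like",
        latitude=14.1,
        #           J    F    M    A    M    J    J    A    S    O    N   D
        rain_total=(2, 3, 8, 15, 20, 80, 190, 180, 70, 20, 8, 4),
        rain_days=(1, 1, 2, 3, 4, 9, 16, 15, 8, 3, 2, 1),
        tmax_mean=(33, 35, 37, 38, 38, 36, 32, 31, 33, 35, 34, 33),
        tmin_mean=(15, 16, 19, 21, 22, 22, 20, 20, 20, 19, 17, 15),
        radn_mean=(21, 23, 24, 24, 24, 22, 19, 19, 21, 22, 21, 20),
    ),
    "bimodal_babile_like": ClimateNormals(
        site="bimodal_babile_like",
        latitude=9.2,
        rain_total=(8, 15, 70, 110, 60, 35, 110, 130, 90, 40, 20, 12),
        rain_days=(2, 3, 7, 10, 7, 5, 11, 12, 9, 5, 3, 2),
        tmax_mean=(29, 30, 31, 30, 30, 29, 27, 27, 28, 29, 29, 28),
        tmin_mean=(13, 14, 16, 17, 17, 17, 16, 16, 16, 15, 13, 12),
        radn_mean=(21, 22, 22, 21, 21, 20, 19, 19, 20, 21, 21, 20),
    ),
    "melkassa_like": ClimateNormals(
        site="melkassa_like",
        latitude=8.4,
        rain_total=(13, 25, 50, 55, 45, 65, 210, 200, 95, 35, 15, 10),
        rain_days=(2, 4, 6, 7, 6, 7, 16, 15, 10, 4, 2, 2),
        tmax_mean=(27, 28, 30, 30, 31, 31, 28, 28, 29, 29, 28, 27),
        tmin_mean=(12, 13, 15, 16, 16, 17, 16, 16, 15, 13, 12, 11),
        radn_mean=(21, 22, 22, 22, 22, 21, 18, 18, 20, 21, 21, 20),
    ),
    "miesso_like": ClimateNormals(
        site="miesso_like",
        latitude=9.2,
        rain_total=(10, 18, 60, 85, 45, 35, 170, 185, 90, 35, 15, 8),
        rain_days=(2, 3, 6, 8, 6, 5, 13, 14, 9, 4, 2, 1),
        tmax_mean=(29, 31, 32, 32, 33, 33, 30, 30, 31, 31, 30, 29),
        tmin_mean=(13, 14, 16, 17, 18, 18, 17, 17, 16, 15, 13, 12),
        radn_mean=(21, 22, 22, 22, 22, 21, 19, 19, 20, 21, 21, 20),
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> ClimateNormals:
    """Return bundled climate normals by preset name."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise InputError(f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None


# ---------------------------------------------------------------------------
# I/O


def read_weather(path: str | Path) -> WeatherSeries:
    """Read a daily weather CSV with header date,radn,tmax,tmin,rain."""
    df = pd.read_csv(path)
    missing = [c for c in WeatherSeries.COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"weather file missing columns: {missing}")
    return WeatherSeries(df)


def write_weather(series: WeatherSeries, path: str | Path) -> None:
    out = series.frame.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
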