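"""Climate-zone co-variables from weather series.

Three indices characterise a site's climate for the meta-model, following
the Global Yield Gap Atlas zonation triplet: growing degree days, aridity
index, and temperature seasonality. Potential evapotranspiration is an
input, not modelled here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = [
    "WeatherSeries",
    "growing_degree_days",
    "aridity_index",
    "temperature_seasonality",
    "climate_indices",
    "site_climate_from_daily",
]


@dataclass(frozen=True)
class WeatherSeries:
    """One year of site weather.

    daily_mean_temp: °C per day (length 365 or 366);
    monthly_mean_temp: °C per calendar month (exactly 12 values);
    annual_precip / annual_pet: mm totals, pet > 0.
    """

    daily_mean_temp: tuple[float, ...]
    monthly_mean_temp: tuple[float, ...]
    annual_precip: float
    annual_pet: float

    def __post_init__(self):
        if len(self.monthly_mean_temp) != 12:
            raise DomainError("monthly_mean_temp must have exactly 12 values")
        if len(self.daily_mean_temp) not in (365, 366):
            raise DomainError("daily_mean_temp must cover one year (365/366 days)")
        if self.annual_pet <= 0:
            raise DomainError("annual_pet must be > 0")


def growing_degree_days(daily_mean_temp: Sequence[float], base_temp: float = 0.0) -> float:
    """Accumulated daily mean temperature above ``base_temp`` (°C·day).

    The base defaults to 0 °C, the usual convention for small-grain cereals;
    it is a configuration choice, not a measured property.
    """
    t = np.asarray(daily_mean_temp, dtype=float)
    if t.size == 0:
        raise DomainError("daily temperature series is empty")
    return float(np.maximum(t - base_temp, 0.0).sum())


def aridity_index(annual_precip: float, annual_pet: float) -> float:
    """Annual precipitation over annual potential evapotranspiration."""
    if annual_pet <= 0:
        raise DomainError("annual_pet must be > 0")
    return annual_precip / annual_pet


def temperature_seasonality(monthly_mean_temp: Sequence[float]) -> float:
    """Sample standard deviation (divisor n-1) of the 12 monthly means (°C)."""
    t = np.asarray(monthly_mean_temp, dtype=float)
    if t.size != 12:
        raise DomainError("temperature_seasonality needs exactly 12 monthly means")
    return float(np.std(t, ddof=1))


def climate_indices(ws: WeatherSeries, base_temp: float = 0.0) -> dict[str, float]:
    """The GYGA triplet for one weather year."""
    return {
        "gdd": growing_degree_days(ws.daily_mean_temp, base_temp),
        "aridity": aridity_index(ws.annual_precip, ws.annual_pet),
        "temp_seasonality": temperature_seasonality(ws.monthly_mean_temp),
    }


def site_climate_from_daily(df: pd.DataFrame, base_temp: float = 0.0) -> dict[str, float]:
    """Indices from a daily weather table, averaged over the years present.

    Expects columns ``date`` (parseable), ``daily_mean_temp`` (°C),
    ``precip`` (mm/day) and ``pet`` (mm/day). Monthly means are derived
    internally; with several years of data the indices are computed per
    calendar year and then averaged (order-stable).
    """
    d = df.copy()
    d["date"] = pd.to_datetime(d["date"])
    per_year = []
    for _, g in d.groupby(d["date"].dt.year, sort=True):
        monthly = g.groupby(g["date"].dt.month)["daily_mean_temp"].mean()
        if len(monthly) != 12:
            raise DomainError(
                f"year {int(g['date'].dt.year.iloc[0])} does not cover all 12 months"
            )
        pet = float(g["pet"].sum())
        if pet <= 0:
            raise DomainError("annual_pet must be > 0")
        per_year.append(
            {
                "gdd": growing_degree_days(g["daily_mean_temp"].to_numpy(), base_temp),
                "aridity": aridity_index(float(g["precip"].sum()), pet),
                "temp_seasonality": temperature_seasonality(monthly.to_numpy()),
            }
        )
    return {k: float(np.mean([y[k] for y in per_year])) for k in per_year[0]}
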