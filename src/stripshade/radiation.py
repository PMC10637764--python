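"""Partition daily global radiation into direct and diffuse components.

Measured daily global radiation R_g is split as R_a = R_g - R_d, where the
diffuse part R_d comes from an empirical diffuse-fraction polynomial in the
clearness index (R_g / R_0) and the sunshine fraction (S / S_0). R_0 is the
daily extraterrestrial radiation on a horizontal surface. Weather is assumed
uniform within each day, so the partition is a single daily number.

Unit care in R_0: the additive omega_s term inside the bracket must be in
radians while the sin/cos terms take the angle itself; this mixed-unit bracket
is the classic source of bugs in the formula and is handled explicitly below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd

from .solar import DayContext, day_context

__all__ = [
    "SOLAR_CONSTANT",
    "DailyWeather",
    "RadiationPartition",
    "extraterrestrial_radiation",
    "diffuse_fraction",
    "partition_day",
    "read_weather_csv",
]

logger = logging.getLogger(__name__)

#: Solar constant (W m^-2).
SOLAR_CONSTANT = 1367.0


@dataclass(frozen=True)
class DailyWeather:
    """One day of measured weather: global radiation and sunshine duration."""

    date: Date
    global_radiation: float  # R_g, MJ m^-2 day^-1
    sunshine_duration: float  # S, hours

    def __post_init__(self) -> None:
        if self.global_radiation < 0:
            raise ValueError(f"global radiation must be >= 0, got {self.global_radiation}")
        if not 0.0 <= self.sunshine_duration <= 24.0:
            raise ValueError(f"sunshine duration must be in [0, 24] h, got {self.sunshine_duration}")


@dataclass(frozen=True)
class RadiationPartition:
    """Derived daily radiation components (MJ m^-2 day^-1)."""

    extraterrestrial: float  # R_0
    diffuse: float  # R_d
    direct: float  # R_a
    clearness_index: float  # R_g / R_0
    sunshine_fraction: float  # S / S_0


def extraterrestrial_radiation(day_of_year: int, latitude_deg: float) -> float:
    """Daily extraterrestrial horizontal radiation R_0 (MJ m^-2 day^-1).

    ``R_0 = (24*3600/pi) I_sc E_0 [cos(phi) cos(delta) sin(omega_s)
    + omega_s sin(phi) sin(delta)]`` with omega_s in radians in the additive
    term; the J m^-2 result is converted to MJ m^-2.
    """
    ctx = day_context(day_of_year, latitude_deg)
    phi = np.deg2rad(latitude_deg)
    delta = np.deg2rad(ctx.declination)
    ws = np.deg2rad(ctx.sunrise_hour_angle)
    bracket = np.cos(phi) * np.cos(delta) * np.sin(ws) + ws * np.sin(phi) * np.sin(delta)
    r0_joule = 24.0 * 3600.0 / np.pi * SOLAR_CONSTANT * ctx.earth_sun_factor * bracket
    return float(r0_joule * 1e-6)


def diffuse_fraction(clearness_index: float, sunshine_fraction: float) -> float:
    """Diffuse fraction R_d / R_g from clearness index and sunshine fraction.

    Empirical polynomial
    ``1.06 - 0.56 k - 0.11 k^2 - 0.26 s - 1.6 s^2`` clamped to [0, 1]:
    the regression can exceed physical bounds at the edges of its fitting
    domain (e.g. 1.06 at fully overcast, negative on very clear days).
    """
    k = float(clearness_index)
    s = float(sunshine_fraction)
    if k < 0 or s < 0:
        raise ValueError(f"clearness index and sunshine fraction must be >= 0, got {k}, {s}")
    raw = 1.06 - 0.56 * k - 0.11 * k**2 - 0.26 * s - 1.6 * s**2
    return float(min(1.0, max(0.0, raw)))


def partition_day(weather: DailyWeather, ctx: DayContext) -> RadiationPartition:
    """Split one day's R_g into diffuse R_d and direct R_a = R_g - R_d."""
    r0 = extraterrestrial_radiation(ctx.day_of_year, ctx.latitude)
    s = weather.sunshine_duration
    s0 = ctx.max_sunshine_duration
    if s > s0:
        logger.warning(
            "sunshine duration %.2f h exceeds astronomical maximum %.2f h on %s; clipping",
            s, s0, weather.date,
        )
        s = s0
    k = weather.global_radiation / r0
    sf = s / s0 if s0 > 0 else 0.0
    frac = diffuse_fraction(k, sf)
    ra = weather.global_radiation - frac * weather.global_radiation
    # re-derive R_d from the rounded R_a so R_d + R_a reproduces R_g bit-exactly
    rd = weather.global_radiation - ra
    return RadiationPartition(
        extraterrestrial=r0,
        diffuse=rd,
        direct=ra,
        clearness_index=k,
        sunshine_fraction=sf,
    )


def read_weather_csv(path: str | Path) -> list[DailyWeather]:
    """Read a daily weather table: columns ``date,Rg,S`` (ISO dates, MJ m^-2, h).

    Rows with missing or unparseable values are rejected with a logged reason.
    """
    df = pd.read_csv(path)
    missing = {"date", "Rg", "S"} - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV {path} lacks columns: {sorted(missing)}")
    out: list[DailyWeather] = []
    for idx, row in df.iterrows():
        try:
            if pd.isna(row["Rg"]) or pd.isna(row["S"]):
                raise ValueError("missing value")
            out.append(
                DailyWeather(
                    date=pd.Timestamp(row["date"]).date(),
                    global_radiation=float(row["Rg"]),
                    sunshine_duration=float(row["S"]),
                )
            )
        except (ValueError, TypeError) as exc:
            logger.warning("rejecting weather row %s (%s): %s", idx, dict(row), exc)
    return out
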