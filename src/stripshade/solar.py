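"""Solar position for daily shading geometry.

All public interfaces take and return angles in degrees; trigonometry is done
in radians internally. Local solar time (LST) is used directly — no longitude
or equation-of-time correction is applied by default (``lst_offset_hours``
provides the 4 min-per-degree correction for callers that need it).

Accuracy is that of the classic agronomic formulas (Cooper declination,
spherical-triangle azimuth); atmospheric refraction and sub-degree ephemeris
corrections are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DayContext",
    "SolarAngles",
    "declination",
    "hour_angle",
    "elevation",
    "azimuth",
    "sunrise_hour_angle",
    "earth_sun_factor",
    "max_sunshine_duration",
    "day_context",
    "lst_offset_hours",
]

_CLAMP_TOL = 1e-9


class PolarDayNightError(ValueError):
    """The sun never rises or never sets on this date at this latitude."""


def _clamped_arcsin(x: float | np.ndarray) -> float | np.ndarray:
    return np.arcsin(np.clip(x, -1.0 - _CLAMP_TOL, 1.0 + _CLAMP_TOL).clip(-1.0, 1.0))


def _clamped_arccos(x: float | np.ndarray) -> float | np.ndarray:
    return np.arccos(np.clip(x, -1.0 - _CLAMP_TOL, 1.0 + _CLAMP_TOL).clip(-1.0, 1.0))


def declination(day_of_year: int | np.ndarray) -> float | np.ndarray:
    """Solar declination delta (degrees) from the day of year.

    Cooper's approximation: ``delta = 23.45 sin(360 (284 + N) / 365 deg)``.
    """
    n = np.asarray(day_of_year)
    if np.any(n < 1) or np.any(n > 366):
        raise ValueError(f"day_of_year must be in 1..366, got {day_of_year}")
    out = 23.45 * np.sin(np.deg2rad(360.0 * (284.0 + n) / 365.0))
    return float(out) if np.isscalar(day_of_year) else out


def hour_angle(local_solar_time: float | np.ndarray) -> float | np.ndarray:
    """Hour angle omega (degrees): ``15 * (LST - 12)``, zero at solar noon."""
    t = np.asarray(local_solar_time, dtype=float)
    if np.any(t < 0) or np.any(t > 24):
        raise ValueError(f"local solar time must be in [0, 24] h, got {local_solar_time}")
    out = 15.0 * (t - 12.0)
    return float(out) if np.isscalar(local_solar_time) else out


def elevation(
    declination_deg: float,
    latitude_deg: float,
    hour_angle_deg: float | np.ndarray,
) -> float | np.ndarray:
    """Solar elevation alpha (degrees).

    ``sin(alpha) = sin(delta) sin(phi) + cos(delta) cos(phi) cos(omega)``.
    """
    d = np.deg2rad(declination_deg)
    p = np.deg2rad(latitude_deg)
    w = np.deg2rad(np.asarray(hour_angle_deg, dtype=float))
    s = np.sin(d) * np.sin(p) + np.cos(d) * np.cos(p) * np.cos(w)
    out = np.rad2deg(_clamped_arcsin(s))
    return float(out) if np.isscalar(hour_angle_deg) else out


def azimuth(
    declination_deg: float,
    latitude_deg: float,
    hour_angle_deg: float | np.ndarray,
    elevation_deg: float | np.ndarray | None = None,
) -> float | np.ndarray:
    """Solar azimuth beta (degrees clockwise from north, 0..360).

    Piecewise: ``arccos((sin d cos p - cos d sin p cos w) / cos a)`` before
    solar noon, and ``360 - arccos(...)`` after. At exactly ``omega = 0`` the
    morning-branch limit is used (180 deg for a sun due south at noon).
    """
    if elevation_deg is None:
        elevation_deg = elevation(declination_deg, latitude_deg, hour_angle_deg)
    a = np.asarray(elevation_deg, dtype=float)
    if np.any(np.abs(a) >= 90.0 - 1e-12):
        raise ValueError("azimuth is undefined at the zenith (|elevation| = 90 deg)")
    d = np.deg2rad(declination_deg)
    p = np.deg2rad(latitude_deg)
    w = np.asarray(hour_angle_deg, dtype=float)
    num = np.sin(d) * np.cos(p) - np.cos(d) * np.sin(p) * np.cos(np.deg2rad(w))
    base = np.rad2deg(_clamped_arccos(num / np.cos(np.deg2rad(a))))
    out = np.where(w > 0, 360.0 - base, base)
    return float(out) if np.isscalar(hour_angle_deg) else out


def sunrise_hour_angle(latitude_deg: float, declination_deg: float) -> float:
    """Sunrise hour angle omega_s (degrees): ``arccos(-tan(phi) tan(delta))``.

    Raises :class:`PolarDayNightError` when the sun never crosses the horizon.
    """
    arg = -np.tan(np.deg2rad(latitude_deg)) * np.tan(np.deg2rad(declination_deg))
    if abs(arg) > 1.0 + _CLAMP_TOL:
        raise PolarDayNightError(
            f"polar day/night: |tan(phi) tan(delta)| = {abs(arg):.4f} > 1 "
            f"(phi={latitude_deg}, delta={declination_deg})"
        )
    return float(np.rad2deg(_clamped_arccos(arg)))


def earth_sun_factor(day_of_year: int) -> float:
    """Sun-earth distance factor E0 = ``1 + 0.033 cos(2 pi N / 365)``."""
    n = np.asarray(day_of_year)
    if np.any(n < 1) or np.any(n > 366):
        raise ValueError(f"day_of_year must be in 1..366, got {day_of_year}")
    return float(1.0 + 0.033 * np.cos(2.0 * np.pi * n / 365.0))


def max_sunshine_duration(sunrise_hour_angle_deg: float) -> float:
    """Astronomical day length S0 (hours): ``2 omega_s / 15``."""
    w = float(sunrise_hour_angle_deg)
    if not 0.0 <= w <= 180.0:
        raise ValueError(f"sunrise hour angle must be in [0, 180] deg, got {w}")
    return 2.0 * w / 15.0


def lst_offset_hours(longitude_deg: float, reference_meridian_deg: float) -> float:
    """Clock-time offset to local solar time: 4 min per degree of longitude."""
    return (longitude_deg - reference_meridian_deg) * 4.0 / 60.0


@dataclass(frozen=True)
class DayContext:
    """Everything about the sun that is fixed for one date at one site."""

    day_of_year: int
    latitude: float
    declination: float
    sunrise_hour_angle: float
    max_elevation: float
    max_sunshine_duration: float
    earth_sun_factor: float

    @property
    def sunrise_lst(self) -> float:
        return 12.0 - self.sunrise_hour_angle / 15.0

    @property
    def sunset_lst(self) -> float:
        return 12.0 + self.sunrise_hour_angle / 15.0

    def elevation_at(self, lst: float | np.ndarray) -> float | np.ndarray:
        return elevation(self.declination, self.latitude, hour_angle(lst))

    def azimuth_at(self, lst: float | np.ndarray) -> float | np.ndarray:
        return azimuth(self.declination, self.latitude, hour_angle(lst))


@dataclass(frozen=True)
class SolarAngles:
    """Instantaneous solar position (degrees)."""

    elevation: float
    azimuth: float
    hour_angle: float


def day_context(day_of_year: int, latitude_deg: float) -> DayContext:
    """Assemble the per-day solar context for a site."""
    delta = declination(day_of_year)
    ws = sunrise_hour_angle(latitude_deg, delta)
    return DayContext(
        day_of_year=int(day_of_year),
        latitude=float(latitude_deg),
        declination=float(delta),
        sunrise_hour_angle=ws,
        max_elevation=90.0 - abs(latitude_deg - delta),
        max_sunshine_duration=max_sunshine_duration(ws),
        earth_sun_factor=earth_sun_factor(day_of_year),
    )
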