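"""Solar position via the NOAA solar calculator equations.

A dance's up-direction on the vertical comb points toward the solar
azimuth, so translating comb angles to compass bearings needs the sun's
azimuth at the time of the dance. The implementation follows the NOAA
general solar position equations (Julian-century polynomial series for the
geometric mean longitude/anomaly, equation of time, apparent declination
and hour angle), which are accurate to well under 0.5 deg for the years and
latitudes relevant to field work.
"""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np

__all__ = ["solar_position", "solar_azimuth"]

_LOW_SUN_ELEVATION_DEG = -6.0


def _to_utc(when: datetime) -> datetime:
    if when.tzinfo is None:
        return when.replace(tzinfo=timezone.utc)
    return when.astimezone(timezone.utc)


def _julian_day(when: datetime) -> float:
    y, mo = when.year, when.month
    d = (
        when.day
        + when.hour / 24.0
        + when.minute / 1440.0
        + (when.second + when.microsecond / 1e6) / 86400.0
    )
    if mo <= 2:
        y -= 1
        mo += 12
    a = y // 100
    b = 2 - a + a // 4
    return int(365.25 * (y + 4716)) + int(30.6001 * (mo + 1)) + d + b - 1524.5


def solar_position(when: datetime, lat_deg: float, lon_deg: float):
    """Return ``(azimuth_deg, elevation_deg)`` of the sun.

    Azimuth uses the compass convention (0 = true north, clockwise,
    in [0, 360)); elevation is the geometric altitude above the horizon
    (no atmospheric refraction — irrelevant at the 0.5 deg level away from
    the horizon).
    """
    when = _to_utc(when)
    jd = _julian_day(when)
    t = (jd - 2451545.0) / 36525.0

    l0 = np.mod(280.46646 + t * (36000.76983 + 0.0003032 * t), 360.0)
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    e = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mr = np.deg2rad(m)
    c = (
        np.sin(mr) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + np.sin(2 * mr) * (0.019993 - 0.000101 * t)
        + np.sin(3 * mr) * 0.000289
    )
    true_long = l0 + c
    omega = np.deg2rad(125.04 - 1934.136 * t)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)

    eps0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * np.cos(omega)
    epsr = np.deg2rad(eps)

    decl = np.rad2deg(np.arcsin(np.sin(epsr) * np.sin(np.deg2rad(app_long))))

    y = np.tan(epsr / 2.0) ** 2
    l0r = np.deg2rad(l0)
    eot = 4.0 * np.rad2deg(
        y * np.sin(2 * l0r)
        - 2 * e * np.sin(mr)
        + 4 * e * y * np.sin(mr) * np.cos(2 * l0r)
        - 0.5 * y * y * np.sin(4 * l0r)
        - 1.25 * e * e * np.sin(2 * mr)
    )  # equation of time, minutes

    minutes_utc = when.hour * 60.0 + when.minute + when.second / 60.0 + when.microsecond / 6e7
    tst = np.mod(minutes_utc + eot + 4.0 * lon_deg, 1440.0)  # true solar time
    ha = tst / 4.0 - 180.0 if tst / 4.0 >= 0 else tst / 4.0 + 180.0

    phi = np.deg2rad(lat_deg)
    dr = np.deg2rad(decl)
    har = np.deg2rad(ha)
    cos_zen = np.sin(phi) * np.sin(dr) + np.cos(phi) * np.cos(dr) * np.cos(har)
    cos_zen = np.clip(cos_zen, -1.0, 1.0)
    zen = np.arccos(cos_zen)
    elevation = 90.0 - np.rad2deg(zen)

    sin_zen = np.sin(zen)
    if sin_zen < 1e-9:
        azimuth = 180.0  # sun at zenith: azimuth ill-defined
    else:
        cos_az = (np.sin(phi) * cos_zen - np.sin(dr)) / (np.cos(phi) * sin_zen)
        az = np.rad2deg(np.arccos(np.clip(cos_az, -1.0, 1.0)))
        azimuth = np.mod(az + 180.0, 360.0) if ha > 0 else np.mod(540.0 - az, 360.0)
    return float(azimuth), float(elevation)


def solar_azimuth(when: datetime, lat_deg: float, lon_deg: float):
    """Compass azimuth of the sun, plus a low-sun flag.

    Returns ``(azimuth_deg, low_sun)``. ``low_sun`` is set when the sun sits
    below civil-twilight elevation (including polar night), where dances are
    not expected and the azimuth reference is unreliable.
    """
    az, elev = solar_position(when, lat_deg, lon_deg)
    return az, elev < _LOW_SUN_ELEVATION_DEG
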