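"""Low-precision solar geometry for light-level geolocation.

Declination and the equation of time follow the NOAA truncated Fourier
series in the fractional year.  Accuracy is a few hundredths of a degree in
declination and a fraction of a minute in the equation of time -- one to two
orders of magnitude below the intrinsic error of threshold geolocation
(~0.5-2 degrees), which is all that is required here.  The same formulas are
used by the forward simulator and the position estimator, so systematic
terms cancel in round-trips; the test suite checks them against an
independent dense-grid evaluation.

All angles are in degrees, times in UTC.  Timestamps are numpy
``datetime64`` values (or arrays) interpreted as UTC.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

__all__ = [
    "fractional_year",
    "declination",
    "equation_of_time",
    "solar_elevation",
    "solar_noon_utc",
    "day_length_hours",
    "equinox_dates",
    "twilight_times_utc",
]

_DEG = np.pi / 180.0


def _to_datetime64(t) -> np.ndarray:
    return np.asarray(t, dtype="datetime64[s]")


def fractional_year(t) -> np.ndarray:
    """Fractional year angle (radians) of UTC timestamp(s) ``t``."""
    t64 = _to_datetime64(t)
    years = t64.astype("datetime64[Y]")
    doy = (t64.astype("datetime64[D]") - years.astype("datetime64[D]")).astype(float)
    secs = (t64 - t64.astype("datetime64[D]")).astype(float)
    return 2.0 * np.pi / 365.0 * (doy + (secs / 86400.0 - 0.5))


def declination(t) -> np.ndarray:
    """Solar declination (degrees) at UTC timestamp(s) ``t``."""
    g = fractional_year(t)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    return decl / _DEG


def equation_of_time(t) -> np.ndarray:
    """Equation of time (minutes; true solar minus mean solar time)."""
    g = fractional_year(t)
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )


def _minutes_of_day(t64: np.ndarray) -> np.ndarray:
    return (t64 - t64.astype("datetime64[D]")).astype(float) / 60.0


def hour_angle(t, lon) -> np.ndarray:
    """Solar hour angle (degrees, 0 at local solar noon) at longitude ``lon``."""
    t64 = _to_datetime64(t)
    tst = _minutes_of_day(t64) + equation_of_time(t64) + 4.0 * np.asarray(lon, float)
    return tst / 4.0 - 180.0


def solar_elevation(t, lon, lat) -> np.ndarray:
    """Solar elevation angle (degrees, no refraction) at (lon, lat)."""
    t64 = _to_datetime64(t)
    decl = declination(t64) * _DEG
    ha = hour_angle(t64, lon) * _DEG
    phi = np.asarray(lat, float) * _DEG
    sin_el = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
    return np.arcsin(np.clip(sin_el, -1.0, 1.0)) / _DEG


def solar_noon_utc(date: _dt.date, lon: float) -> np.datetime64:
    """UTC time of local solar noon on ``date`` at longitude ``lon``."""
    approx = np.datetime64(date.isoformat()) + np.timedelta64(
        int(round((720.0 - 4.0 * lon) * 60)), "s"
    )
    # one fixed-point refinement of the equation of time
    eot = float(equation_of_time(approx))
    minutes = 720.0 - 4.0 * lon - eot
    return np.datetime64(date.isoformat()) + np.timedelta64(int(round(minutes * 60)), "s")


def day_length_hours(date: _dt.date, lat: float, ea: float, lon: float = 0.0) -> float:
    """Time (hours) the sun spends above elevation ``ea`` on ``date`` at ``lat``.

    Returns 0.0 / 24.0 for polar night / day with respect to ``ea``.
    """
    noon = solar_noon_utc(date, lon)
    decl = float(declination(noon)) * _DEG
    phi = lat * _DEG
    cos_h0 = (np.sin(ea * _DEG) - np.sin(phi) * np.sin(decl)) / (
        np.cos(phi) * np.cos(decl)
    )
    if cos_h0 >= 1.0:
        return 0.0
    if cos_h0 <= -1.0:
        return 24.0
    h0 = np.arccos(cos_h0) / _DEG  # degrees
    return 2.0 * h0 / 15.0


def twilight_times_utc(
    date: _dt.date, lon: float, lat: float, ea: float
) -> tuple[np.datetime64, np.datetime64] | None:
    """(sunrise, sunset) UTC crossing times of elevation ``ea``, or None."""
    d = day_length_hours(date, lat, ea, lon)
    if d <= 0.0 or d >= 24.0:
        return None
    noon = solar_noon_utc(date, lon)
    half = np.timedelta64(int(round(d * 1800)), "s")
    return noon - half, noon + half


def day_interval(
    date: _dt.date, lon: float, lat: float, ea: float = -6.0
) -> tuple[np.datetime64, np.datetime64] | None:
    """(dawn, dusk) of ``date``: sun above elevation ``ea`` at (lon, lat)."""
    return twilight_times_utc(date, lon, lat, ea)


def night_interval(
    date: _dt.date, lon: float, lat: float, ea: float = -6.0
) -> tuple[np.datetime64, np.datetime64] | None:
    """The night *starting* on ``date``: dusk of ``date`` to dawn of the next day.

    This is the attendance convention used throughout: a colony night visit
    on date d spans the dark period that begins at dusk of d.
    """
    tw0 = twilight_times_utc(date, lon, lat, ea)
    tw1 = twilight_times_utc(date + _dt.timedelta(days=1), lon, lat, ea)
    if tw0 is None or tw1 is None:
        return None
    return tw0[1], tw1[0]


def equinox_dates(year: int) -> tuple[_dt.date, _dt.date]:
    """March and September equinox dates (declination zero-crossings)."""
    days = np.arange(
        np.datetime64(f"{year}-01-01"), np.datetime64(f"{year + 1}-01-01")
    ).astype("datetime64[s]") + np.timedelta64(12 * 3600, "s")
    decl = declination(days)
    sign = np.sign(decl)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    dates = [days[i].astype("datetime64[D]").astype(_dt.date) for i in crossings]
    march = [d for d in dates if d.month < 6]
    sept = [d for d in dates if d.month >= 6]
    return march[0], sept[0]
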