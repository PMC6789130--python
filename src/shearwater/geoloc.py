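"""Threshold light-level geolocation.

Twilights are the times the light trace crosses a fixed threshold (default
10 on the 0-64 sensor scale); longitude follows from the twilight midpoint
(local solar noon or midnight), latitude from the day length through the
sun-elevation-angle (EA) equation

    sin(EA) = sin(phi) sin(delta) + cos(phi) cos(delta) cos(H0),

with ``delta`` the solar declination and ``H0`` the half-day-length hour
angle.  The EA corresponding to the threshold is a per-device calibration
constant, recovered by grid search against a period when the bird is known
to stay near the colony.  The filtering cascade flags (never deletes)
fixes in equinox windows, outside plausible latitudes, or implying
unrealistic travel speeds.

Fix filter vocabulary: ``equinox``, ``lat_bounds``, ``speed``, ``manual``,
plus ``no_lat`` for fixes whose latitude is unsolvable (polar day/night or
equinox degeneracy).  A fix is retained iff its filter set is empty.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar
from .geodesy import haversine_km

__all__ = [
    "GeoFix",
    "CalibrationResult",
    "detect_twilights",
    "position_from_twilights",
    "positions_from_twilights",
    "calibrate_ea",
    "calibrate_from_light",
    "filter_track",
    "DEFAULT_EA_GRID",
]

DEFAULT_THRESHOLD = 10.0
DEFAULT_EA_GRID = np.round(np.arange(-5.0, -1.99, 0.25), 2)
LAT_BOUNDS = (30.0, 52.0)
EQUINOX_DECL_EPS_DEG = 0.5

_PAIR_COLUMNS = ["sunrise_utc", "sunset_utc", "kind", "date", "quality"]


@dataclass
class GeoFix:
    """One twilight-pair position estimate with filter provenance."""

    date: _dt.date
    time: np.datetime64
    lon: float
    lat: float | None
    kind: str  # noon | midnight
    filters: set = field(default_factory=set)

    @property
    def retained(self) -> bool:
        return not self.filters


@dataclass
class CalibrationResult:
    ea: float
    score_km: float
    n_on_land: int
    window: tuple
    per_ea: dict


# ---------------------------------------------------------------------------
# twilight detection


def _crossings(t: np.ndarray, y: np.ndarray, threshold: float):
    """Linear-interpolated threshold crossings: list of (time, 'rise'|'fall')."""
    below = y < threshold
    events = []
    tsec = t.astype("datetime64[s]").astype("int64")
    for i in np.nonzero(below[:-1] != below[1:])[0]:
        frac = (threshold - y[i]) / (y[i + 1] - y[i])
        tc = tsec[i] + frac * (tsec[i + 1] - tsec[i])
        events.append((np.datetime64(int(round(tc)), "s"), "rise" if below[i] else "fall"))
    return events


def detect_twilights(
    series: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    min_dark_h: float = 4.0,
    min_light_h: float = 1.0,
) -> pd.DataFrame:
    """Detect sunrise/sunset threshold crossings and pair them.

    Returns a DataFrame with columns ``sunrise_utc, sunset_utc, kind
    (noon|midnight), date, quality (ok|short_dark|interference)``.  Dark
    periods shorter than ``min_dark_h`` (cave visits, shading) and light
    periods shorter than ``min_light_h`` (night-time interference) are
    flagged and excluded from pairing.  ``noon`` pairs span sunrise ->
    sunset of one day; ``midnight`` pairs span sunset -> next sunrise.  The
    fix date is the civil date of the pair midpoint.
    """
    if len(series) == 0:
        raise ValueError("empty light series")
    t = series["timestamp"].to_numpy().astype("datetime64[s]")
    y = series["light"].to_numpy(float)
    if t[-1] - t[0] < np.timedelta64(20, "h"):
        raise ValueError("light series must span at least one full day")
    events = _crossings(t, y, threshold)
    if not events:
        warnings.warn("no threshold crossings in light series", stacklevel=2)
        return pd.DataFrame(columns=_PAIR_COLUMNS)

    flagged_rows = []
    # iteratively remove too-short dark / light intervals (artifacts)
    changed = True
    while changed:
        changed = False
        for i in range(len(events) - 1):
            (t0, k0), (t1, k1) = events[i], events[i + 1]
            dur_h = (t1 - t0) / np.timedelta64(1, "h")
            if k0 == "fall" and k1 == "rise" and dur_h < min_dark_h:
                flagged_rows.append((t1, t0, "midnight", _mid_date(t0, t1), "short_dark"))
                del events[i : i + 2]
                changed = True
                break
            if k0 == "rise" and k1 == "fall" and dur_h < min_light_h:
                flagged_rows.append((t0, t1, "noon", _mid_date(t0, t1), "interference"))
                del events[i : i + 2]
                changed = True
                break

    rows = []
    for (t0, k0), (t1, k1) in zip(events[:-1], events[1:]):
        if k0 == "rise" and k1 == "fall":
            rows.append((t0, t1, "noon", _mid_date(t0, t1), "ok"))
        elif k0 == "fall" and k1 == "rise":
            rows.append((t1, t0, "midnight", _mid_date(t0, t1), "ok"))
    out = pd.DataFrame(rows + flagged_rows, columns=_PAIR_COLUMNS)
    return out.sort_values("date", kind="stable").reset_index(drop=True)


def _mid_date(t0: np.datetime64, t1: np.datetime64) -> _dt.date:
    mid = t0 + (t1 - t0) / 2
    return mid.astype("datetime64[D]").astype(_dt.date)


# ---------------------------------------------------------------------------
# positions


def _wrap_lon(lon: float) -> float:
    return ((lon + 180.0) % 360.0) - 180.0


def _solve_latitude(daylength_h: float, decl_deg: float, ea: float):
    """Latitudes phi (deg) solving the day-length equation; [] if unsolvable."""
    h0 = np.radians(daylength_h / 2.0 * 15.0)
    d = np.radians(decl_deg)
    a, b, c = np.sin(d), np.cos(d) * np.cos(h0), np.sin(np.radians(ea))
    r = np.hypot(a, b)
    if r < 1e-12 or abs(c) > r:
        return []
    psi = np.arctan2(b, a)
    base = np.arcsin(c / r)
    sols = set()
    for cand in (base - psi, np.pi - base - psi):
        for k in (-2 * np.pi, 0.0, 2 * np.pi):
            phi = cand + k
            if -np.pi / 2 <= phi <= np.pi / 2:
                if abs(a * np.sin(phi) + b * np.cos(phi) - c) < 1e-9:
                    sols.add(round(np.degrees(phi), 9))
    return sorted(sols)


def position_from_twilights(pair, ea: float) -> GeoFix:
    """Estimate one position from a twilight pair at sun elevation angle ``ea``.

    ``pair`` is a row of :func:`detect_twilights` output (or anything with
    ``sunrise_utc``, ``sunset_utc`` and ``kind`` attributes/keys).
    Latitude is left missing (with a flag) near the equinox (|declination|
    < 0.5 deg) and when the day-length equation has no solution.
    """
    if abs(ea) > 9.0:
        raise ValueError("|ea| must be <= 9 degrees")
    sr = np.datetime64(pair["sunrise_utc"], "s")
    ss = np.datetime64(pair["sunset_utc"], "s")
    kind = pair["kind"]
    if kind == "noon":
        midpoint = sr + (ss - sr) / 2
        daylength = (ss - sr) / np.timedelta64(1, "h")
    elif kind == "midnight":
        midpoint = ss + (sr - ss) / 2
        daylength = 24.0 - (sr - ss) / np.timedelta64(1, "h")
    else:
        raise ValueError(f"unknown pair kind {kind!r}")

    eot = float(solar.equation_of_time(midpoint))
    minutes = (midpoint - midpoint.astype("datetime64[D]")).astype("int64") / 60.0
    lon = (720.0 - eot - minutes) / 4.0
    if kind == "midnight":
        lon += 180.0
    lon = _wrap_lon(lon)

    date = midpoint.astype("datetime64[D]").astype(_dt.date)
    decl = float(solar.declination(midpoint))
    filters: set = set()
    lat: float | None = None
    if abs(decl) < EQUINOX_DECL_EPS_DEG:
        filters.add("equinox")
    else:
        sols = _solve_latitude(daylength, decl, ea)
        if not sols:
            filters.add("no_lat")
        else:
            # hemisphere hint: a day longer than the equatorial day length
            # (for this EA and declination) puts the bird on the summer side
            cos_h0_eq = np.clip(np.sin(np.radians(ea)) / np.cos(np.radians(decl)), -1, 1)
            d_eq = 2 * np.degrees(np.arccos(cos_h0_eq)) / 15.0
            want_sign = np.sign(decl) if daylength >= d_eq else -np.sign(decl)
            matching = [s for s in sols if np.sign(s) == want_sign or s == 0.0]
            pool = matching if matching else sols
            lat = min(pool, key=abs)
    return GeoFix(date=date, time=midpoint, lon=lon, lat=lat, kind=kind, filters=filters)


def positions_from_twilights(pairs: pd.DataFrame, ea: float) -> pd.DataFrame:
    """Vectorised wrapper: one fix per ``quality == 'ok'`` pair."""
    rows = []
    for _, pair in pairs.iterrows():
        if pair["quality"] != "ok":
            continue
        fx = position_from_twilights(pair, ea)
        rows.append(
            {
                "date": fx.date,
                "time": fx.time,
                "kind": fx.kind,
                "lon": fx.lon,
                "lat": np.nan if fx.lat is None else fx.lat,
                "filters": ";".join(sorted(fx.filters)),
                "retained": fx.retained,
            }
        )
    return pd.DataFrame(
        rows, columns=["date", "time", "kind", "lon", "lat", "filters", "retained"]
    )


# ---------------------------------------------------------------------------
# EA calibration


def _usable(fixes: pd.DataFrame, window) -> pd.DataFrame:
    df = fixes
    if window is not None:
        d0, d1 = window
        df = df[(df["date"] >= d0) & (df["date"] <= d1)]
    df = df[df["lat"].notna()]
    return df[~df["filters"].str.contains("equinox", na=False)]


def calibrate_ea(
    fixes_by_ea: dict[float, pd.DataFrame],
    colony: tuple[float, float],
    window: tuple[_dt.date, _dt.date] | None = None,
    *,
    land_polygon=None,
    min_fixes: int = 10,
) -> CalibrationResult:
    """Choose the sun elevation angle minimising colony displacement.

    ``fixes_by_ea`` maps each candidate EA to the fixes computed with it.
    The score is the median great-circle distance (km) of usable window
    fixes to the colony; ties are broken by fewer on-land fixes (if a
    shapely ``land_polygon`` in lon/lat is supplied), then by EA closest to
    -3.5 degrees.
    """
    if not fixes_by_ea:
        raise ValueError("empty EA grid")
    per_ea = {}
    for ea, fixes in fixes_by_ea.items():
        df = _usable(fixes, window)
        if len(df) < min_fixes:
            raise ValueError(
                f"calibration window holds only {len(df)} usable fixes at EA={ea} "
                f"(need >= {min_fixes})"
            )
        score = float(np.median(haversine_km(df["lon"], df["lat"], colony[0], colony[1])))
        n_land = 0
        if land_polygon is not None:
            from shapely.geometry import Point

            n_land = int(sum(land_polygon.contains(Point(x, y))
                             for x, y in zip(df["lon"], df["lat"])))
        per_ea[float(ea)] = (score, n_land)
    best = min(
        per_ea,
        key=lambda ea: (round(per_ea[ea][0], 6), per_ea[ea][1], abs(ea + 3.5)),
    )
    return CalibrationResult(
        ea=best,
        score_km=per_ea[best][0],
        n_on_land=per_ea[best][1],
        window=window,
        per_ea=per_ea,
    )


def calibrate_from_light(
    series: pd.DataFrame,
    colony: tuple[float, float],
    window: tuple[_dt.date, _dt.date] | None = None,
    *,
    grid=None,
    threshold: float = DEFAULT_THRESHOLD,
    land_polygon=None,
) -> CalibrationResult:
    """Grid-search EA calibration straight from a light series."""
    grid = DEFAULT_EA_GRID if grid is None else np.asarray(grid, float)
    pairs = detect_twilights(series, threshold)
    fixes_by_ea = {float(ea): positions_from_twilights(pairs, float(ea)) for ea in grid}
    return calibrate_ea(fixes_by_ea, colony, window, land_polygon=land_polygon)


# ---------------------------------------------------------------------------
# track filtering


def _equinox_windows(years) -> list[tuple[_dt.date, _dt.date]]:
    wins = []
    for y in sorted(set(years)):
        mar, sep = solar.equinox_dates(int(y))
        # winter side = toward the winter solstice: before the March
        # equinox, after the September equinox
        wins.append((mar - _dt.timedelta(days=10), mar + _dt.timedelta(days=5)))
        wins.append((sep - _dt.timedelta(days=5), sep + _dt.timedelta(days=10)))
    return wins


def filter_track(
    fixes: pd.DataFrame,
    *,
    vmax_kmh: float = 55.0,
    lat_bounds: tuple[float, float] = LAT_BOUNDS,
    equinox_windows=None,
) -> pd.DataFrame:
    """Flag equinox-window, out-of-bounds and over-speed fixes.

    Fixes are flagged, never deleted; ``retained`` is recomputed as
    "filter set empty".  Pre-existing ``manual`` and ``no_lat`` flags are
    preserved; ``equinox``, ``lat_bounds`` and ``speed`` are recomputed
    from scratch, which makes the operation idempotent.  The speed test is
    a single forward pass against the last retained fix.
    """
    if len(fixes) == 0:
        return fixes.copy()
    df = fixes.sort_values("time", kind="stable").reset_index(drop=True).copy()
    old = df.get("filters")
    persistent = [
        set(f.split(";")) - {"", "equinox", "lat_bounds", "speed"}
        if isinstance(f, str) and f else set()
        for f in (old if old is not None else [""] * len(df))
    ]
    if equinox_windows is None:
        equinox_windows = _equinox_windows(pd.DatetimeIndex(df["time"]).year)

    flags = [set(p) for p in persistent]
    for i, row in df.iterrows():
        d = row["date"]
        if any(w0 <= d <= w1 for w0, w1 in equinox_windows):
            flags[i].add("equinox")
        if pd.isna(row["lat"]):
            flags[i].add("no_lat")
        elif not (lat_bounds[0] <= row["lat"] <= lat_bounds[1]):
            flags[i].add("lat_bounds")

    last = None  # (lon, lat, time) of last retained fix
    for i, row in df.iterrows():
        if flags[i]:
            continue
        if last is not None:
            dist = float(haversine_km(last[0], last[1], row["lon"], row["lat"]))
            dh = (np.datetime64(row["time"], "s") - last[2]) / np.timedelta64(1, "h")
            if dh > 0 and dist / dh > vmax_kmh:
                flags[i].add("speed")
                continue
        last = (float(row["lon"]), float(row["lat"]), np.datetime64(row["time"], "s"))

    df["filters"] = [";".join(sorted(f)) for f in flags]
    df["retained"] = [not f for f in flags]
    return df
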