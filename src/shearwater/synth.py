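"""Ground-truthed synthetic biologger and feather-isotope data.

Emulates the data streams of archival geolocators (BAS-style: ambient light
0-64 arbitrary units, and salt-water immersion wet-counts per 10-min block)
deployed on burrow-nesting shearwaters, plus feather stable-isotope tables,
so that the whole downstream pipeline (twilight geolocation, attendance
phenology, kernel density space use, discriminant assignment) can be tested
against known truth without any field data.

The annual cycle generated here follows the Mediterranean *Puffinus*
system: colony attendance from winter through early summer, laying in early
spring (population-specific means), ~50 days of incubation shared between
pair members in multi-day shifts, a pre-laying exodus in females, chick
rearing with nocturnal provisioning visits, and a non-breeding season spent
either in north-east Atlantic or western Mediterranean waters.  Every
schedule records the exact truth (event dates, colony-visit date sets,
daily positions) used by recovery tests.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import solar
from .geodesy import haversine_km

__all__ = [
    "Colony",
    "COLONIES",
    "POPULATION_MIXTURES",
    "REGION_BOXES",
    "RegionIsotopeParams",
    "TABLE1_FEATHER_PARAMS",
    "REGION_FEATHER_PARAMS",
    "BehaviorSchedule",
    "simulate_schedule",
    "simulate_pair",
    "simulate_cohort",
    "simulate_light",
    "simulate_stationary_light",
    "simulate_immersion",
    "simulate_isotopes",
    "simulate_isotope_cohort",
    "table1_params",
]

LIGHT_MAX = 64.0
LIGHT_THRESHOLD = 10.0
RAMP_HALF_WIDTH_DEG = 2.0  # light is 0 at ea-2 deg and saturated at ea+2 deg
ATTENDANCE_EA = -6.0  # sun elevation bounding colony "night" (safely dark)
MAX_DAILY_KM = 600.0


@dataclass(frozen=True)
class Colony:
    name: str
    lon: float
    lat: float


#: Study colonies (approximate positions of the three source populations).
COLONIES: dict[str, Colony] = {
    "Mallorca": Colony("Sa Cella, Mallorca", 2.350, 39.600),
    "Menorca": Colony("La Mola, Menorca", 4.317, 39.867),
    "Yelkouan": Colony("Hyeres archipelago, France", 6.220, 43.010),
}

#: Default probability that a bird of each population winters in each region.
POPULATION_MIXTURES: dict[str, dict[str, float]] = {
    "Mallorca": {"Atlantic": 0.85, "Mediterranean": 0.15},
    "Menorca": {"Atlantic": 0.20, "Mediterranean": 0.80},
    "Yelkouan": {"Mediterranean": 1.0},
}

#: Non-breeding destination boxes (lon_min, lon_max, lat_min, lat_max).
REGION_BOXES: dict[str, tuple[float, float, float, float]] = {
    "Atlantic": (-12.0, -2.0, 38.0, 47.0),
    "Mediterranean": (0.0, 10.0, 36.0, 43.0),
}
# Yelkouan birds may use the far-eastern Mediterranean system (Aegean /
# Black Sea approaches); destinations are eastern centroids, no strait
# routing is modelled.
_YELKOUAN_EAST_BOX = (24.0, 32.0, 40.0, 43.0)
_P_YELKOUAN_EAST = 0.3

# Population phenology defaults: laying day-of-year mean/SD, incubation
# length (d), chick-rearing length mean/SD (d), return day-of-year mean/SD.
_PHENO = {
    "Mallorca": dict(lay=60, lay_sd=5, inc=50, rear=55, rear_sd=7, ret=268, ret_sd=8),
    "Menorca": dict(lay=77, lay_sd=5, inc=50, rear=55, rear_sd=7, ret=278, ret_sd=8),
    "Yelkouan": dict(lay=84, lay_sd=5, inc=50, rear=55, rear_sd=7, ret=283, ret_sd=8),
}


# ---------------------------------------------------------------------------
# isotope parameters


@dataclass(frozen=True)
class RegionIsotopeParams:
    """Bivariate-normal parameters for one (population, feather, year) cell."""

    population: str
    feather: str
    year: int
    mean_d15N: float
    sd_d15N: float
    mean_d13C: float
    sd_d13C: float

    def __post_init__(self):
        if self.sd_d15N <= 0 or self.sd_d13C <= 0:
            raise ValueError("isotope SDs must be positive")


#: Published colony/feather/year cell means and SDs (d15N, sd, d13C, sd).
TABLE1_FEATHER_PARAMS: dict[tuple[str, str, int], tuple[float, float, float, float]] = {
    ("Mallorca", "P1", 2011): (13.7, 1.6, -16.9, 0.7),
    ("Mallorca", "P1", 2012): (13.7, 1.6, -16.1, 0.8),
    ("Menorca", "P1", 2011): (12.1, 1.4, -17.5, 0.7),
    ("Menorca", "P1", 2012): (11.8, 0.8, -17.2, 0.4),
    ("Yelkouan", "P1", 2010): (11.2, 0.7, -17.7, 0.6),
    ("Yelkouan", "P1", 2011): (11.3, 1.0, -18.1, 0.6),
    ("Mallorca", "P6", 2011): (14.5, 1.3, -16.5, 0.7),
    ("Mallorca", "P6", 2012): (14.5, 1.3, -16.1, 0.7),
    ("Menorca", "P6", 2011): (11.8, 1.5, -17.4, 0.6),
    ("Menorca", "P6", 2012): (11.8, 1.8, -16.9, 0.4),
}

#: Region-conditional feather parameters used when a cohort mixes
#: non-breeding regions.  Atlantic cells equal the Mallorca colony cells
#: (a near-pure Atlantic population); the Mediterranean P6 cell is a
#: mixture deconvolution of the Menorca colony cells chosen so that the
#: implied two-group separation reproduces the published training-data
#: Wilks' Lambda (~0.22); the Mediterranean P1 cell equals the French
#: (pure-Mediterranean) colony cell.
REGION_FEATHER_PARAMS: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("Atlantic", "P6"): (14.5, 1.3, -16.1, 0.7),
    ("Mediterranean", "P6"): (11.1, 0.9, -17.4, 0.4),
    ("Atlantic", "P1"): (13.7, 1.6, -16.9, 0.7),
    ("Mediterranean", "P1"): (11.3, 1.0, -18.1, 0.6),
}


def table1_params(population: str, feather: str, year: int) -> RegionIsotopeParams:
    """Published cell parameters for one (population, feather, year)."""
    key = (population, feather, year)
    if key not in TABLE1_FEATHER_PARAMS:
        raise KeyError(f"no published isotope cell for {key}")
    m_n, s_n, m_c, s_c = TABLE1_FEATHER_PARAMS[key]
    return RegionIsotopeParams(population, feather, year, m_n, s_n, m_c, s_c)


# ---------------------------------------------------------------------------
# behaviour schedules


@dataclass
class BehaviorSchedule:
    """One bird-year of ground truth.

    ``daily`` has one row per calendar date with columns
    ``date, lon, lat, day_state, night_state``; ``night_state`` of date d
    refers to the night starting at dusk of d.  ``depart_date`` and
    ``return_date`` are, by construction, the bird's last and first colony
    night before and after the non-breeding season.
    """

    bird_id: str
    population: str
    sex: str
    region: str
    year: int
    colony_lon: float
    colony_lat: float
    laying_date: dt.date
    hatch_date: dt.date
    depart_date: dt.date
    return_date: dt.date
    daily: pd.DataFrame
    night_visit_dates: frozenset
    day_visit_dates: frozenset

    @property
    def truth(self) -> dict:
        """Ground-truth event dates the pipeline is expected to recover."""
        return {
            "last_night_visit": self.depart_date,
            "first_night_visit": self.return_date,
            "first_day_visit": min(self.day_visit_dates),
            "laying_date": self.laying_date,
            "last_day_visit": max(self.day_visit_dates),
        }

    def state_timeline(self, ea: float = ATTENDANCE_EA) -> pd.DataFrame:
        """Tidy (start, end, state) intervals derived from the daily states."""
        rows = []
        for _, r in self.daily.iterrows():
            ivd = solar.day_interval(r["date"], self.colony_lon, self.colony_lat, ea)
            ivn = solar.night_interval(r["date"], self.colony_lon, self.colony_lat, ea)
            if ivd is not None:
                rows.append((ivd[0], ivd[1], r["day_state"]))
            if ivn is not None:
                rows.append((ivn[0], ivn[1], r["night_state"]))
        return pd.DataFrame(rows, columns=["start", "end", "state"])


def _attendance_nights(rng, start: dt.date, end_incl: dt.date) -> list[dt.date]:
    """Colony nights from ``start`` to ``end_incl`` with 1-3 night gaps,
    always including ``end_incl`` (if the range is non-empty)."""
    if end_incl < start:
        return []
    out = []
    d = start + dt.timedelta(days=int(rng.integers(0, 3)))
    while d <= end_incl:
        out.append(d)
        d += dt.timedelta(days=int(rng.integers(1, 4)))
    if not out or out[-1] != end_incl:
        out.append(end_incl)
    return out


def _isolated_days(rng, lo: dt.date, hi: dt.date, n: int) -> list[dt.date]:
    """Up to ``n`` mutually non-adjacent dates in [lo, hi]."""
    if hi < lo:
        return []
    cand = [lo + dt.timedelta(days=i) for i in range((hi - lo).days + 1)]
    order = rng.permutation(len(cand))
    picked: list[dt.date] = []
    for i in order:
        d = cand[i]
        if all(abs((d - p).days) > 1 for p in picked):
            picked.append(d)
            if len(picked) >= n:
                break
    return sorted(picked)


def _incubation_shifts(rng, laying: dt.date, hatch: dt.date) -> list[tuple[dt.date, dt.date, str]]:
    """Alternating 2-4 day incubation shifts, male first, truncated at hatch."""
    shifts = []
    d = laying
    who = "M"
    while d <= hatch:
        length = int(rng.integers(2, 5))
        end = min(d + dt.timedelta(days=length - 1), hatch)
        shifts.append((d, end, who))
        d = end + dt.timedelta(days=1)
        who = "F" if who == "M" else "M"
    return shifts


def _draw_region(rng, population: str, mixture: dict[str, float] | None) -> str:
    mix = dict(POPULATION_MIXTURES[population] if mixture is None else mixture)
    regions = sorted(mix)
    probs = np.array([mix[r] for r in regions], float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("region mixture must sum to 1")
    return regions[int(rng.choice(len(regions), p=probs / probs.sum()))]


def _nonbreeding_track(rng, colony: Colony, region: str, population: str,
                       n_days: int) -> tuple[np.ndarray, int, int]:
    """(n_days, 2) lon/lat plus outbound/inbound transit lengths (days):
    transit out, wander around a centroid, transit back."""
    box = REGION_BOXES[region]
    if population == "Yelkouan" and region == "Mediterranean" and rng.random() < _P_YELKOUAN_EAST:
        box = _YELKOUAN_EAST_BOX
    centroid = np.array([rng.uniform(box[0], box[1]), rng.uniform(box[2], box[3])])
    start = np.array([colony.lon, colony.lat])
    dist = float(haversine_km(start[0], start[1], centroid[0], centroid[1]))
    k_out = max(1, int(np.ceil(dist / 500.0)))
    k_back = k_out
    pos = np.empty((n_days, 2))
    n_wander = max(0, n_days - k_out - k_back)
    # outbound transit
    for i in range(min(k_out, n_days)):
        f = (i + 1) / k_out
        pos[i] = start + f * (centroid - start)
    # wander: AR(1) around the centroid, clipped to the box
    p = centroid.copy()
    for i in range(k_out, k_out + n_wander):
        p = centroid + 0.9 * (p - centroid) + rng.normal(0.0, 0.35, 2)
        p[0] = np.clip(p[0], box[0], box[1])
        p[1] = np.clip(p[1], box[2], box[3])
        pos[i] = p
    # inbound transit
    last = pos[max(k_out + n_wander - 1, 0)] if n_days > k_back else centroid
    for j, i in enumerate(range(k_out + n_wander, n_days)):
        f = (j + 1) / k_back
        pos[i] = last + f * (start - last)
    return pos, min(k_out, n_days), min(k_back, max(n_days - k_out, 0))


def _build_schedule(
    *,
    bird_id: str,
    population: str,
    year: int,
    rng: np.random.Generator,
    sex: str,
    region: str,
    laying: dt.date,
    hatch: dt.date,
    depart: dt.date,
    ret: dt.date,
    shifts: list[tuple[dt.date, dt.date, str]],
    exodus_days: int,
) -> BehaviorSchedule:
    colony = COLONIES[population]
    d0 = dt.date(year, 1, 1)
    d1 = dt.date(year, 12, 31)
    all_dates = [d0 + dt.timedelta(days=i) for i in range((d1 - d0).days + 1)]
    nd = len(all_dates)
    idx = {d: i for i, d in enumerate(all_dates)}

    night_visits: set[dt.date] = set()
    day_visits: set[dt.date] = set()

    # --- pre-laying attendance
    if sex == "F":
        last_pre = laying - dt.timedelta(days=exodus_days + 1)
        night_visits.update(_attendance_nights(rng, d0, last_pre))
        night_visits.add(laying)  # the laying night itself
        pre_hi = laying - dt.timedelta(days=exodus_days + 2)
    else:
        night_visits.update(_attendance_nights(rng, d0, laying - dt.timedelta(days=1)))
        pre_hi = laying - dt.timedelta(days=2)
    # isolated single-day prospecting cave visits (never >=2 consecutive)
    pre_lo = laying - dt.timedelta(days=21)
    day_visits.update(_isolated_days(rng, pre_lo, pre_hi, int(rng.integers(2, 5))))

    # --- incubation shifts for this bird
    for s, e, who in shifts:
        if who != sex:
            continue
        d = s
        while d <= e:
            day_visits.add(d)
            d += dt.timedelta(days=1)
        d = s
        while d < e:  # nights between consecutive cave days
            night_visits.add(d)
            d += dt.timedelta(days=1)

    # --- chick rearing: nocturnal provisioning until departure
    night_visits.update(
        _attendance_nights(rng, hatch + dt.timedelta(days=1), depart)
    )
    # --- post-return attendance
    night_visits.update(_attendance_nights(rng, ret, d1))
    night_visits = {d for d in night_visits if d0 <= d <= d1}
    # the truth contract: depart/return are exactly the last/first colony night
    night_visits = {d for d in night_visits if not (depart < d < ret)}
    night_visits.add(depart)
    night_visits.add(ret)

    # --- daily positions and states
    lon = np.empty(nd)
    lat = np.empty(nd)
    day_state = np.empty(nd, dtype=object)
    night_state = np.empty(nd, dtype=object)

    nb_first = depart + dt.timedelta(days=1)
    nb_last = ret - dt.timedelta(days=1)
    nb_days = (nb_last - nb_first).days + 1
    nb_track, k_out, k_back = _nonbreeding_track(rng, colony, region, population, nb_days)

    for i, d in enumerate(all_dates):
        in_nb = nb_first <= d <= nb_last
        if in_nb:
            j = (d - nb_first).days
            near_edge = j < k_out or j >= nb_days - k_back
        if d in day_visits:
            lon[i], lat[i] = colony.lon, colony.lat
            day_state[i] = "colony_day"
        elif in_nb:
            lon[i], lat[i] = nb_track[j]
            day_state[i] = "transit" if near_edge else "at_sea_forage"
        else:
            lon[i] = colony.lon + rng.normal(0.0, 0.7)
            lat[i] = colony.lat + rng.normal(0.0, 0.5)
            day_state[i] = "at_sea_forage"
        if d in night_visits:
            night_state[i] = "colony_night"
        elif in_nb:
            night_state[i] = (
                "transit" if near_edge
                else ("at_sea_raft" if rng.random() < 0.25 else "at_sea_forage")
            )
        else:
            night_state[i] = "at_sea_raft" if rng.random() < 0.2 else "at_sea_forage"

    daily = pd.DataFrame(
        {"date": all_dates, "lon": lon, "lat": lat,
         "day_state": day_state, "night_state": night_state}
    )
    return BehaviorSchedule(
        bird_id=bird_id,
        population=population,
        sex=sex,
        region=region,
        year=year,
        colony_lon=colony.lon,
        colony_lat=colony.lat,
        laying_date=laying,
        hatch_date=hatch,
        depart_date=depart,
        return_date=ret,
        daily=daily,
        night_visit_dates=frozenset(night_visits),
        day_visit_dates=frozenset(day_visits),
    )


def _draw_dates(rng, population: str, year: int):
    p = _PHENO[population]
    lay_doy = int(round(rng.normal(p["lay"], p["lay_sd"])))
    laying = dt.date(year, 1, 1) + dt.timedelta(days=lay_doy - 1)
    hatch = laying + dt.timedelta(days=p["inc"])
    depart = hatch + dt.timedelta(days=int(round(rng.normal(p["rear"], p["rear_sd"]))))
    ret_doy = int(round(rng.normal(p["ret"], p["ret_sd"])))
    ret = dt.date(year, 1, 1) + dt.timedelta(days=ret_doy - 1)
    if (ret - depart).days < 45:
        ret = depart + dt.timedelta(days=45)
    return laying, hatch, depart, ret


def simulate_schedule(
    population: str,
    year: int,
    seed: int | None = None,
    *,
    sex: str | None = None,
    region: str | None = None,
    mixture: dict[str, float] | None = None,
    exodus_days: int = 12,
    bird_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> BehaviorSchedule:
    """Simulate one bird-year with internally consistent states and truth.

    ``seed`` (or an explicit ``rng``) is required: schedules are stochastic
    and reproducibility is part of the contract.
    """
    if population not in COLONIES:
        raise ValueError(f"unknown population {population!r}; "
                         f"known: {sorted(COLONIES)}")
    if rng is None:
        if seed is None:
            raise ValueError("seed is required for reproducible schedules")
        rng = np.random.default_rng(seed)
    if sex is None:
        sex = "M" if rng.random() < 0.5 else "F"
    if region is None:
        region = _draw_region(rng, population, mixture)
    laying, hatch, depart, ret = _draw_dates(rng, population, year)
    shifts = _incubation_shifts(rng, laying, hatch)
    if bird_id is None:
        bird_id = f"{population[:3].lower()}{year}_{int(rng.integers(0, 10**6)):06d}"
    return _build_schedule(
        bird_id=bird_id, population=population, year=year, rng=rng, sex=sex,
        region=region, laying=laying, hatch=hatch, depart=depart, ret=ret,
        shifts=shifts, exodus_days=exodus_days,
    )


def simulate_pair(
    population: str,
    year: int,
    seed: int,
    *,
    mixture: dict[str, float] | None = None,
    exodus_days: int = 12,
) -> tuple[BehaviorSchedule, BehaviorSchedule]:
    """A breeding pair sharing one laying date and complementary shifts."""
    rng = np.random.default_rng(seed)
    laying, hatch, depart_m, ret_m = _draw_dates(rng, population, year)
    shifts = _incubation_shifts(rng, laying, hatch)
    depart_f = hatch + dt.timedelta(days=int(round(rng.normal(55, 7))))
    ret_f = ret_m + dt.timedelta(days=int(rng.integers(-5, 6)))
    if (ret_f - depart_f).days < 45:
        ret_f = depart_f + dt.timedelta(days=45)
    male = _build_schedule(
        bird_id=f"{population[:3].lower()}{year}_m", population=population,
        year=year, rng=rng, sex="M", region=_draw_region(rng, population, mixture),
        laying=laying, hatch=hatch, depart=depart_m, ret=ret_m, shifts=shifts,
        exodus_days=exodus_days,
    )
    female = _build_schedule(
        bird_id=f"{population[:3].lower()}{year}_f", population=population,
        year=year, rng=rng, sex="F", region=_draw_region(rng, population, mixture),
        laying=laying, hatch=hatch, depart=depart_f, ret=ret_f, shifts=shifts,
        exodus_days=exodus_days,
    )
    return male, female


def simulate_cohort(
    population: str,
    n: int,
    year: int,
    seed: int,
    *,
    mixture: dict[str, float] | None = None,
) -> list[BehaviorSchedule]:
    """``n`` independent bird-years with derived per-bird seeds."""
    seqs = np.random.SeedSequence(seed).spawn(n)
    return [
        simulate_schedule(
            population, year, rng=np.random.default_rng(s), mixture=mixture,
            bird_id=f"{population[:3].lower()}{year}_{i:04d}",
        )
        for i, s in enumerate(seqs)
    ]


# ---------------------------------------------------------------------------
# light


def _light_from_elevation(elev: np.ndarray, ea: float) -> np.ndarray:
    # piecewise-linear ramp anchored so that light == threshold exactly at
    # the true sun elevation angle: 0 at ea-2, 10 at ea, 64 at ea+2
    return np.interp(
        elev,
        [ea - RAMP_HALF_WIDTH_DEG, ea, ea + RAMP_HALF_WIDTH_DEG],
        [0.0, LIGHT_THRESHOLD, LIGHT_MAX],
    )


def _light_for_daily(
    daily: pd.DataFrame,
    cave_dates: frozenset,
    ea: float,
    cadence_min: float,
    jitter_sd_min: float,
    shading_events_per_day: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    dates = list(daily["date"])
    gaps = [
        (a, b) for a, b in zip(dates[:-1], dates[1:]) if (b - a).days != 1
    ]
    if gaps:
        raise ValueError(f"schedule has date gaps: {gaps[:5]}")
    start = np.datetime64(dates[0].isoformat())
    end = np.datetime64(dates[-1].isoformat()) + np.timedelta64(1, "D")
    step = np.timedelta64(int(round(cadence_min * 60)), "s")
    times = np.arange(start.astype("datetime64[s]"), end.astype("datetime64[s]"), step)
    didx = (times.astype("datetime64[D]") - start.astype("datetime64[D]")).astype(int)
    lon = daily["lon"].to_numpy(float)[didx]
    lat = daily["lat"].to_numpy(float)[didx]

    if jitter_sd_min > 0:
        tau = rng.normal(0.0, jitter_sd_min * 60.0, size=(len(dates), 2))
        ha = solar.hour_angle(times, lon)
        morning = ((ha + 180.0) % 360.0) - 180.0 < 0
        shift = np.where(morning, tau[didx, 0], tau[didx, 1])
        t_eff = times + shift.round().astype("timedelta64[s]")
    else:
        t_eff = times
    elev = solar.solar_elevation(t_eff, lon, lat)
    light = _light_from_elevation(elev, ea)

    # shading: brief events during full daylight where the sensor is covered
    if shading_events_per_day > 0:
        n_ev = rng.poisson(shading_events_per_day, size=len(dates))
        per_day = int(round(1440.0 / cadence_min))
        for i, k in enumerate(n_ev):
            for _ in range(k):
                s = i * per_day + int(rng.integers(0, per_day))
                dur = int(round(rng.uniform(20, 40) / cadence_min))
                sl = slice(s, min(s + dur, len(light)))
                if np.all(elev[sl] > ea + RAMP_HALF_WIDTH_DEG):
                    light[sl] = 0.0

    # cave days: the bird is inside the colony cave, the sensor sees no light
    if cave_dates:
        cave_mask = np.isin(didx, [ (d - dates[0]).days for d in cave_dates ])
        light[cave_mask] = 0.0
    return pd.DataFrame({"timestamp": times, "light": light})


def simulate_light(
    schedule: BehaviorSchedule,
    ea_true: float = -3.5,
    *,
    twilight_jitter_sd_min: float = 2.0,
    cadence_min: float = 2.0,
    shading_events_per_day: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward-model the light trace of one schedule.

    Returns a DataFrame ``timestamp`` (UTC), ``light`` (0-64 arbitrary
    units).  Light is a clipped piecewise-linear map of solar elevation at
    the bird's daily position; twilight transition times receive Gaussian
    jitter of SD ``twilight_jitter_sd_min`` (one draw per twilight); days
    spent inside the colony cave are forced dark.
    """
    if not (-9.0 <= ea_true <= 0.0):
        raise ValueError("ea_true must be in [-9, 0] degrees")
    if cadence_min < 1.0:
        raise ValueError("cadence must be at least 1 minute")
    rng = np.random.default_rng(seed)
    return _light_for_daily(
        schedule.daily, schedule.day_visit_dates, ea_true, cadence_min,
        twilight_jitter_sd_min, shading_events_per_day, rng,
    )


def simulate_stationary_light(
    lon: float,
    lat: float,
    start_date: dt.date,
    n_days: int,
    ea_true: float = -3.5,
    *,
    cadence_min: float = 2.0,
    twilight_jitter_sd_min: float = 0.0,
    shading_events_per_day: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Light trace of a logger held at a fixed position (for calibration
    and round-trip tests)."""
    if not (-9.0 <= ea_true <= 0.0):
        raise ValueError("ea_true must be in [-9, 0] degrees")
    dates = [start_date + dt.timedelta(days=i) for i in range(n_days)]
    daily = pd.DataFrame({
        "date": dates, "lon": lon, "lat": lat,
        "day_state": "at_sea_forage", "night_state": "at_sea_forage",
    })
    rng = np.random.default_rng(seed)
    return _light_for_daily(
        daily, frozenset(), ea_true, cadence_min, twilight_jitter_sd_min,
        shading_events_per_day, rng,
    )


# ---------------------------------------------------------------------------
# immersion


def simulate_immersion(
    schedule: BehaviorSchedule,
    *,
    block_min: int = 10,
    samples_per_block: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward-model the salt-water immersion trace of one schedule.

    Wet-count per block: 0 in colony states (the bird is dry in its
    burrow), near-saturated when rafting, intermediate and stochastic while
    foraging, and mostly dry with regular short water rests in transit (so
    that a night in transit never contains a 2-h dry run and cannot mimic a
    colony visit).
    """
    rng = np.random.default_rng(seed)
    daily = schedule.daily
    dates = list(daily["date"])
    gaps = [(a, b) for a, b in zip(dates[:-1], dates[1:]) if (b - a).days != 1]
    if gaps:
        raise ValueError(f"schedule has date gaps: {gaps[:5]}")

    start = np.datetime64(dates[0].isoformat(), "s")
    end = np.datetime64(dates[-1].isoformat(), "s") + np.timedelta64(1, "D")
    step = np.timedelta64(block_min * 60, "s")
    times = np.arange(start, end, step)
    didx = (times.astype("datetime64[D]") - start.astype("datetime64[D]")).astype(int)

    # colony dusk/dawn per date (the same convention the detector uses)
    dawns = np.empty(len(dates), dtype="datetime64[s]")
    dusks = np.empty(len(dates), dtype="datetime64[s]")
    for i, d in enumerate(dates):
        iv = solar.day_interval(d, schedule.colony_lon, schedule.colony_lat, ATTENDANCE_EA)
        if iv is None:  # not reachable at study latitudes; defensive
            dawns[i] = np.datetime64(d.isoformat(), "s") + np.timedelta64(6, "h")
            dusks[i] = np.datetime64(d.isoformat(), "s") + np.timedelta64(18, "h")
        else:
            dawns[i], dusks[i] = iv

    day_state = daily["day_state"].to_numpy(object)
    night_state = daily["night_state"].to_numpy(object)
    is_day = (times >= dawns[didx]) & (times < dusks[didx])
    night_idx = np.where(times < dawns[didx], didx - 1, didx)
    night_idx = np.clip(night_idx, 0, len(dates) - 1)
    state = np.where(is_day, day_state[didx], night_state[night_idx])

    spb = int(samples_per_block)
    wet = np.zeros(len(times), dtype=int)
    m = state == "at_sea_raft"
    wet[m] = np.maximum(
        spb - rng.binomial(spb, 0.06, size=int(m.sum())), int(np.ceil(0.8 * spb))
    )
    m = state == "at_sea_forage"
    p = rng.uniform(0.25, 0.7, size=int(m.sum()))
    wet[m] = np.maximum(rng.binomial(spb, p), 1)
    m = state == "transit"
    # flight with a water rest at least every 4th block (40 min at default)
    tr = np.zeros(int(m.sum()), dtype=int)
    rest = (np.arange(len(tr)) % 4) == 3
    tr[rest] = rng.binomial(spb, 0.5, size=int(rest.sum()))
    tr[rest] = np.maximum(tr[rest], 1)
    wet[m] = tr
    # colony_day / colony_night stay 0
    return pd.DataFrame({"timestamp": times, "wet_count": wet})


# ---------------------------------------------------------------------------
# isotopes


def simulate_isotopes(
    params,
    n_per_group: int,
    seed: int,
    *,
    correlation: float = 0.0,
) -> pd.DataFrame:
    """Independent bivariate-normal draws for each parameter cell.

    ``params`` is a single :class:`RegionIsotopeParams` or an iterable of
    them; returns one row per sample with columns ``population, feather,
    year, d15N, d13C``.
    """
    if isinstance(params, RegionIsotopeParams):
        params = [params]
    params = list(params)
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    if not (-1.0 < correlation < 1.0):
        raise ValueError("correlation must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    frames = []
    for p in params:
        cov = np.array(
            [
                [p.sd_d15N**2, correlation * p.sd_d15N * p.sd_d13C],
                [correlation * p.sd_d15N * p.sd_d13C, p.sd_d13C**2],
            ]
        )
        draws = rng.multivariate_normal(
            [p.mean_d15N, p.mean_d13C], cov, size=n_per_group
        )
        frames.append(
            pd.DataFrame(
                {
                    "population": p.population,
                    "feather": p.feather,
                    "year": p.year,
                    "d15N": draws[:, 0],
                    "d13C": draws[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_isotope_cohort(
    population: str,
    n: int,
    seed: int,
    *,
    feather: str = "P6",
    year: int = 2012,
    mixture: dict[str, float] | None = None,
    tracked_fraction: float = 0.2,
    correlation: float = 0.0,
) -> pd.DataFrame:
    """A colony cohort whose isotopes are conditional on the (latent)
    non-breeding region.

    Each bird draws a region from the population mixture and then its
    feather isotopes from the region-conditional cell
    (:data:`REGION_FEATHER_PARAMS`).  ``true_region`` records the generative
    truth for every bird; ``region`` is only filled for tracked birds, as it
    would be in a field dataset.
    """
    if population not in POPULATION_MIXTURES:
        raise ValueError(f"unknown population {population!r}")
    rng = np.random.default_rng(seed)
    mix = dict(POPULATION_MIXTURES[population] if mixture is None else mixture)
    regions = sorted(mix)
    probs = np.array([mix[r] for r in regions], float)
    probs = probs / probs.sum()
    region_draw = [regions[i] for i in rng.choice(len(regions), size=n, p=probs)]
    rows = []
    for i, reg in enumerate(region_draw):
        m_n, s_n, m_c, s_c = REGION_FEATHER_PARAMS[(reg, feather)]
        cov = np.array(
            [[s_n**2, correlation * s_n * s_c], [correlation * s_n * s_c, s_c**2]]
        )
        d15n, d13c = rng.multivariate_normal([m_n, m_c], cov)
        tracked = bool(rng.random() < tracked_fraction)
        rows.append(
            {
                "bird_id": f"{population[:3].lower()}_{i:04d}",
                "population": population,
                "feather": feather,
                "year": year,
                "d15N": d15n,
                "d13C": d13c,
                "tracked": tracked,
                "region": reg if tracked else "",
                "true_region": reg,
            }
        )
    return pd.DataFrame(rows)
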