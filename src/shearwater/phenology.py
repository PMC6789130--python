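"""Colony-attendance events and annual-cycle dates from activity traces.

Burrow-nesting shearwaters are dry while inside the colony, so a night
visit shows up as a run of continuous night-time dryness (>= 2 h of zero
wet-counts) in the immersion trace, and an incubation day visit as complete
daytime darkness in the light trace (the bird sits in a cave).  From these
events the module infers the non-breeding period (last night visit before
the longest attendance gap to the first night visit after it), the laying
date (sex-specific rules: onset of >= 2-day daytime-visit runs in males;
first colony visit after the pre-laying exodus in females; alternating
incubation shifts when both pair members are available) and the hatching
proxy (last day visit).
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar

__all__ = [
    "VisitEvent",
    "PhenologySummary",
    "colony_night_table",
    "colony_day_table",
    "detect_night_visits",
    "detect_day_visits",
    "nonbreeding_bounds",
    "infer_laying_date",
    "impute_return_date",
    "summarize_bird",
]

MIN_DRY_HOURS = 2.0


@dataclass(frozen=True)
class VisitEvent:
    date: _dt.date
    kind: str  # night_visit | day_visit
    start: np.datetime64
    end: np.datetime64


@dataclass
class PhenologySummary:
    """Per-bird annual-cycle dates; any field may be None when undetectable."""

    bird_id: str
    last_night_visit: _dt.date | None = None
    first_night_visit: _dt.date | None = None
    first_day_visit: _dt.date | None = None
    laying_date: _dt.date | None = None
    last_day_visit: _dt.date | None = None
    imputed: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# colony day/night interval tables


def _date_range(d0: _dt.date, d1: _dt.date) -> list[_dt.date]:
    return [d0 + _dt.timedelta(days=i) for i in range((d1 - d0).days + 1)]


def colony_night_table(
    d0: _dt.date, d1: _dt.date, lon: float, lat: float, ea: float = -6.0
) -> pd.DataFrame:
    """Per-date (dusk, dawn) night intervals at the colony.

    The night of date d runs from dusk of d to dawn of d+1.
    """
    rows = []
    for d in _date_range(d0, d1):
        iv = solar.night_interval(d, lon, lat, ea)
        if iv is not None:
            rows.append((d, iv[0], iv[1]))
    return pd.DataFrame(rows, columns=["date", "dusk", "dawn"])


def colony_day_table(
    d0: _dt.date, d1: _dt.date, lon: float, lat: float, ea: float = -6.0
) -> pd.DataFrame:
    """Per-date (dawn, dusk) daylight intervals at the colony."""
    rows = []
    for d in _date_range(d0, d1):
        iv = solar.day_interval(d, lon, lat, ea)
        if iv is not None:
            rows.append((d, iv[0], iv[1]))
    return pd.DataFrame(rows, columns=["date", "dawn", "dusk"])


# ---------------------------------------------------------------------------
# visit detection


def detect_night_visits(
    immersion: pd.DataFrame,
    nights: pd.DataFrame,
    *,
    min_dry_hours: float = MIN_DRY_HOURS,
) -> list[VisitEvent]:
    """Nights containing >= ``min_dry_hours`` of continuous dryness.

    ``immersion`` has columns ``timestamp`` (block start), ``wet_count``;
    ``nights`` is a :func:`colony_night_table`.  The run-length threshold is
    rescaled to the trace's actual block size (12 blocks of 10 min at the
    default), so detection is invariant to block refinement.
    """
    t = immersion["timestamp"].to_numpy().astype("datetime64[s]")
    w = immersion["wet_count"].to_numpy()
    if len(t) < 2:
        raise ValueError("immersion series too short")
    block_s = np.median(np.diff(t)).astype("timedelta64[s]").astype(int)
    need = int(np.ceil(min_dry_hours * 3600.0 / block_s))
    events = []
    for _, row in nights.iterrows():
        dusk = np.datetime64(row["dusk"], "s")
        dawn = np.datetime64(row["dawn"], "s")
        sel = (t >= dusk) & (t + np.timedelta64(block_s, "s") <= dawn)
        if not sel.any():
            continue
        dry = w[sel] == 0
        # longest run of consecutive dry blocks
        best_len, best_start, run, run_start = 0, -1, 0, 0
        for i, v in enumerate(dry):
            if v:
                if run == 0:
                    run_start = i
                run += 1
                if run > best_len:
                    best_len, best_start = run, run_start
            else:
                run = 0
        if best_len >= need:
            idx = np.nonzero(sel)[0]
            start = t[idx[best_start]]
            end = t[idx[best_start + best_len - 1]] + np.timedelta64(block_s, "s")
            events.append(VisitEvent(row["date"], "night_visit", start, end))
    return events


def detect_day_visits(
    light: pd.DataFrame,
    days: pd.DataFrame,
    threshold: float = 10.0,
) -> list[VisitEvent]:
    """Dates whose every daytime light sample is below ``threshold``."""
    t = light["timestamp"].to_numpy().astype("datetime64[s]")
    y = light["light"].to_numpy(float)
    events = []
    for _, row in days.iterrows():
        dawn = np.datetime64(row["dawn"], "s")
        dusk = np.datetime64(row["dusk"], "s")
        sel = (t >= dawn) & (t < dusk)
        if not sel.any():
            warnings.warn(f"no daytime light samples on {row['date']}", stacklevel=2)
            continue
        if np.all(y[sel] < threshold):
            events.append(VisitEvent(row["date"], "day_visit", dawn, dusk))
    return events


# ---------------------------------------------------------------------------
# annual-cycle inference


def nonbreeding_bounds(
    night_visits: list[VisitEvent],
    *,
    min_migration_days: int = 30,
) -> tuple[_dt.date, _dt.date]:
    """(last night visit before, first night visit after) the longest gap.

    Raises if no attendance gap exceeds ``min_migration_days`` or if the
    maximal gap is ambiguous (two equal longest gaps).
    """
    dates = sorted({e.date for e in night_visits if e.kind == "night_visit"})
    if len(dates) < 2:
        raise ValueError("need night visits on both sides of the migration gap")
    gaps = np.array([(b - a).days for a, b in zip(dates[:-1], dates[1:])])
    gmax = gaps.max()
    if gmax <= min_migration_days:
        raise ValueError("no non-breeding period detected "
                         f"(longest gap {gmax} d <= {min_migration_days} d)")
    if int((gaps == gmax).sum()) > 1:
        raise ValueError("ambiguous non-breeding period: two equal maximal gaps")
    i = int(np.argmax(gaps))
    return dates[i], dates[i + 1]


def _runs(dates: set[_dt.date]) -> list[tuple[_dt.date, _dt.date]]:
    """Maximal runs of consecutive dates, sorted by start."""
    out = []
    for d in sorted(dates):
        if out and (d - out[-1][1]).days == 1:
            out[-1] = (out[-1][0], d)
        else:
            out.append((d, d))
    return out


def infer_laying_date(
    day_visits: list[VisitEvent],
    night_visits: list[VisitEvent],
    sex: str,
    *,
    partner_day_visits: list[VisitEvent] | None = None,
    exodus_min_days: int = 5,
    window: tuple[_dt.date, _dt.date] | None = None,
) -> _dt.date | None:
    """Laying date from attendance patterns.

    Pair rule (when the partner's day visits are available): start of the
    first pair of abutting, non-overlapping day-visit runs, one per
    partner.  Male rule: first day of the first day-visit run of length
    >= 2.  Female rule: first colony visit (night or day) ending the
    longest pre-season at-sea absence longer than ``exodus_min_days`` (the
    pre-laying exodus); gaps are evaluated up to the first day visit (or
    inside ``window`` when given) so the non-breeding gap is not mistaken
    for an exodus.  Returns None when no qualifying pattern exists.
    """
    own_days = {e.date for e in day_visits if e.kind == "day_visit"}

    if partner_day_visits is not None:
        partner_days = {e.date for e in partner_day_visits if e.kind == "day_visit"}
        own_runs = [(s, e, "own") for s, e in _runs(own_days)]
        partner_runs = [(s, e, "partner") for s, e in _runs(partner_days)]
        allr = sorted(own_runs + partner_runs)
        # incubation shifts are multi-day: require both abutting runs >= 2 d
        # so isolated prospecting day visits cannot mimic a shift handover
        for s, e, who in allr:
            if (e - s).days + 1 < 2:
                continue
            nxt = [r for r in allr
                   if r[2] != who and (r[0] - e).days == 1 and (r[1] - r[0]).days + 1 >= 2]
            if nxt:
                return s
        # fall through to the single-bird rules

    if sex == "M":
        for s, e in _runs(own_days):
            if (e - s).days + 1 >= 2:
                return s
        return None
    if sex == "F":
        visits = {e.date for e in night_visits if e.kind == "night_visit"} | own_days
        if window is None and own_days:
            # the pre-season ends at incubation onset: the first multi-day
            # day-visit run (isolated prospecting visits do not qualify)
            run2 = [s for s, e in _runs(own_days) if (e - s).days + 1 >= 2]
            end = run2[0] if run2 else max(own_days)
            window = (min(visits), end)
        if window is not None:
            visits = {d for d in visits if window[0] <= d <= window[1]}
        vs = sorted(visits)
        if len(vs) < 2:
            return None
        gaps = [(b - a).days for a, b in zip(vs[:-1], vs[1:])]
        gmax = max(gaps)
        if gmax <= exodus_min_days:
            return None
        # the exodus immediately precedes laying: take the last maximal gap
        i = len(gaps) - 1 - gaps[::-1].index(gmax)
        return vs[i + 1]
    raise ValueError(f"unknown sex {sex!r}")


def impute_return_date(
    cohort: list[PhenologySummary],
    target: PhenologySummary,
) -> PhenologySummary:
    """Fill ``target.first_night_visit`` with the cohort median.

    Median over day-of-year with the earlier central value for even n (a
    deterministic convention); requires >= 3 observed values.
    """
    observed = sorted(
        s.first_night_visit for s in cohort
        if s.first_night_visit is not None and s.bird_id != target.bird_id
    )
    if len(observed) < 3:
        return target
    target.first_night_visit = observed[(len(observed) - 1) // 2]
    target.imputed.add("first_night_visit")
    return target


def summarize_bird(
    bird_id: str,
    immersion: pd.DataFrame,
    light: pd.DataFrame,
    colony_lonlat: tuple[float, float],
    sex: str,
    *,
    partner_light: pd.DataFrame | None = None,
    exodus_min_days: int = 5,
    min_migration_days: int = 30,
    attendance_ea: float = -6.0,
) -> PhenologySummary:
    """Full phenology for one bird-year of immersion + light data."""
    t = immersion["timestamp"].to_numpy().astype("datetime64[D]")
    d0 = t.min().astype(_dt.date)
    d1 = t.max().astype(_dt.date)
    lon, lat = colony_lonlat
    nights = colony_night_table(d0, d1, lon, lat, attendance_ea)
    days = colony_day_table(d0, d1, lon, lat, attendance_ea)
    nv = detect_night_visits(immersion, nights)
    dv = detect_day_visits(light, days)
    out = PhenologySummary(bird_id)
    try:
        out.last_night_visit, out.first_night_visit = nonbreeding_bounds(
            nv, min_migration_days=min_migration_days
        )
    except ValueError as err:
        warnings.warn(f"{bird_id}: {err}", stacklevel=2)
    ddates = {e.date for e in dv}
    if ddates:
        out.first_day_visit = min(ddates)
        out.last_day_visit = max(ddates)
    partner_dv = None
    if partner_light is not None:
        partner_dv = detect_day_visits(partner_light, days)
    out.laying_date = infer_laying_date(
        dv, nv, sex, partner_day_visits=partner_dv, exodus_min_days=exodus_min_days
    )
    return out
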