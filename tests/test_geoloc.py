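"""Twilight detection, positioning, calibration and the filter cascade."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import shearwater as sw
from shearwater import geoloc, solar
from shearwater.geodesy import haversine_km


def _square_wave_day(date="2012-05-10", rise_h=6.0, set_h=18.0, cadence_min=10):
    t = np.arange(
        np.datetime64(f"{date}T00:00", "s"),
        np.datetime64(f"{date}T00:00", "s") + np.timedelta64(48, "h"),
        np.timedelta64(cadence_min * 60, "s"),
    )
    hours = (t - t.astype("datetime64[D]")).astype(float) / 3600.0
    light = np.where((hours >= rise_h) & (hours < set_h), 64.0, 0.0)
    return pd.DataFrame({"timestamp": t, "light": light})


def test_constant_light_yields_no_pairs():
    df = _square_wave_day()
    df["light"] = 64.0
    with pytest.warns(UserWarning, match="no threshold crossings"):
        pairs = sw.detect_twilights(df)
    assert len(pairs) == 0


def test_square_wave_transitions_within_one_step():
    pairs = sw.detect_twilights(_square_wave_day(cadence_min=10))
    noon = pairs[(pairs["kind"] == "noon") & (pairs["quality"] == "ok")].iloc[0]
    rise_h = (np.datetime64(noon["sunrise_utc"], "s")
              - np.datetime64("2012-05-10T00:00", "s")) / np.timedelta64(1, "h")
    set_h = (np.datetime64(noon["sunset_utc"], "s")
             - np.datetime64("2012-05-10T00:00", "s")) / np.timedelta64(1, "h")
    assert abs(rise_h - 6.0) <= 10 / 60
    assert abs(set_h - 18.0) <= 10 / 60


def test_short_dark_artifact_flagged_and_not_paired():
    df = _square_wave_day()
    hours = (df["timestamp"].to_numpy() - df["timestamp"].to_numpy().astype("datetime64[D]")
             ).astype(float) / 3600.0
    df.loc[(hours >= 11) & (hours < 14) & (df["light"] > 0)
           & (np.arange(len(df)) < 144), "light"] = 0.0
    pairs = sw.detect_twilights(df)
    flagged = pairs[pairs["quality"] == "short_dark"]
    assert len(flagged) == 1
    ok_noon = pairs[(pairs["quality"] == "ok") & (pairs["kind"] == "noon")]
    # the surrounding day still pairs normally across the removed artifact
    assert len(ok_noon) >= 1
    rise_h = (np.datetime64(ok_noon.iloc[0]["sunrise_utc"], "s")
              - np.datetime64("2012-05-10T00:00", "s")) / np.timedelta64(1, "h")
    assert abs(rise_h - 6.0) <= 10 / 60


def test_longitude_zero_at_solar_noon_midpoint():
    date = dt.date(2012, 5, 10)
    noon = solar.solar_noon_utc(date, 0.0)
    pair = {"sunrise_utc": noon - np.timedelta64(7, "h"),
            "sunset_utc": noon + np.timedelta64(7, "h"), "kind": "noon"}
    fx = sw.position_from_twilights(pair, -3.5)
    assert fx.lon == pytest.approx(0.0, abs=0.1)


def test_stationary_roundtrip_june():
    light = sw.simulate_stationary_light(4.0, 40.0, dt.date(2012, 6, 20), 3, ea_true=-3.5)
    fx = sw.positions_from_twilights(sw.detect_twilights(light), -3.5)
    assert (fx["lat"] - 40.0).abs().max() <= 0.5
    assert (fx["lon"] - 4.0).abs().max() <= 0.2


def test_equinox_date_latitude_indeterminate():
    mar, _ = solar.equinox_dates(2012)
    noon = solar.solar_noon_utc(mar, 0.0)
    pair = {"sunrise_utc": noon - np.timedelta64(6, "h"),
            "sunset_utc": noon + np.timedelta64(6, "h"), "kind": "noon"}
    fx = sw.position_from_twilights(pair, -3.5)
    assert fx.lat is None
    assert "equinox" in fx.filters
    assert not fx.retained


def test_ea_bias_shifts_latitude_one_direction():
    """A mis-specified EA biases latitude systematically (one sign per
    hemisphere/season)."""
    light = sw.simulate_stationary_light(4.0, 40.0, dt.date(2012, 6, 1), 8, ea_true=-3.5)
    pairs = sw.detect_twilights(light)
    lat_low = sw.positions_from_twilights(pairs, -4.5)["lat"]
    lat_high = sw.positions_from_twilights(pairs, -2.5)["lat"]
    # June, northern hemisphere: assuming a too-low EA inflates day length
    # interpretation -> latitude biased one way on every fix
    assert (lat_low < 40.0).all()
    assert (lat_high > 40.0).all()


def test_jitter_never_improves_median_error():
    date = dt.date(2012, 5, 1)
    errs = []
    for i, sd in enumerate([0.0, 3.0, 8.0]):
        light = sw.simulate_stationary_light(
            4.0, 40.0, date, 100, ea_true=-3.5, twilight_jitter_sd_min=sd, seed=9
        )
        fx = sw.positions_from_twilights(sw.detect_twilights(light), -3.5)
        fx = fx[fx["lat"].notna()]
        errs.append(np.median(haversine_km(fx["lon"], fx["lat"], 4.0, 40.0)))
    assert errs[0] <= errs[1] <= errs[2]


def test_calibration_recovers_true_ea():
    light = sw.simulate_stationary_light(4.317, 39.867, dt.date(2012, 4, 5), 20,
                                         ea_true=-3.5)
    cal = sw.calibrate_from_light(light, (4.317, 39.867),
                                  (dt.date(2012, 4, 5), dt.date(2012, 4, 24)))
    assert abs(cal.ea - (-3.5)) <= 0.25


def test_calibration_single_candidate_and_ties():
    fixes = pd.DataFrame({
        "date": [dt.date(2012, 4, i) for i in range(1, 13)],
        "time": np.arange(np.datetime64("2012-04-01T12:00", "s"),
                          np.datetime64("2012-04-13T12:00", "s"),
                          np.timedelta64(1, "D")),
        "kind": "noon", "lon": 4.3, "lat": 39.9, "filters": "", "retained": True,
    })
    res = sw.calibrate_ea({-2.75: fixes}, (4.317, 39.867),
                          (dt.date(2012, 4, 1), dt.date(2012, 4, 30)))
    assert res.ea == -2.75
    # equal scores (symmetric north/south offsets), tie broken by fewer
    # on-land points: the northern set sits inside the land polygon
    from shapely.geometry import box

    north = fixes.copy()
    north["lon"], north["lat"] = 4.317, 39.867 + 0.2
    south = fixes.copy()
    south["lon"], south["lat"] = 4.317, 39.867 - 0.2
    land = box(4.0, 39.95, 5.0, 40.5)
    window = (dt.date(2012, 4, 1), dt.date(2012, 4, 30))
    res2 = sw.calibrate_ea({-3.0: north, -4.0: south}, (4.317, 39.867), window,
                           land_polygon=land)
    assert res2.per_ea[-3.0][0] == pytest.approx(res2.per_ea[-4.0][0], abs=1e-6)
    assert res2.ea == -4.0
    # equal score and equal land count -> EA closest to -3.5 wins
    res3 = sw.calibrate_ea({-2.75: north.copy(), -3.25: north.copy()},
                           (4.317, 39.867), window)
    assert res3.ea == -3.25


def test_calibration_requires_enough_fixes():
    few = pd.DataFrame({
        "date": [dt.date(2012, 4, 1)], "time": [np.datetime64("2012-04-01T12:00", "s")],
        "kind": ["noon"], "lon": [4.3], "lat": [39.9], "filters": [""],
        "retained": [True],
    })
    with pytest.raises(ValueError, match="usable fixes"):
        sw.calibrate_ea({-3.5: few}, (4.317, 39.867),
                        (dt.date(2012, 4, 1), dt.date(2012, 4, 30)))


# ---------------------------------------------------------------------------
# filtering


def _fix_frame(rows):
    return pd.DataFrame(rows, columns=["date", "time", "kind", "lon", "lat",
                                       "filters", "retained"])


def test_equinox_window_sides():
    mar, sep = solar.equinox_dates(2012)
    rows = []
    for d in [mar - dt.timedelta(days=3), mar - dt.timedelta(days=11),
              mar + dt.timedelta(days=4), mar + dt.timedelta(days=6),
              sep - dt.timedelta(days=4), sep - dt.timedelta(days=6),
              sep + dt.timedelta(days=9), sep + dt.timedelta(days=11)]:
        rows.append((d, np.datetime64(d.isoformat() + "T12:00", "s"), "noon",
                     4.0, 40.0, "", True))
    out = sw.filter_track(_fix_frame(rows))
    flagged = dict(zip(out["date"], out["filters"].str.contains("equinox")))
    # 10 d before / 5 d after March; 5 d before / 10 d after September
    expect = {
        mar - dt.timedelta(days=3): True, mar - dt.timedelta(days=11): False,
        mar + dt.timedelta(days=4): True, mar + dt.timedelta(days=6): False,
        sep - dt.timedelta(days=4): True, sep - dt.timedelta(days=6): False,
        sep + dt.timedelta(days=9): True, sep + dt.timedelta(days=11): False,
    }
    assert flagged == expect


def test_speed_filter_threshold():
    t0 = np.datetime64("2012-05-01T12:00", "s")
    base = (dt.date(2012, 5, 1), t0, "noon", 4.0, 40.0, "", True)
    # 120 km in 2 h = 60 km/h -> flagged
    fast = (dt.date(2012, 5, 1), t0 + np.timedelta64(2, "h"), "midnight",
            4.0, 40.0 + 120 / 111.19, "", True)
    out = sw.filter_track(_fix_frame([base, fast]))
    assert out.iloc[1]["filters"] == "speed"
    # same displacement in 3 h = 40 km/h -> retained
    slow = (dt.date(2012, 5, 1), t0 + np.timedelta64(3, "h"), "midnight",
            4.0, 40.0 + 120 / 111.19, "", True)
    out = sw.filter_track(_fix_frame([base, slow]))
    assert out["retained"].all()


def _bruteforce_filter(df, vmax=55.0):
    """Independent plain-loop implementation of the filtering rules."""
    mar, sep = solar.equinox_dates(2012)
    windows = [(mar - dt.timedelta(days=10), mar + dt.timedelta(days=5)),
               (sep - dt.timedelta(days=5), sep + dt.timedelta(days=10))]
    flags = []
    for _, r in df.iterrows():
        f = set()
        if any(a <= r["date"] <= b for a, b in windows):
            f.add("equinox")
        if pd.isna(r["lat"]):
            f.add("no_lat")
        elif not (30.0 <= r["lat"] <= 52.0):
            f.add("lat_bounds")
        flags.append(f)
    last = None
    for i, (_, r) in enumerate(df.iterrows()):
        if flags[i]:
            continue
        if last is not None:
            km = haversine_km(last[0], last[1], r["lon"], r["lat"])
            hrs = (np.datetime64(r["time"], "s") - last[2]) / np.timedelta64(1, "h")
            if km / hrs > vmax:
                flags[i].add("speed")
                continue
        last = (r["lon"], r["lat"], np.datetime64(r["time"], "s"))
    return [not f for f in flags]


def test_planted_fixture_matches_bruteforce_oracle():
    from shearwater.pipeline import fixture_filter_track

    df = fixture_filter_track()
    out = sw.filter_track(df)
    expected = _bruteforce_filter(df)
    assert out["retained"].tolist() == expected
    assert int(out["retained"].sum()) == 14


@given(st.lists(st.tuples(st.integers(0, 200), st.floats(-10, 10),
                          st.floats(25, 55)), min_size=1, max_size=25))
def test_filter_idempotent(raw):
    t0 = np.datetime64("2012-04-01T00:00", "s")
    rows = []
    for k, (offset_h, lon, lat) in enumerate(sorted(raw)):
        t = t0 + np.timedelta64(int(offset_h * 3600 + k), "s")
        rows.append((t.astype("datetime64[D]").astype(dt.date), t, "noon",
                     lon, lat, "", True))
    df = _fix_frame(rows)
    once = sw.filter_track(df)
    twice = sw.filter_track(once)
    pd.testing.assert_frame_equal(once, twice)


def test_manual_flags_survive_refiltering():
    t0 = np.datetime64("2012-05-01T12:00", "s")
    df = _fix_frame([
        (dt.date(2012, 5, 1), t0, "noon", 4.0, 40.0, "manual", False),
        (dt.date(2012, 5, 2), t0 + np.timedelta64(1, "D"), "noon", 4.1, 40.1, "", True),
    ])
    out = sw.filter_track(df)
    assert out.iloc[0]["filters"] == "manual"
    assert not out.iloc[0]["retained"]
    assert out.iloc[1]["retained"]
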