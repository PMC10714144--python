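"""GPS filtering, trip segmentation, distances and day/night apportionment."""

import numpy as np
import pandas as pd
import pytest

from fmrcal import solar, trips

COLONY = (-38.2783, 144.6967)


def track(times_s, lats, lons, t0="2014-12-06T00:00:00"):
    t = np.datetime64(t0) + np.array(times_s).astype("timedelta64[s]")
    return pd.DataFrame({"time": t, "lat": lats, "lon": lons})


class TestHaversine:
    def test_coincident_points(self):
        assert trips.haversine_km(10.0, 20.0, 10.0, 20.0) == 0.0

    def test_symmetry(self, rng):
        a = rng.uniform(-60, 60, 20)
        b = rng.uniform(-180, 180, 20)
        c = rng.uniform(-60, 60, 20)
        d = rng.uniform(-180, 180, 20)
        assert np.allclose(trips.haversine_km(a, b, c, d), trips.haversine_km(c, d, a, b))

    def test_one_degree_longitude_at_equator(self):
        # closed form: 2*pi*R/360
        expected = 2 * np.pi * trips.EARTH_RADIUS_KM / 360.0
        assert trips.haversine_km(0.0, 0.0, 0.0, 1.0) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(111.19, abs=0.01)


class TestSpeedFilter:
    def test_teleport_fix_removed(self):
        # middle fix implies ~500 km/h
        df = track([0, 120, 240], [-38.0, -37.0, -38.001], [144.0, 148.0, 144.001])
        out = trips.speed_filter(df, vmax_kmh=85.0)
        assert len(out) == 2
        assert out["lat"].iloc[1] == pytest.approx(-38.001)

    def test_slow_track_unchanged(self):
        lats = -38.0 + np.arange(10) * 0.001
        df = track(np.arange(10) * 120, lats, np.full(10, 144.0))
        out = trips.speed_filter(df, 85.0)
        pd.testing.assert_frame_equal(out, df)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        lats = -38.0 + np.cumsum(rng.normal(0, 0.005, 30))
        df = track(np.arange(30) * 120, lats, np.full(30, 144.0))
        once = trips.speed_filter(df, 40.0)
        twice = trips.speed_filter(once, 40.0)
        pd.testing.assert_frame_equal(once, twice)

    def test_never_increases_distance(self):
        rng = np.random.default_rng(1)
        lats = -38.0 + np.cumsum(rng.normal(0, 0.01, 50))
        df = track(np.arange(50) * 120, lats, np.full(50, 144.0))
        out = trips.speed_filter(df, 60.0)

        def total(d):
            return np.sum(
                trips.haversine_km(
                    d["lat"].to_numpy()[:-1], d["lon"].to_numpy()[:-1],
                    d["lat"].to_numpy()[1:], d["lon"].to_numpy()[1:],
                )
            )

        assert total(out) <= total(df) + 1e-9


class TestSegmentTrips:
    def test_no_fix_beyond_radius(self):
        df = track([0, 120, 240], [COLONY[0]] * 3, [COLONY[1]] * 3)
        s = trips.segment_trips(df, COLONY, 0.5)
        assert s.n_trips == 0 and s.total_distance_km == 0.0

    def test_out_and_back_distance(self):
        # straight 50 km out along a meridian and back: total ~ 100 km
        deg = 50.0 / (2 * np.pi * trips.EARTH_RADIUS_KM / 360.0)
        steps = np.concatenate([np.linspace(0, deg, 26), np.linspace(deg, 0, 26)[1:]])
        df = track(np.arange(len(steps)) * 120, COLONY[0] + steps, np.full(len(steps), COLONY[1]))
        s = trips.segment_trips(df, COLONY, 0.5)
        assert s.n_trips == 1
        assert s.total_distance_km == pytest.approx(100.0, rel=0.03)

    def test_trips_do_not_overlap(self):
        deg = 5.0 / 111.195
        lats = COLONY[0] + np.array([0, deg, deg, 0, 0, deg, 0])
        df = track(np.arange(7) * 600, lats, np.full(7, COLONY[1]))
        s = trips.segment_trips(df, COLONY, 0.5)
        assert s.n_trips == 2
        assert (s.trips["start"].iloc[1] - s.trips["end"].iloc[0]) > np.timedelta64(0, "s")

    def test_collinear_midpoint_invariance(self):
        deg = 30.0 / 111.195
        lats = COLONY[0] + np.array([0.0, deg / 2, deg, deg / 2, 0.0])
        df = track(np.arange(5) * 1800, lats, np.full(5, COLONY[1]))
        base = trips.segment_trips(df, COLONY, 0.5).total_distance_km
        # insert collinear midpoints
        lats2 = COLONY[0] + np.array([0, deg / 4, deg / 2, 3 * deg / 4, deg,
                                      3 * deg / 4, deg / 2, deg / 4, 0.0])
        df2 = track(np.arange(9) * 900, lats2, np.full(9, COLONY[1]))
        dense = trips.segment_trips(df2, COLONY, 0.5).total_distance_km
        assert dense == pytest.approx(base, rel=1e-3)

    def test_window_clips_fixes(self):
        deg = 5.0 / 111.195
        df = track(np.arange(6) * 600, COLONY[0] + deg * np.ones(6), np.full(6, COLONY[1]))
        w = (df["time"].iloc[2], df["time"].iloc[4])
        s = trips.segment_trips(df, COLONY, 0.5, window=w)
        assert s.total_time_h == pytest.approx(2 * 600 / 3600.0)


# --- independent solar ephemeris (Astronomical Almanac low-precision sun) ---

def _almanac_elevation_deg(t, lat, lon):
    jd = 2451545.0 + float(
        (np.datetime64(t, "s") - np.datetime64("2000-01-01T12:00:00")) / np.timedelta64(1, "D")
    )
    n = jd - 2451545.0
    L = np.deg2rad((280.460 + 0.9856474 * n) % 360.0)
    g = np.deg2rad((357.528 + 0.9856003 * n) % 360.0)
    lam = L + np.deg2rad(1.915) * np.sin(g) + np.deg2rad(0.020) * np.sin(2 * g)
    eps = np.deg2rad(23.439 - 0.0000004 * n)
    decl = np.arcsin(np.sin(eps) * np.sin(lam))
    ra = np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))
    gmst_h = (18.697374558 + 24.06570982441908 * n) % 24.0
    ha = np.deg2rad(gmst_h * 15.0) + np.deg2rad(lon) - ra
    phi = np.deg2rad(lat)
    sin_el = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
    return np.rad2deg(np.arcsin(sin_el))


def _almanac_crossing(day, lat, lon, rising):
    lo = np.datetime64(day, "s")
    hi = lo + np.timedelta64(86399, "s")
    # scan hourly for the bracketing interval around -0.833 deg
    times = [lo + np.timedelta64(h * 3600, "s") for h in range(25)]
    els = [_almanac_elevation_deg(t, lat, lon) - (-0.833) for t in times]
    for a, b, ea, eb in zip(times[:-1], times[1:], els[:-1], els[1:]):
        if ea < 0 < eb and rising or ea > 0 > eb and not rising:
            while (b - a) > np.timedelta64(1, "s"):
                mid = a + (b - a) / 2
                em = _almanac_elevation_deg(mid, lat, lon) - (-0.833)
                if (em < 0) == (ea < 0):
                    a, ea = mid, em
                else:
                    b, eb = mid, em
            return a
    raise AssertionError("no crossing found")


class TestDayNight:
    def test_interval_within_daylight_is_all_day(self):
        iv = [(np.datetime64("2014-12-06T00:00"), np.datetime64("2014-12-06T04:00"))]
        d, n = solar.day_night_split(iv, *COLONY)  # 11:00-15:00 local summer
        assert d == pytest.approx(4.0) and n == pytest.approx(0.0)

    def test_conservation(self):
        iv = [
            (np.datetime64("2014-12-05T20:00"), np.datetime64("2014-12-06T13:30")),
            (np.datetime64("2014-12-07T02:00"), np.datetime64("2014-12-07T21:15")),
        ]
        d, n = solar.day_night_split(iv, *COLONY)
        total = 17.5 + 19.25
        assert d + n == pytest.approx(total, abs=1e-6)
        assert d > 0 and n > 0

    @pytest.mark.parametrize("date", ["2014-12-06", "2014-12-08", "2015-06-21"])
    def test_sunrise_sunset_match_independent_ephemeris(self, date):
        # NOAA-style routine vs the Astronomical Almanac low-precision sun
        rise, sett = solar.sunrise_sunset(np.datetime64(date), *COLONY)
        rise_o = _almanac_crossing(np.datetime64(date, "D"), *COLONY, rising=True)
        set_o = _almanac_crossing(np.datetime64(date, "D"), *COLONY, rising=False)

        def mins(a, b):
            return abs(float((np.datetime64(a, "s") - b) / np.timedelta64(1, "m")))

        # events may belong to adjacent UTC days; compare modulo 24 h
        dr = mins(rise, rise_o)
        ds = mins(sett, set_o)
        assert min(dr, abs(dr - 1440)) < 2.0
        assert min(ds, abs(ds - 1440)) < 2.0

    def test_polar_night_raises(self):
        with pytest.raises(ValueError, match="polar"):
            solar.sunrise_sunset(np.datetime64("2014-12-21"), 80.0, 0.0)
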