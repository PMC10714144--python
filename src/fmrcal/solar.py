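"""Sunrise/sunset from the NOAA solar-position equations.

Used to apportion time on the nest (and at sea) into day and night.  The
routine follows the NOAA Solar Calculator formulation: Julian-century solar
geometry, the equation of time, and the hour angle at the standard
sunrise/sunset zenith of 90.833 deg (solar centre 0.833 deg below the
horizon, accounting for refraction and the solar radius).  Accuracy is well
inside one minute at mid-latitudes, which is ample for hour-scale budgets.

All timestamps are UTC (numpy datetime64).
"""

from __future__ import annotations

import numpy as np

__all__ = ["sunrise_sunset", "sun_elevation_deg", "day_night_split"]

_ZENITH_DEG = 90.833


def _julian_day(t: np.datetime64) -> float:
    # days since the J2000.0 epoch (2000-01-01 12:00 UTC), as a Julian Day
    epoch = np.datetime64("2000-01-01T12:00:00")
    return 2451545.0 + float((t - epoch) / np.timedelta64(1, "D"))


def _solar_geometry(jd: float):
    jc = (jd - 2451545.0) / 36525.0
    l0 = np.deg2rad((280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0)
    m = np.deg2rad(357.52911 + jc * (35999.05029 - 0.0001537 * jc))
    e = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    c = (
        np.sin(m) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * m) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * m) * 0.000289
    )
    true_long = np.rad2deg(l0) + c
    omega = np.deg2rad(125.04 - 1934.136 * jc)
    app_long = np.deg2rad(true_long - 0.00569 - 0.00478 * np.sin(omega))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = np.deg2rad(mean_obliq + 0.00256 * np.cos(omega))
    decl = np.arcsin(np.sin(obliq) * np.sin(app_long))
    y = np.tan(obliq / 2.0) ** 2
    eot_min = 4.0 * np.rad2deg(
        y * np.sin(2 * l0)
        - 2.0 * e * np.sin(m)
        + 4.0 * e * y * np.sin(m) * np.cos(2 * l0)
        - 0.5 * y * y * np.sin(4 * l0)
        - 1.25 * e * e * np.sin(2 * m)
    )
    return decl, eot_min


def sun_elevation_deg(t: np.datetime64, lat: float, lon: float) -> float:
    """Apparent solar elevation (deg, no refraction term) at UTC time t."""
    jd = _julian_day(t)
    decl, eot = _solar_geometry(jd)
    day_start = t.astype("datetime64[D]").astype("datetime64[s]")
    minutes_utc = float((t - day_start) / np.timedelta64(1, "m"))
    true_solar_min = (minutes_utc + eot + 4.0 * lon) % 1440.0
    ha = np.deg2rad(true_solar_min / 4.0 - 180.0)
    phi = np.deg2rad(lat)
    sin_el = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
    return float(np.rad2deg(np.arcsin(np.clip(sin_el, -1.0, 1.0))))


def sunrise_sunset(
    date: np.datetime64, lat: float, lon: float
) -> tuple[np.datetime64, np.datetime64]:
    """UTC sunrise and sunset for the given UTC calendar date.

    Raises for polar day/night (no crossing of the 90.833 deg zenith).
    """
    day = np.datetime64(date, "D").astype("datetime64[s]")
    phi = np.deg2rad(lat)

    def events(noon_guess_min: float | None = None):
        guess = 720.0 if noon_guess_min is None else noon_guess_min
        jd = _julian_day(day + np.timedelta64(int(round(guess * 60)), "s"))
        decl, eot = _solar_geometry(jd)
        cos_ha = (
            np.cos(np.deg2rad(_ZENITH_DEG)) / (np.cos(phi) * np.cos(decl))
            - np.tan(phi) * np.tan(decl)
        )
        if not (-1.0 < cos_ha < 1.0):
            raise ValueError("polar day or polar night: sun never crosses the horizon")
        ha_deg = np.rad2deg(np.arccos(cos_ha))
        noon_min = 720.0 - 4.0 * lon - eot
        return noon_min, ha_deg

    noon_min, ha_deg = events()
    # one refinement pass with geometry evaluated at the actual event times
    _, ha_rise = events(noon_min - ha_deg * 4.0)
    noon_min2, ha_set = events(noon_min + ha_deg * 4.0)
    rise_min = noon_min2 - ha_rise * 4.0
    set_min = noon_min2 + ha_set * 4.0
    rise = day + np.timedelta64(int(round(rise_min * 60.0)), "s")
    sett = day + np.timedelta64(int(round(set_min * 60.0)), "s")
    return rise, sett


def _events_between(t0: np.datetime64, t1: np.datetime64, lat: float, lon: float) -> np.ndarray:
    d0 = (np.datetime64(t0, "D") - np.timedelta64(1, "D")).astype("datetime64[D]")
    d1 = (np.datetime64(t1, "D") + np.timedelta64(1, "D")).astype("datetime64[D]")
    ev = []
    d = d0
    while d <= d1:
        r, s = sunrise_sunset(d, lat, lon)
        ev.extend([r, s])
        d = d + np.timedelta64(1, "D")
    ev = np.array(sorted(ev), dtype="datetime64[s]")
    return ev[(ev > np.datetime64(t0, "s")) & (ev < np.datetime64(t1, "s"))]


def day_night_split(
    intervals: list[tuple[np.datetime64, np.datetime64]], lat: float, lon: float
) -> tuple[float, float]:
    """Split a set of time intervals into (day_hours, night_hours).

    Each interval is cut at every sunrise/sunset event it spans; each piece
    is classified by the solar elevation at its midpoint against the
    -0.833 deg horizon.  Day + night always equals the total interval
    length.
    """
    t_day = 0.0
    t_night = 0.0
    horizon = 90.0 - _ZENITH_DEG  # -0.833 deg
    for t0, t1 in intervals:
        t0 = np.datetime64(t0, "s")
        t1 = np.datetime64(t1, "s")
        if t1 <= t0:
            continue
        cuts = np.concatenate(([t0], _events_between(t0, t1, lat, lon), [t1]))
        for a, b in zip(cuts[:-1], cuts[1:]):
            mid = a + (b - a) / 2
            hours = float((b - a) / np.timedelta64(1, "h"))
            if sun_elevation_deg(mid, lat, lon) > horizon:
                t_day += hours
            else:
                t_night += hours
    return t_day, t_night
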