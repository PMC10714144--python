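"""GPS processing for a central-place forager: speed filter, foraging-trip
segmentation, distance/duration covariates, and day/night apportionment.

Fixes arrive at a nominal 2-min interval.  A McConnell-style iterative
speed filter removes fixes implying unrealistic travel speeds; trips are
maximal runs of fixes beyond a radius around the colony; total distance
travelled (TD) sums great-circle legs within trips over the DLW sampling
window (equilibration sample to final sample).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import solar

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "speed_filter",
    "segment_trips",
    "interp_speed_1s",
    "TripSummary",
]

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance (km) on a sphere of radius 6371 km; vectorized."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlam = np.deg2rad(lon2) - np.deg2rad(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _leg_speeds_kmh(df: pd.DataFrame) -> np.ndarray:
    d = haversine_km(
        df["lat"].to_numpy()[:-1], df["lon"].to_numpy()[:-1],
        df["lat"].to_numpy()[1:], df["lon"].to_numpy()[1:],
    )
    dt_h = np.diff(df["time"].to_numpy()) / np.timedelta64(1, "h")
    with np.errstate(divide="ignore"):
        return np.where(dt_h > 0, d / dt_h, np.inf)


def speed_filter(fixes: pd.DataFrame, vmax_kmh: float = 85.0) -> pd.DataFrame:
    """Iteratively drop fixes implying point-to-point speed above vmax.

    Each pass removes the later fix of every over-speed leg; passes repeat
    until no leg exceeds vmax.  The first and last fixes are never dropped.
    Raises if filtering would empty the track.
    """
    if vmax_kmh <= 0:
        raise ValueError("vmax must be positive")
    df = fixes.sort_values("time").reset_index(drop=True)
    if not df["time"].is_monotonic_increasing or df["time"].duplicated().any():
        raise ValueError("fix times must be strictly increasing")
    while len(df) > 2:
        sp = _leg_speeds_kmh(df)
        bad = np.nonzero(sp > vmax_kmh)[0] + 1  # index of the later fix
        bad = bad[bad < len(df) - 1]  # protect the last fix
        if bad.size == 0:
            break
        # drop one fix per offending run to avoid cascading removals
        drop = [int(bad[0])]
        for b in bad[1:]:
            if b > drop[-1] + 1:
                drop.append(int(b))
        df = df.drop(index=drop).reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("speed filter removed all fixes")
    return df


class TripSummary:
    """Per-trip table plus per-bird movement covariates."""

    def __init__(self, trips: pd.DataFrame, total_distance_km: float,
                 time_at_sea_h: float, total_time_h: float):
        self.trips = trips
        self.total_distance_km = total_distance_km
        self.time_at_sea_h = time_at_sea_h
        self.total_time_h = total_time_h

    @property
    def n_trips(self) -> int:
        return len(self.trips)

    @property
    def proportion_at_sea(self) -> float:
        return self.time_at_sea_h / self.total_time_h if self.total_time_h > 0 else 0.0


def segment_trips(
    fixes: pd.DataFrame,
    colony_latlon: tuple[float, float],
    radius_km: float = 0.5,
    window: tuple[np.datetime64, np.datetime64] | None = None,
) -> TripSummary:
    """Segment a track into foraging trips.

    A trip is a maximal run of fixes beyond ``radius_km`` from the colony;
    trip distance sums consecutive great-circle legs between those fixes.
    If a sampling ``window`` is given (equilibration -> final blood sample),
    fixes outside it are discarded first and partial trips truncate at the
    boundary.
    """
    df = fixes.sort_values("time").reset_index(drop=True)
    if window is not None:
        t0, t1 = window
        df = df[(df["time"] >= t0) & (df["time"] <= t1)].reset_index(drop=True)
    lat0, lon0 = colony_latlon
    if len(df) == 0:
        empty = pd.DataFrame(columns=["start", "end", "duration_h", "distance_km"])
        return TripSummary(empty, 0.0, 0.0, 0.0)
    away = haversine_km(df["lat"].to_numpy(), df["lon"].to_numpy(), lat0, lon0) > radius_km
    t = df["time"].to_numpy()
    total_h = float((t[-1] - t[0]) / np.timedelta64(1, "h"))
    rows = []
    i = 0
    n = len(df)
    while i < n:
        if not away[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and away[j + 1]:
            j += 1
        # include the anchor fix on each side (last/first fix inside the
        # radius) so the commute legs crossing the boundary count towards
        # distance travelled
        lo = i - 1 if i > 0 else i
        hi = j + 1 if j + 1 < n else j
        seg = df.iloc[lo : hi + 1]
        dist = float(
            np.sum(
                haversine_km(
                    seg["lat"].to_numpy()[:-1], seg["lon"].to_numpy()[:-1],
                    seg["lat"].to_numpy()[1:], seg["lon"].to_numpy()[1:],
                )
            )
        )
        core = df.iloc[i : j + 1]
        dur = float((core["time"].iloc[-1] - core["time"].iloc[0]) / np.timedelta64(1, "h"))
        # half a fix interval on each side: run boundaries fall between fixes
        if i > 0:
            dur += float((core["time"].iloc[0] - df["time"].iloc[i - 1]) / np.timedelta64(1, "h")) / 2.0
        if j + 1 < n:
            dur += float((df["time"].iloc[j + 1] - core["time"].iloc[-1]) / np.timedelta64(1, "h")) / 2.0
        rows.append({"start": core["time"].iloc[0], "end": core["time"].iloc[-1],
                     "duration_h": dur, "distance_km": dist})
        i = j + 1
    trips = pd.DataFrame(rows, columns=["start", "end", "duration_h", "distance_km"])
    td = float(trips["distance_km"].sum()) if len(trips) else 0.0
    sea_h = float(trips["duration_h"].sum()) if len(trips) else 0.0
    return TripSummary(trips, td, sea_h, total_h)


def interp_speed_1s(fixes: pd.DataFrame, grid_times: np.ndarray) -> np.ndarray:
    """Travel speed (km/h) on a 1-s grid by linear interpolation.

    Each leg between consecutive fixes carries a constant speed; grid
    seconds before the first or after the last fix get the nearest leg's
    speed.  Coarse (2-min fixes), but the only speed information available.
    """
    t = fixes["time"].to_numpy().astype("datetime64[s]").astype(np.int64)
    if len(t) < 2:
        return np.zeros(len(grid_times))
    sp = _leg_speeds_kmh(fixes)
    g = np.asarray(grid_times).astype("datetime64[s]").astype(np.int64)
    idx = np.clip(np.searchsorted(t, g, side="right") - 1, 0, len(sp) - 1)
    return sp[idx]


def on_land_mask_1s(
    fixes: pd.DataFrame,
    grid_times: np.ndarray,
    colony_latlon: tuple[float, float],
    radius_km: float = 0.5,
) -> np.ndarray:
    """Per-second colony mask: nearest-fix distance to colony <= radius."""
    t = fixes["time"].to_numpy().astype("datetime64[s]").astype(np.int64)
    lat = np.interp(
        np.asarray(grid_times).astype("datetime64[s]").astype(np.int64),
        t, fixes["lat"].to_numpy(),
    )
    lon = np.interp(
        np.asarray(grid_times).astype("datetime64[s]").astype(np.int64),
        t, fixes["lon"].to_numpy(),
    )
    return haversine_km(lat, lon, colony_latlon[0], colony_latlon[1]) <= radius_km


def land_day_night(
    land_intervals: list[tuple[np.datetime64, np.datetime64]],
    lat: float,
    lon: float,
) -> tuple[float, float]:
    """(T_land_day, T_land_night) in hours via the solar-position routine."""
    return solar.day_night_split(land_intervals, lat, lon)
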