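"""Synthetic seabird deployments with known ground truth.

Generates, per bird: a per-second six-class ethogram with central-place
structure (alternating colony visits and foraging trips), the matching
25 Hz tri-axial accelerometry, a 2-min GPS track, and a two-isotope
washout record consistent with a known true energy budget
``EE = sum_i C_i * T_i``.  Every downstream stage of the pipeline is
therefore testable against exact truth.

Behaviour model: a semi-Markov chain with exponential dwell times.  A
deployment alternates colony blocks (rest_land) with trips; a trip
alternates flight phases (flapping/gliding sub-bouts) with surface-rest
phases.  Plunge dives are inserted at flight sub-bout boundaries (entered
from flight); duck dives interrupt surface rest (entered from the water).

Isotope model: the single-pool DLW equation is inverted.  The water
turnover k_d is fixed by config; given the true energy budget, the pool
size implied by body mass, and the energy equivalent, the oxygen turnover
k_o is solved from

    rCO2 = (N / 2.078) (k_o - k_d) - 0.0062 k_d N

and the enrichments follow exponential washout plus Gaussian measurement
noise.  Noise-free records round-trip through the DLW module exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dlw as dlw_mod
from .accel import AccelTrace
from .behaviour import BEHAVIOURS, Ethogram

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_ethogram",
    "simulate_accel",
    "simulate_gps",
    "simulate_isotopes",
    "simulate_morphometrics",
    "draw_dwell",
]


def _default_dwell() -> dict[str, float]:
    # mean dwell (s): colony visits are half-day-scale, surface-rest phases
    # tens of minutes, flight sub-bouts around a minute, dives seconds
    return {
        "flapping": 60.0,
        "gliding": 24.0,
        "rest_sea": 1550.0,
        "rest_land": 43200.0,
        "plunge_dive": 2.0,
        "duck_dive": 2.0,
    }


def _default_accel() -> dict[str, tuple[float, float, tuple[float, float, float]]]:
    # per behaviour: (dominant frequency Hz, heave dynamic amplitude g,
    # static orientation unit vector).  Amplitudes chosen so cohort VeDBA
    # means sit at realistic levels for a large plunge-diving sulid.
    return {
        "flapping": (3.5, 2.2, (0.26, 0.0, 0.966)),
        "gliding": (0.8, 0.45, (0.17, 0.0, 0.985)),
        "rest_sea": (0.6, 0.32, (0.05, 0.0, 0.999)),
        "rest_land": (0.7, 0.08, (0.0, 0.0, 1.0)),
        "plunge_dive": (1.5, 3.0, (0.71, 0.0, 0.71)),
        "duck_dive": (1.5, 3.0, (0.71, 0.0, 0.71)),
    }


def _default_coefficients() -> dict[str, float]:
    # true energy rates C_i (kJ/h); flight and dives costly, land cheapest
    return {
        "flapping": 360.0,
        "gliding": 240.0,
        "rest_sea": 140.0,
        "rest_land": 55.0,
        "plunge_dive": 580.0,
        "duck_dive": 480.0,
    }


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort."""

    n_birds: int = 15
    sampling_rate: float = 25.0
    deployment_h: float = 74.0
    start_time: np.datetime64 = field(default_factory=lambda: np.datetime64("2014-12-05T21:00:00"))
    colony_latlon: tuple[float, float] = (-38.2783, 144.6967)
    trip_speed_kmh: float = 45.0
    trip_h: float = 13.0  # mean trip duration (0 disables trips)
    flight_bout_s: float = 700.0  # mean flight-phase duration within a trip
    behaviour_dwell: dict[str, float] = field(default_factory=_default_dwell)
    behaviour_accel: dict[str, tuple] = field(default_factory=_default_accel)
    true_coefficients: dict[str, float] = field(default_factory=_default_coefficients)
    plunge_per_sea_h: float = 2.1
    duck_per_sea_h: float = 2.2
    #: between-bird lognormal CV on dwell means / trip length; drives the
    #: spread in activity mixes that identifies the activity coefficients
    individual_variation_cv: float = 0.35
    vedba_noise_sd: float = 0.05  # g per axis
    isotope_noise_sd: float = 2.0  # ppm on measured enrichments
    gps_noise_km: float = 0.01
    # isotope / body parameters
    body_mass_mean_kg: float = 2.61
    body_mass_sd_kg: float = 0.15
    tarsus_mean_mm: float = 57.0
    tarsus_sd_mm: float = 2.0
    tbw_fraction: float = 0.60
    k_d_per_day: float = 0.30
    dose_g: float = 1.85
    inj_O_ppm: float = 643000.0
    inj_H_ppm: float = 341000.0
    bg_O_ppm: float = 1990.0
    bg_H_ppm: float = 150.0
    energy_equiv_kj_per_L: float = dlw_mod.DEFAULT_ENERGY_EQUIV_KJ_PER_L
    seed: int = 0

    def validate(self) -> None:
        if set(self.behaviour_dwell) != set(BEHAVIOURS):
            raise ValueError(f"behaviour set must be exactly {BEHAVIOURS}")
        if set(self.true_coefficients) != set(BEHAVIOURS):
            raise ValueError(f"coefficient set must be exactly {BEHAVIOURS}")
        for name, v in self.behaviour_dwell.items():
            if v <= 0:
                raise ValueError(f"dwell time for {name} must be positive")
        for name, v in self.true_coefficients.items():
            if v <= 0:
                raise ValueError(f"energy rate for {name} must be positive")
        for name, (f, a, _o) in self.behaviour_accel.items():
            if f <= 0 or a < 0:
                raise ValueError(f"accel parameters for {name} invalid")
        if self.deployment_h <= 0 or self.sampling_rate <= 0:
            raise ValueError("deployment and sampling rate must be positive")
        if self.trip_h < 0:
            raise ValueError("trip_h must be non-negative")


@dataclass
class TruthRecord:
    """Ground truth carried alongside one synthetic bird."""

    bird_id: str
    true_T_h: dict[str, float] = field(default_factory=dict)
    true_EE_kj: float = 0.0
    true_rco2_L_h: float | None = None
    true_k_d: float | None = None
    true_k_o: float | None = None
    true_trip_distance_km: float | None = None
    n_plunge: int = 0
    n_duck: int = 0


def draw_dwell(rng: np.random.Generator, mean_s: float) -> int:
    """One dwell time: exponential with the configured mean, rounded to the
    1-s grid, at least 1 s."""
    return max(1, int(round(rng.exponential(mean_s))))


def simulate_ethogram(config: SimConfig, bird_id: str, rng: np.random.Generator | None = None
                      ) -> tuple[Ethogram, TruthRecord]:
    """Per-second behaviour sequence with central-place structure."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_sec = int(round(config.deployment_h * 3600))
    if n_sec < min(config.behaviour_dwell.values()):
        raise ValueError("deployment shorter than one dwell time")

    # per-bird behavioural heterogeneity: lognormal multipliers on the dwell
    # means (mean 1), one per behaviour plus trip length and flight phases
    cv = config.individual_variation_cv
    if cv > 0:
        sig = np.sqrt(np.log1p(cv * cv))

        def jitter() -> float:
            return float(rng.lognormal(-0.5 * sig * sig, sig))

    else:
        def jitter() -> float:
            return 1.0

    dw = {b: v * jitter() for b, v in config.behaviour_dwell.items()}
    trip_h = config.trip_h * jitter() if config.trip_h > 0 else 0.0
    flight_bout_s = config.flight_bout_s * jitter()

    # expected at-sea composition, used to convert per-sea-hour dive rates
    # into insertion probabilities
    flight_frac = flight_bout_s / (flight_bout_s + dw["rest_sea"])
    mean_sub = 0.5 * (dw["flapping"] + dw["gliding"])
    subbouts_per_sea_h = flight_frac * 3600.0 / mean_sub if mean_sub > 0 else 0.0
    p_plunge = min(1.0, config.plunge_per_sea_h / subbouts_per_sea_h) if subbouts_per_sea_h else 0.0
    rest_frac = 1.0 - flight_frac
    duck_per_rest_h = config.duck_per_sea_h / rest_frac if rest_frac > 0 else 0.0

    labels: list[str] = []
    n_plunge = n_duck = 0

    def emit(kind: str, dur: int) -> None:
        labels.extend([kind] * dur)

    at_colony = True
    while len(labels) < n_sec:
        if at_colony or trip_h == 0:
            emit("rest_land", draw_dwell(rng, dw["rest_land"]))
            at_colony = False
            if trip_h == 0:
                at_colony = True  # stay ashore forever
            continue
        # one foraging trip: alternate flight and surface-rest phases,
        # closing with a flight phase (the homeward commute) so the bird is
        # back inside the colony when the trip ends
        trip_len = draw_dwell(rng, trip_h * 3600.0)
        trip_end = len(labels) + trip_len

        def emit_flight_phase(limit: int) -> None:
            nonlocal n_plunge
            phase_end = len(labels) + draw_dwell(rng, flight_bout_s)
            flap = True
            while len(labels) < min(phase_end, limit, n_sec):
                emit("flapping" if flap else "gliding",
                     draw_dwell(rng, dw["flapping" if flap else "gliding"]))
                flap = not flap
                if rng.random() < p_plunge:
                    emit("plunge_dive", draw_dwell(rng, dw["plunge_dive"]))
                    n_plunge += 1

        flying = True
        while len(labels) < min(trip_end, n_sec):
            if flying:
                emit_flight_phase(trip_end)
            else:
                dur = draw_dwell(rng, dw["rest_sea"])
                n_dives = rng.poisson(duck_per_rest_h * dur / 3600.0)
                if n_dives == 0:
                    emit("rest_sea", dur)
                else:
                    pieces = np.sort(rng.integers(1, max(2, dur), size=n_dives))
                    prev = 0
                    for cut in pieces:
                        emit("rest_sea", int(cut) - prev)
                        emit("duck_dive", draw_dwell(rng, dw["duck_dive"]))
                        n_duck += 1
                        prev = int(cut)
                    emit("rest_sea", dur - prev)
            flying = not flying
        if flying and len(labels) < n_sec:
            # trip ran out during a rest phase: fly home
            emit_flight_phase(n_sec)
        at_colony = True

    lab = np.array(labels[:n_sec], dtype=object)
    time = config.start_time + np.arange(n_sec) * np.timedelta64(1, "s")
    eth = Ethogram(time, lab)
    truth = TruthRecord(bird_id)
    truth.true_T_h = {b: float((lab == b).sum()) / 3600.0 for b in BEHAVIOURS}
    truth.true_EE_kj = float(
        sum(config.true_coefficients[b] * truth.true_T_h[b] for b in BEHAVIOURS)
    )
    truth.n_plunge, truth.n_duck = n_plunge, n_duck
    return eth, truth


def simulate_accel(ethogram: Ethogram, config: SimConfig,
                   rng: np.random.Generator | None = None) -> AccelTrace:
    """25 Hz tri-axial trace matching the ethogram.

    Per behaviour the heave axis carries a sinusoid at the configured
    dominant frequency (continuous phase within a bout) on top of the
    gravity-consistent static orientation; dives are high-amplitude
    bursts.  Independent Gaussian noise on every axis.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    per = int(round(config.sampling_rate))
    lab = ethogram.behaviour
    n_sec = len(lab)
    n = n_sec * per
    x = np.empty(n)
    y = np.empty(n)
    z = np.empty(n)
    # iterate over behaviour bouts for phase-continuous waveforms
    change = np.nonzero(lab[1:] != lab[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n_sec]))
    for a, b in zip(starts, ends):
        freq, amp, orient = config.behaviour_accel[lab[a]]
        m = (b - a) * per
        t_rel = np.arange(m) / config.sampling_rate
        phase = rng.uniform(0, 2 * np.pi)
        sl = slice(a * per, b * per)
        x[sl] = orient[0]
        y[sl] = orient[1]
        z[sl] = orient[2] + amp * np.sin(2 * np.pi * freq * t_rel + phase)
    if config.vedba_noise_sd > 0:
        x += rng.normal(0.0, config.vedba_noise_sd, n)
        y += rng.normal(0.0, config.vedba_noise_sd, n)
        z += rng.normal(0.0, config.vedba_noise_sd, n)
    time = ethogram.time[0] + (np.arange(n) * (1e9 / config.sampling_rate)).astype(
        "timedelta64[ns]"
    )
    return AccelTrace(time, x, y, z, config.sampling_rate)


_FLIGHT = ("flapping", "gliding")


def simulate_gps(ethogram: Ethogram, config: SimConfig,
                 rng: np.random.Generator | None = None,
                 truth: TruthRecord | None = None) -> pd.DataFrame:
    """2-min GPS fixes consistent with the ethogram.

    The bird sits at the colony during rest_land, and on a trip moves along
    a random radial bearing at trip speed whenever flying (out for the
    first half of the trip's flight time, back for the second), drifting
    on the surface otherwise.  Records the true path length in the truth
    record when given.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lab = ethogram.behaviour
    n_sec = len(lab)
    lat0, lon0 = config.colony_latlon
    deg_per_km_lat = 1.0 / 111.195
    deg_per_km_lon = deg_per_km_lat / np.cos(np.deg2rad(lat0))

    at_sea = lab != "rest_land"
    # trip boundaries
    change = np.nonzero(at_sea[1:] != at_sea[:-1])[0] + 1
    bounds = np.concatenate(([0], change, [n_sec]))
    along_km = np.zeros(n_sec)  # signed distance from colony along the bearing
    bearing = np.zeros(n_sec)
    total_path = 0.0
    v_kms = config.trip_speed_kmh / 3600.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        if not at_sea[a]:
            continue
        theta = rng.uniform(0, 2 * np.pi)
        bearing[a:b] = theta
        flying = np.isin(lab[a:b], _FLIGHT)
        step = np.where(flying, v_kms, 0.0)
        cum_flight = np.cumsum(step)
        half = cum_flight[-1] / 2.0
        signed = np.where(cum_flight <= half, cum_flight, 2 * half - cum_flight)
        along_km[a:b] = signed
        total_path += float(cum_flight[-1])
    if truth is not None:
        truth.true_trip_distance_km = total_path

    idx = np.arange(0, n_sec, 120)
    d = along_km[idx]
    th = bearing[idx]
    lat = lat0 + d * np.cos(th) * deg_per_km_lat
    lon = lon0 + d * np.sin(th) * deg_per_km_lon
    if config.gps_noise_km > 0:
        lat = lat + rng.normal(0, config.gps_noise_km * deg_per_km_lat, len(idx))
        lon = lon + rng.normal(0, config.gps_noise_km * deg_per_km_lon, len(idx))
    return pd.DataFrame({"time": ethogram.time[idx], "lat": lat, "lon": lon})


def simulate_morphometrics(config: SimConfig, rng: np.random.Generator
                           ) -> tuple[float, float]:
    """(body mass kg, tarsus mm) for one bird."""
    mass = float(np.clip(rng.normal(config.body_mass_mean_kg, config.body_mass_sd_kg), 1.8, 3.6))
    tarsus = float(rng.normal(config.tarsus_mean_mm, config.tarsus_sd_mm))
    return mass, tarsus


def simulate_isotopes(
    truth: TruthRecord,
    body_mass_kg: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    elapsed_d: float | None = None,
) -> dlw_mod.IsotopeRecord:
    """Invert the single-pool DLW model for a bird with known true EE.

    Fixes the water turnover k_d, derives the true CO2 rate from the true
    energy budget and the configured energy equivalent, solves for k_o,
    and emits background / post-equilibration / final enrichments following
    exponential washout plus Gaussian measurement noise.
    """
    if truth.true_EE_kj <= 0:
        raise ValueError("true EE must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if elapsed_d is None:
        elapsed_d = config.deployment_h / 24.0
    n_mol = config.tbw_fraction * body_mass_kg * 1000.0 / dlw_mod.MOLAR_MASS_WATER_G
    k_d = config.k_d_per_day
    rco2_L_day = truth.true_EE_kj / (config.energy_equiv_kj_per_L * elapsed_d) if elapsed_d > 0 else 0.0
    rco2_mol_day = rco2_L_day / dlw_mod.LITRES_PER_MOL_GAS
    if elapsed_d > 0:
        k_o = k_d + 2.078 * (rco2_mol_day + 0.0062 * k_d * n_mol) / n_mol
        if k_o <= k_d:
            raise ValueError("parameters imply k_o <= k_d")
    else:
        k_o = k_d
    dose_mol = config.dose_g / dlw_mod.MOLAR_MASS_WATER_G

    def plateau(inj, bg):
        return (dose_mol * inj + n_mol * bg) / (n_mol + dose_mol)

    e_eq_o = plateau(config.inj_O_ppm, config.bg_O_ppm)
    e_eq_h = plateau(config.inj_H_ppm, config.bg_H_ppm)
    e_fin_o = config.bg_O_ppm + (e_eq_o - config.bg_O_ppm) * np.exp(-k_o * elapsed_d)
    e_fin_h = config.bg_H_ppm + (e_eq_h - config.bg_H_ppm) * np.exp(-k_d * elapsed_d)
    if config.isotope_noise_sd > 0:
        e_eq_o, e_eq_h, e_fin_o, e_fin_h = (
            v + rng.normal(0.0, config.isotope_noise_sd)
            for v in (e_eq_o, e_eq_h, e_fin_o, e_fin_h)
        )
    truth.true_rco2_L_h = rco2_L_day / 24.0
    truth.true_k_d, truth.true_k_o = k_d, k_o
    t_eq = config.start_time
    t_fin = t_eq + np.timedelta64(int(round(elapsed_d * 86400)), "s")
    return dlw_mod.IsotopeRecord(
        bird_id=truth.bird_id,
        E_bg_O=config.bg_O_ppm, E_bg_H=config.bg_H_ppm,
        E_eq_O=float(e_eq_o), E_eq_H=float(e_eq_h),
        E_fin_O=float(e_fin_o), E_fin_H=float(e_fin_h),
        t_eq=t_eq, t_fin=t_fin,
        dose_g=config.dose_g, inj_O=config.inj_O_ppm, inj_H=config.inj_H_ppm,
        mass_initial=body_mass_kg, mass_final=body_mass_kg,
    )
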