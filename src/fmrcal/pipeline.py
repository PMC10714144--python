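"""End-to-end drivers: synthetic cohort -> energy table -> calibrations.

These functions glue the stage modules together exactly as the analysis
scripts and the acceptance checks use them, so every reported number comes
from the same code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import accel as accel_mod
from . import activity as activity_mod
from . import behaviour as behaviour_mod
from . import calibration as calibration_mod
from . import dlw as dlw_mod
from . import solar, synthetic, trips as trips_mod
from .behaviour import BEHAVIOURS

__all__ = [
    "BirdResult",
    "CohortResult",
    "process_vedba",
    "classify_deployment",
    "classification_accuracy",
    "simulate_bird",
    "run_cohort",
    "coefficient_recovery_mc",
    "TOTAL_CANDIDATES",
    "AT_SEA_CANDIDATES",
]

#: stepwise candidate covariates for the whole-period model
TOTAL_CANDIDATES = ("TD", "dive_rate", "mass", "prop_at_sea", "tarsus")
#: for the at-sea model the night-at-sea proportion replaces prop_at_sea
AT_SEA_CANDIDATES = ("TD", "dive_rate", "mass", "NT", "tarsus")


@dataclass
class BirdResult:
    bird_id: str
    ethogram: behaviour_mod.Ethogram
    budget: behaviour_mod.ActivityBudget
    truth: synthetic.TruthRecord
    dlw: dlw_mod.DlwResult
    vedba_mean_T: float
    vedba_mean_S: float
    trip_summary: trips_mod.TripSummary
    t_land_day_h: float
    t_land_night_h: float
    nt: float
    mass_kg: float
    tarsus_mm: float


@dataclass
class CohortResult:
    birds: list[BirdResult]
    energy: pd.DataFrame
    coeffs: activity_mod.ActivityCoefficients
    activity_table: pd.DataFrame
    fits: dict[str, calibration_mod.RegressionFit] = field(default_factory=dict)
    stepwise_total: calibration_mod.ModelSearchResult | None = None
    stepwise_total_fit: calibration_mod.RegressionFit | None = None
    stepwise_at_sea: calibration_mod.ModelSearchResult | None = None
    stepwise_at_sea_fit: calibration_mod.RegressionFit | None = None


def process_vedba(trace: accel_mod.AccelTrace, window_s: float = 2.0):
    """Static/dynamic split -> per-sample VeDBA -> per-second means."""
    _static, dynamic = accel_mod.split_static_dynamic(trace, window_s)
    series = accel_mod.compute_vedba(dynamic)
    t1s, v1s = accel_mod.vedba_per_second(series)
    return dynamic, series, t1s, v1s


def classify_deployment(
    trace: accel_mod.AccelTrace,
    gps: pd.DataFrame,
    colony_latlon: tuple[float, float],
    seed: int = 0,
    window_s: float = 2.0,
    k: int = 12,
    colony_radius_km: float = 0.5,
    glide_speed_threshold_kmh: float = 10.0,
    vmax_kmh: float = 85.0,
) -> behaviour_mod.Ethogram:
    """Full unsupervised classification of one deployment."""
    dynamic, _series, t1s, v1s = process_vedba(trace, window_s)
    frames = behaviour_mod.wavelet_frames(dynamic.z, trace.rate, time=trace.time)
    clusters = behaviour_mod.cluster_frames(frames, k=k, seed=seed)
    provisional, _mapping = behaviour_mod.assign_behaviours(clusters, frames)
    fixes = trips_mod.speed_filter(gps, vmax_kmh)
    t0, t1 = fixes["time"].iloc[0], fixes["time"].iloc[-1]
    uncovered = (frames.time < np.datetime64(t0)) | (frames.time > np.datetime64(t1))
    if uncovered.any():
        warnings.warn(
            f"{int(uncovered.sum())} s of accelerometry outside GPS coverage; "
            "speed/location rules use the nearest fix there",
            stacklevel=2,
        )
    speed = trips_mod.interp_speed_1s(fixes, frames.time)
    on_land = trips_mod.on_land_mask_1s(fixes, frames.time, colony_latlon, colony_radius_km)
    ruled = behaviour_mod.apply_rules(provisional, speed, on_land, glide_speed_threshold_kmh)
    final, _np_, _nd = behaviour_mod.classify_dives(ruled)
    n = min(len(final), len(v1s))
    return behaviour_mod.Ethogram(frames.time[:n], final[:n], v1s[:n])


def classification_accuracy(
    config: synthetic.SimConfig, bird_id: str = "acc", seed: int = 0
) -> tuple[float, pd.DataFrame]:
    """Per-second agreement between classified and true ethograms.

    Returns (accuracy, confusion matrix with true behaviours as rows).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    eth_true, truth = synthetic.simulate_ethogram(config, bird_id, rng)
    trace = synthetic.simulate_accel(eth_true, config, rng)
    gps = synthetic.simulate_gps(eth_true, config, rng, truth)
    eth_hat = classify_deployment(trace, gps, config.colony_latlon, seed=seed)
    n = min(len(eth_true), len(eth_hat))
    a = eth_true.behaviour[:n]
    b = eth_hat.behaviour[:n]
    acc = float(np.mean(a == b))
    conf = pd.crosstab(
        pd.Series(a, name="true"), pd.Series(b, name="classified")
    ).reindex(index=BEHAVIOURS, columns=BEHAVIOURS, fill_value=0)
    return acc, conf


def _label_intervals(eth: behaviour_mod.Ethogram, on_land: np.ndarray) -> tuple[list, list]:
    """Maximal (start, end) runs of land and sea seconds as datetime pairs."""
    t = eth.time
    land_iv, sea_iv = [], []
    change = np.nonzero(on_land[1:] != on_land[:-1])[0] + 1
    bounds = np.concatenate(([0], change, [len(on_land)]))
    one_s = np.timedelta64(1, "s")
    for a, b in zip(bounds[:-1], bounds[1:]):
        iv = (t[a], t[b - 1] + one_s)
        (land_iv if on_land[a] else sea_iv).append(iv)
    return land_iv, sea_iv


def simulate_bird(
    config: synthetic.SimConfig,
    bird_id: str,
    rng: np.random.Generator,
    budgets_from_truth_labels: bool = True,
    window_s: float = 2.0,
) -> BirdResult:
    """Generate and process one bird through every pipeline stage.

    Behaviour budgets use the true labels when
    ``budgets_from_truth_labels`` (the classifier's per-second accuracy is
    validated separately); the VeDBA attached to them is always the
    *measured* VeDBA from the processed trace.
    """
    eth, truth = synthetic.simulate_ethogram(config, bird_id, rng)
    trace = synthetic.simulate_accel(eth, config, rng)
    gps = synthetic.simulate_gps(eth, config, rng, truth)
    mass, tarsus = synthetic.simulate_morphometrics(config, rng)
    iso = synthetic.simulate_isotopes(truth, mass, config, rng)

    _dyn, series, _t1s, v1s = process_vedba(trace, window_s)
    n = min(len(eth), len(v1s))
    eth = behaviour_mod.Ethogram(eth.time[:n], eth.behaviour[:n], v1s[:n])
    bud = behaviour_mod.budget(eth)

    vedba_mean_T = float(np.mean(v1s[:n]))
    at_sea_mask = eth.behaviour != "rest_land"
    vedba_mean_S = float(np.mean(v1s[:n][at_sea_mask])) if at_sea_mask.any() else float("nan")

    fixes = trips_mod.speed_filter(gps, 85.0)
    tsum = trips_mod.segment_trips(fixes, config.colony_latlon, 0.5)

    land_iv, sea_iv = _label_intervals(eth, ~at_sea_mask)
    lat, lon = config.colony_latlon
    t_land_day, t_land_night = solar.day_night_split(land_iv, lat, lon)
    t_sea_day, t_sea_night = solar.day_night_split(sea_iv, lat, lon)
    sea_total = t_sea_day + t_sea_night
    nt = t_sea_night / sea_total if sea_total > 0 else float("nan")

    res = dlw_mod.process_bird(iso, config.energy_equiv_kj_per_L)
    return BirdResult(
        bird_id, eth, bud, truth, res, vedba_mean_T, vedba_mean_S,
        tsum, t_land_day, t_land_night, nt, mass, tarsus,
    )


def run_cohort(
    config: synthetic.SimConfig,
    seed: int | None = None,
    land_constants_kj_h: tuple[float, float] | None = None,
    basis: str = "time",
) -> CohortResult:
    """Simulate and analyse a full cohort.

    Builds the per-bird energy table, fits the activity coefficients,
    predicts EE, partitions at-sea energy (S1 always; S2 when day/night
    land rates are supplied), and runs the calibration and stepwise
    models.
    """
    if seed is None:
        seed = config.seed
    birds: list[BirdResult] = []
    for i in range(config.n_birds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        birds.append(simulate_bird(config, f"bird{i:02d}", rng))

    budgets = [b.budget for b in birds]
    ee = np.array([b.dlw.DLW_EE_kj for b in birds])
    coeffs = activity_mod.fit_activity_coefficients(ee, budgets, basis=basis)

    rows = []
    for b in birds:
        pred_ee, pred_dee = activity_mod.predict_ee(coeffs, b.budget, b.dlw.elapsed_d)
        ee_s1, dee_s1 = activity_mod.at_sea_s1(b.dlw.DLW_EE_kj, coeffs, b.budget)
        row = {
            "bird_id": b.bird_id,
            "DLW_EE": b.dlw.DLW_EE_kj,
            "DLW_DEE": b.dlw.DLW_DEE_kj_day,
            "Pred_EE": pred_ee,
            "Pred_DEE": pred_dee,
            "DLW_EE_S1": ee_s1,
            "DLW_DEE_S1": dee_s1,
            "VeDBA_mean_T": b.vedba_mean_T,
            "VeDBA_mean_S": b.vedba_mean_S,
            "TD": b.trip_summary.total_distance_km,
            "NT": b.nt,
            "mass": b.mass_kg,
            "tarsus": b.tarsus_mm,
            "dive_rate": b.budget.dive_rate_per_h,
            "prop_at_sea": b.budget.time_at_sea_h / b.budget.total_h,
            "T_land_day": b.t_land_day_h,
            "T_land_night": b.t_land_night_h,
            "true_EE": b.truth.true_EE_kj,
        }
        if land_constants_kj_h is not None:
            c_day, c_night = land_constants_kj_h
            ee_s2, dee_s2, flagged = activity_mod.at_sea_s2(
                b.dlw.DLW_EE_kj, b.t_land_day_h, b.t_land_night_h,
                c_day, c_night, b.budget.time_at_sea_h,
            )
            row.update({"DLW_EE_S2": ee_s2, "DLW_DEE_S2": dee_s2, "s2_flagged": flagged})
        rows.append(row)
    energy = pd.DataFrame(rows).set_index("bird_id")

    result = CohortResult(
        birds=birds,
        energy=energy,
        coeffs=coeffs,
        activity_table=activity_mod.activity_fit_table(coeffs, budgets),
    )
    result.fits = calibration_mod.calibrate_total(energy)
    if land_constants_kj_h is not None:
        result.fits.update(calibration_mod.calibrate_at_sea(energy))
    else:
        result.fits["s1_vs_vedba_s"] = calibration_mod.ols(
            energy["DLW_DEE_S1"].to_numpy(), energy[["VeDBA_mean_S"]], "DLW_DEE_S1"
        )
    result.stepwise_total, result.stepwise_total_fit = calibration_mod.stepwise(
        energy, "DLW_DEE", base=("VeDBA_mean_T",), candidates=TOTAL_CANDIDATES
    )
    result.stepwise_at_sea, result.stepwise_at_sea_fit = calibration_mod.stepwise(
        energy, "DLW_DEE_S1", base=("VeDBA_mean_S",), candidates=AT_SEA_CANDIDATES
    )
    return result


def coefficient_recovery_mc(
    n_reps: int = 500,
    n_birds: int = 15,
    ee_noise_cv: float = 0.05,
    deployment_h: float = 74.0,
    seed: int = 0,
    coefficients: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Monte-Carlo coverage of the activity-coefficient estimator.

    Each replicate draws per-bird activity budgets (Dirichlet around the
    study's mean activity mix), forms EE = sum C_i T_i with multiplicative
    Gaussian noise, refits the no-intercept model and checks whether each
    true C_i lies within 2 SE of its estimate.  Returns per-behaviour
    coverage over replicates.
    """
    if coefficients is None:
        coefficients = synthetic._default_coefficients()
    mean_mix = np.array([0.117, 0.046, 0.347, 0.476, 0.009, 0.005])
    mean_mix = mean_mix / mean_mix.sum()
    conc = mean_mix * 60.0
    c_true = np.array([coefficients[b] for b in BEHAVIOURS])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    hits = np.zeros(len(BEHAVIOURS))
    for _ in range(n_reps):
        T = rng.dirichlet(conc, size=n_birds) * deployment_h
        ee = T @ c_true
        ee = ee * (1.0 + rng.normal(0.0, ee_noise_cv, n_birds))
        coef, _, _, _ = np.linalg.lstsq(T, ee, rcond=None)
        resid = ee - T @ coef
        dof = n_birds - T.shape[1]
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(T.T @ T)
        se = np.sqrt(np.diag(cov))
        hits += (np.abs(coef - c_true) <= 2.0 * se).astype(float)
    return pd.DataFrame(
        {"behaviour": BEHAVIOURS, "coverage": hits / n_reps}
    ).set_index("behaviour")
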