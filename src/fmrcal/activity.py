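"""Activity-specific energy coefficients and at-sea energy partitioning.

The additive time-activity energy model treats a bird's total energy
expenditure over the sampling period as

    EE = sum_i C_i * T_i

over the six behaviours (resting on land, resting at sea, flapping flight,
gliding flight, plunge diving, duck diving), with C_i the energy rate of
behaviour i (kJ/h) and T_i the time spent in it (h).  The coefficients are
estimated by no-intercept multiple least squares of DLW-measured EE on the
per-bird activity predictors; a bird spending zero time in every behaviour
must expend zero energy, which is what forces the origin through zero.

Two predictor bases are supported: time in hours (default; the model's
units close only then) and activity-specific VeDBA sums.

At-sea energy is obtained by subtracting land costs from the DLW total in
two ways: S1 uses the fitted land coefficient (C_land * T_land); S2 uses
externally published day/night on-land rates, which must be supplied
explicitly (no defaults exist in this package).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .behaviour import BEHAVIOURS, ActivityBudget

__all__ = [
    "ActivityCoefficients",
    "fit_activity_coefficients",
    "predict_ee",
    "at_sea_s1",
    "at_sea_s2",
    "activity_fit_table",
    "budget_matrix",
]


@dataclass
class ActivityCoefficients:
    """Fitted energy rates per behaviour with diagnostics."""

    C: dict[str, float]  # kJ per predictor unit (kJ/h under the time basis)
    se: dict[str, float]
    r_squared: float  # uncentred R^2 (no-intercept model)
    basis: str  # "time" or "vedba_sum"
    n_birds: int
    dropped: tuple[str, ...] = ()


def budget_matrix(budgets: list[ActivityBudget], basis: str = "time") -> pd.DataFrame:
    """Per-bird design matrix of activity predictors (one column per behaviour)."""
    if basis == "time":
        rows = [{b: bud.T_h[b] for b in BEHAVIOURS} for bud in budgets]
    elif basis == "vedba_sum":
        rows = [{b: bud.vedba_sum[b] for b in BEHAVIOURS} for bud in budgets]
    else:
        raise ValueError("basis must be 'time' or 'vedba_sum'")
    return pd.DataFrame(rows, columns=list(BEHAVIOURS))


def fit_activity_coefficients(
    ee_kj: np.ndarray,
    budgets: list[ActivityBudget] | pd.DataFrame,
    basis: str = "time",
) -> ActivityCoefficients:
    """No-intercept least squares of DLW EE on activity predictors.

    Requires more birds than coefficients.  Behaviours absent in every bird
    make the design rank-deficient; those terms are dropped with a warning
    and reported in ``dropped``.
    """
    X = budgets if isinstance(budgets, pd.DataFrame) else budget_matrix(budgets, basis)
    y = np.asarray(ee_kj, dtype=float)
    if len(y) != len(X):
        raise ValueError("EE vector and budget set differ in length")
    if len(y) <= X.shape[1]:
        raise ValueError(
            f"need more birds ({len(y)}) than coefficients ({X.shape[1]})"
        )
    zero = [c for c in X.columns if np.allclose(X[c], 0.0)]
    if zero:
        warnings.warn(f"behaviours absent in all birds dropped from fit: {zero}", stacklevel=2)
    keep = [c for c in X.columns if c not in zero]
    fit = sm.OLS(y, X[keep]).fit()
    C = {b: float(fit.params[b]) for b in keep}
    se = {b: float(fit.bse[b]) for b in keep}
    for b in zero:
        C[b] = float("nan")
        se[b] = float("nan")
    return ActivityCoefficients(C, se, float(fit.rsquared), basis, len(y), tuple(zero))


def predict_ee(
    coeffs: ActivityCoefficients,
    budget: ActivityBudget,
    elapsed_d: float | None = None,
) -> tuple[float, float]:
    """(Pred_EE kJ, Pred_DEE kJ/day) for one bird from the fitted rates."""
    pred = 0.0
    for b in BEHAVIOURS:
        c = coeffs.C.get(b, float("nan"))
        x = budget.T_h[b] if coeffs.basis == "time" else budget.vedba_sum[b]
        if np.isnan(c):
            if x > 0:
                raise ValueError(f"budget has time in dropped behaviour {b}")
            continue
        pred += c * x
    if elapsed_d is None:
        elapsed_d = budget.total_h / 24.0
    dee = pred / elapsed_d if elapsed_d > 0 else float("nan")
    return pred, dee


def at_sea_s1(
    dlw_ee_kj: float,
    coeffs: ActivityCoefficients,
    budget: ActivityBudget,
) -> tuple[float, float]:
    """At-sea energy by subtracting the fitted land cost (method S1).

    EE_S1 = DLW_EE - C_land * T_land; the daily rate divides by time at
    sea.  Conservation holds by construction: EE_S1 plus the estimated
    land energy equals the DLW total exactly.
    """
    c_land = coeffs.C.get("rest_land")
    if c_land is None or np.isnan(c_land):
        raise ValueError("no land coefficient available")
    x_land = budget.T_h["rest_land"] if coeffs.basis == "time" else budget.vedba_sum["rest_land"]
    ee_s1 = dlw_ee_kj - c_land * x_land
    sea_d = budget.time_at_sea_h / 24.0
    if sea_d <= 0:
        raise ValueError("bird never went to sea: at-sea rate undefined")
    return ee_s1, ee_s1 / sea_d


def at_sea_s2(
    dlw_ee_kj: float,
    t_land_day_h: float,
    t_land_night_h: float,
    c_day_kj_h: float,
    c_night_kj_h: float,
    time_at_sea_h: float,
) -> tuple[float, float, bool]:
    """At-sea energy using published day/night on-land rates (method S2).

    Land energy = c_day * T_land_day + c_night * T_land_night is subtracted
    from the DLW total.  The published constants must be supplied by the
    caller; the source literature's values are deployment-specific and this
    package deliberately ships none.  Returns (EE_S2, DEE_S2, flagged);
    a bird whose estimated land energy reaches its DLW total is flagged for
    exclusion from downstream regressions.
    """
    if c_day_kj_h is None or c_night_kj_h is None:
        raise ValueError("day and night on-land rates must be supplied explicitly")
    land = c_day_kj_h * t_land_day_h + c_night_kj_h * t_land_night_h
    ee_s2 = dlw_ee_kj - land
    flagged = land >= dlw_ee_kj
    if time_at_sea_h <= 0:
        raise ValueError("bird never went to sea: at-sea rate undefined")
    return ee_s2, ee_s2 / (time_at_sea_h / 24.0), bool(flagged)


def activity_fit_table(
    coeffs: ActivityCoefficients,
    budgets: list[ActivityBudget],
) -> pd.DataFrame:
    """Per-behaviour regression of estimated activity energy on VeDBA sums.

    For each behaviour, the per-bird estimated energy C_i * T_i is
    regressed (with intercept) against the per-bird activity-specific
    VeDBA sum; rows report slope, R^2, F and p.  Behaviours with zero
    variance across birds are omitted.
    """
    rows = []
    for b in BEHAVIOURS:
        c = coeffs.C.get(b, float("nan"))
        if np.isnan(c):
            continue
        x = np.array([bud.vedba_sum[b] for bud in budgets])
        energy = np.array(
            [c * (bud.T_h[b] if coeffs.basis == "time" else bud.vedba_sum[b]) for bud in budgets]
        )
        if np.allclose(np.var(x), 0.0) or np.allclose(np.var(energy), 0.0):
            continue
        fit = sm.OLS(energy, sm.add_constant(x)).fit()
        rows.append(
            {
                "behaviour": b,
                "slope": float(fit.params[1]),
                "intercept": float(fit.params[0]),
                "r_squared": float(fit.rsquared),
                "F": float(fit.fvalue),
                "p": float(fit.f_pvalue),
                "n": int(fit.nobs),
            }
        )
    return pd.DataFrame(rows).set_index("behaviour")
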