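"""Calibration regressions between DLW energy expenditure and VeDBA.

Ordinary least squares with intercept relates the DLW-derived rates to the
accelerometry proxies; a bidirectional (forward + backward) stepwise search
on AIC explores movement and morphometric covariates on top of the
VeDBA-only base model.  The VeDBA term is protected by default — every
calibration model of interest contains it — but can be released.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionFit",
    "ModelSearchResult",
    "ols",
    "calibrate_total",
    "calibrate_at_sea",
    "stepwise",
]


@dataclass
class RegressionFit:
    """One OLS fit: coefficients, R^2, F with df, p."""

    response: str
    predictors: tuple[str, ...]
    coef: dict[str, float]
    se: dict[str, float]
    r_squared: float
    f_stat: float
    df: tuple[int, int]  # (k, n - k - 1)
    p_value: float
    n: int
    aic: float

    def summary_row(self) -> dict:
        return {
            "response": self.response,
            "predictors": " + ".join(self.predictors) or "1",
            "r_squared": self.r_squared,
            "F": self.f_stat,
            "df_model": self.df[0],
            "df_resid": self.df[1],
            "p": self.p_value,
            "n": self.n,
        }


@dataclass
class ModelSearchResult:
    """Stepwise-search bookkeeping: candidates, selection and AIC trace."""

    candidates: tuple[str, ...]
    selected: tuple[str, ...]
    trace: list[dict] = field(default_factory=list)


def ols(y: np.ndarray, X: pd.DataFrame, response: str = "y") -> RegressionFit:
    """Least squares with intercept; R^2 = 1 - SSE/SST.

    Raises for a constant response (R^2 undefined) or too few
    observations.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X)
    n, k = len(y), X.shape[1]
    if n <= k + 1:
        raise ValueError(f"need n > predictors + 1 (n={n}, k={k})")
    if np.allclose(np.var(y), 0.0):
        raise ValueError("constant response: R^2 undefined")
    fit = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    names = tuple(X.columns)
    coef = {c: float(fit.params[c]) for c in fit.params.index}
    se = {c: float(fit.bse[c]) for c in fit.bse.index}
    if k > 0:
        fstat, pval = float(fit.fvalue), float(fit.f_pvalue)
    else:
        fstat, pval = float("nan"), float("nan")
    return RegressionFit(
        response=response,
        predictors=names,
        coef=coef,
        se=se,
        r_squared=float(fit.rsquared),
        f_stat=fstat,
        df=(int(fit.df_model), int(fit.df_resid)),
        p_value=pval,
        n=n,
        aic=float(fit.aic),
    )


def calibrate_total(energy: pd.DataFrame) -> dict[str, RegressionFit]:
    """Whole-sampling-period calibrations.

    Fits DLW_DEE ~ VeDBA_mean_T (the simple correlative calibration),
    DLW_EE ~ Pred_EE and DLW_DEE ~ Pred_DEE (the activity-specific
    predictions, total and daily).  Requires at least four birds.
    """
    if len(energy) < 4:
        raise ValueError("need at least 4 birds")
    out = {}
    out["dee_vs_vedba"] = ols(
        energy["DLW_DEE"].to_numpy(), energy[["VeDBA_mean_T"]], "DLW_DEE"
    )
    out["ee_vs_pred_ee"] = ols(
        energy["DLW_EE"].to_numpy(), energy[["Pred_EE"]], "DLW_EE"
    )
    out["dee_vs_pred_dee"] = ols(
        energy["DLW_DEE"].to_numpy(), energy[["Pred_DEE"]], "DLW_DEE"
    )
    return out


def calibrate_at_sea(energy: pd.DataFrame) -> dict[str, RegressionFit]:
    """At-sea calibrations: DLW_DEE_S1 and _S2 against VeDBA_mean_S.

    Birds flagged by the S2 partition (published land costs exceeding the
    DLW total) are excluded listwise from the S2 regression only.
    """
    out = {}
    out["s1_vs_vedba_s"] = ols(
        energy["DLW_DEE_S1"].to_numpy(), energy[["VeDBA_mean_S"]], "DLW_DEE_S1"
    )
    sub = energy
    if "s2_flagged" in energy.columns:
        sub = energy[~energy["s2_flagged"].astype(bool)]
    out["s2_vs_vedba_s"] = ols(
        sub["DLW_DEE_S2"].to_numpy(), sub[["VeDBA_mean_S"]], "DLW_DEE_S2"
    )
    return out


def stepwise(
    data: pd.DataFrame,
    response: str,
    base: tuple[str, ...],
    candidates: tuple[str, ...],
    protected: tuple[str, ...] | None = None,
    criterion: str = "aic",
) -> tuple[ModelSearchResult, RegressionFit]:
    """Bidirectional stepwise regression on AIC from the base model.

    At each step every single-term addition from the unused candidates and
    every single-term removal of a non-protected current term is scored;
    the best move is taken while it lowers the criterion.  ``protected``
    defaults to the base terms (the VeDBA term is never dropped).
    """
    if criterion != "aic":
        raise ValueError("only AIC is supported")
    missing = [c for c in (*base, *candidates) if c not in data.columns]
    if missing:
        raise ValueError(f"terms absent from data: {missing}")
    if protected is None:
        protected = tuple(base)
    current = list(base)
    y = data[response].to_numpy()

    def score(terms: list[str]) -> float:
        return ols(y, data[terms], response).aic if terms else ols(y, data[[]], response).aic

    best_aic = score(current)
    trace = [{"action": "start", "terms": tuple(current), "aic": best_aic}]
    while True:
        moves: list[tuple[float, str, str]] = []
        for c in candidates:
            if c not in current:
                moves.append((score(current + [c]), "add", c))
        for c in current:
            if c not in protected:
                moves.append((score([t for t in current if t != c]), "drop", c))
        if not moves:
            break
        aic, action, term = min(moves, key=lambda m: m[0])
        if aic >= best_aic - 1e-9:
            break
        if action == "add":
            current.append(term)
        else:
            current.remove(term)
        best_aic = aic
        trace.append({"action": f"{action} {term}", "terms": tuple(current), "aic": aic})
    final = ols(y, data[current], response)
    return ModelSearchResult(tuple(candidates), tuple(current), trace), final
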