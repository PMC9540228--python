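"""Per-participant daily time-series stage: ARIMA with exogenous regressors.

Daily Simple Score (mean over a training day's blocks) is modelled as a
regression on that day's survey responses (wellbeing, stress, busyness,
mood, sleep hours) with ARMA(p, q) errors on the d-times-differenced series
— the regression-with-ARMA-errors formulation used by auto-ARIMA
forecasting tools.  Model order is chosen by an exhaustive grid search over
p <= 5, d <= 1, q <= 5, scored by the Akaike Information Criterion
AIC = 2k - 2 logL with k counting every free parameter (regression
coefficients, intercept when d = 0, ARMA coefficients, and the innovation
variance).  Ties are broken toward the more parsimonious order (smaller
p + q, then smaller p).  Exogenous significance is judged by asymptotic
z-tests; no multiplicity correction is applied (per-participant alpha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.tsa.statespace.sarimax import SARIMAX

__all__ = [
    "DailySeries",
    "CandidateFit",
    "ARIMAXResult",
    "EXOG_COLUMNS",
    "aggregate_daily",
    "drop_invariant_regressors",
    "fit_arimax",
    "summarize_cohort",
    "MIN_SERIES_LENGTH",
]

EXOG_COLUMNS = ("wellbeing", "stress", "busyness", "mood", "sleep_hours")
MIN_SERIES_LENGTH = 10

_FIT_KWARGS = dict(method="lbfgs", maxiter=15, factr=1e10, disp=0)
_TIE_TOL = 1e-9


@dataclass
class DailySeries:
    participant_id: str
    day_index: np.ndarray          # ordinal training day, 1..D
    y: np.ndarray                  # daily mean Simple Score
    x: pd.DataFrame                # exogenous columns aligned to days
    dropped_regressors: list[str] = field(default_factory=list)
    excluded_days: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class CandidateFit:
    order: tuple[int, int, int]
    aic: float
    loglik: float
    k_params: int
    converged: bool


@dataclass
class ARIMAXResult:
    participant_id: str
    order: Optional[tuple[int, int, int]]
    aic: float
    exog_coefs: pd.DataFrame       # index regressor, cols coef/se/z/pvalue
    ar_coefs: np.ndarray
    ma_coefs: np.ndarray
    converged: bool
    n_obs: int
    dropped_regressors: list[str]
    candidates: list[CandidateFit] = field(default_factory=list)
    failure_reason: Optional[str] = None

    @property
    def fitted(self) -> bool:
        return self.order is not None

    def significant_regressors(self, alpha: float = 0.05) -> list[str]:
        if not self.fitted or self.exog_coefs.empty:
            return []
        sig = self.exog_coefs[self.exog_coefs["pvalue"] < alpha]
        return list(sig.index)


def aggregate_daily(block_log: pd.DataFrame, survey_log: pd.DataFrame,
                    participant_id: Optional[str] = None) -> DailySeries:
    """Collapse a scored block log and a survey log into one daily series.

    y[day] is the mean Simple Score over that day's blocks; x[day] is the
    day's first survey.  A day with blocks but no survey is excluded from
    the series (recorded in ``excluded_days``) with a warning.
    """
    if participant_id is not None:
        block_log = block_log[block_log["participant_id"] == participant_id]
        survey_log = survey_log[survey_log["participant_id"] == participant_id]
    elif "participant_id" in block_log.columns:
        ids = set(block_log["participant_id"].unique())
        if len(ids) > 1:
            raise ValueError("multiple participants in log; pass participant_id")
        participant_id = next(iter(ids))
    if block_log.empty:
        raise ValueError("no blocks for participant")
    if "simple_score" not in block_log.columns:
        raise ValueError("block log must be scored first (simple_score column)")

    daily_y = block_log.groupby("day_index")["simple_score"].mean()
    first_survey = (survey_log.sort_values("day_index")
                    .groupby("day_index").first())

    days = daily_y.index.to_numpy()
    have_survey = np.isin(days, first_survey.index.to_numpy())
    excluded = [int(d) for d in days[~have_survey]]
    if excluded:
        warnings.warn(
            f"participant {participant_id}: {len(excluded)} training day(s) "
            f"without a survey excluded from the daily series", UserWarning)
    days = days[have_survey]
    x = first_survey.loc[days, list(EXOG_COLUMNS)].reset_index(drop=True)
    return DailySeries(
        participant_id=str(participant_id),
        day_index=days.astype(int),
        y=daily_y.loc[days].to_numpy(dtype=float),
        x=x.astype(float),
        excluded_days=excluded,
    )


def drop_invariant_regressors(series: DailySeries) -> DailySeries:
    """Remove exogenous columns with zero sample variance.

    Participants who give the same survey response every day contribute a
    constant column that cannot be estimated; those columns are removed and
    their names recorded.  The day index is always retained.
    """
    keep, dropped = [], list(series.dropped_regressors)
    for col in series.x.columns:
        if series.x[col].nunique(dropna=False) <= 1:
            dropped.append(col)
        else:
            keep.append(col)
    return DailySeries(
        participant_id=series.participant_id,
        day_index=series.day_index,
        y=series.y,
        x=series.x[keep].copy(),
        dropped_regressors=dropped,
        excluded_days=list(series.excluded_days),
    )


def _aic_k(order: tuple[int, int, int], n_exog: int) -> int:
    """Free parameters: ARMA terms + exog + intercept (d=0 only) + variance."""
    p, d, q = order
    return p + q + n_exog + (1 if d == 0 else 0) + 1


def fit_arimax(series: DailySeries, max_p: int = 5, max_d: int = 1,
               max_q: int = 5,
               min_series_length: int = MIN_SERIES_LENGTH) -> ARIMAXResult:
    """Exhaustive AIC selection over the (p, d, q) grid for one participant.

    Every candidate within the bounds is fitted by maximum likelihood;
    candidates whose fit fails or yields a non-finite likelihood are
    skipped.  Returns a fit-failure result (order None) when the series is
    too short or no candidate can be fitted, rather than raising.
    """
    series = drop_invariant_regressors(series)
    n = len(series)
    empty = pd.DataFrame(columns=["coef", "se", "z", "pvalue"])
    if n < min_series_length:
        return ARIMAXResult(series.participant_id, None, float("nan"), empty,
                            np.array([]), np.array([]), False, n,
                            series.dropped_regressors,
                            failure_reason=f"series too short (n={n})")

    exog = series.x if series.x.shape[1] else None  # DataFrame keeps names
    exog_names = list(series.x.columns)
    candidates: list[CandidateFit] = []
    fits: dict[tuple[int, int, int], object] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in range(max_p + 1):
            for d in range(max_d + 1):
                for q in range(max_q + 1):
                    order = (p, d, q)
                    try:
                        model = SARIMAX(series.y, exog=exog, order=order,
                                        trend="c" if d == 0 else "n",
                                        concentrate_scale=True)
                        res = model.fit(**_FIT_KWARGS)
                    except Exception:
                        continue
                    llf = float(res.llf)
                    if not np.isfinite(llf) or not np.all(np.isfinite(res.params)):
                        continue
                    k = _aic_k(order, len(exog_names))
                    candidates.append(CandidateFit(
                        order=order, aic=2.0 * k - 2.0 * llf, loglik=llf,
                        k_params=k,
                        converged=bool(res.mle_retvals.get("converged", False))))
                    fits[order] = res

    if not candidates:
        return ARIMAXResult(series.participant_id, None, float("nan"), empty,
                            np.array([]), np.array([]), False, n,
                            series.dropped_regressors,
                            failure_reason="no candidate model could be fitted")

    best_aic = min(c.aic for c in candidates)
    tied = [c for c in candidates if c.aic <= best_aic + _TIE_TOL]
    winner = min(tied, key=lambda c: (c.order[0] + c.order[2], c.order[0]))
    res = fits[winner.order]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
    names = list(res.model.param_names)
    rows = []
    for name in exog_names:
        i = names.index(name)
        coef, se = params[i], bse[i]
        z = coef / se if se > 0 else float("nan")
        rows.append({"coef": coef, "se": se, "z": z,
                     "pvalue": 2.0 * norm.sf(abs(z)) if np.isfinite(z) else float("nan")})
    exog_table = pd.DataFrame(rows, index=exog_names,
                              columns=["coef", "se", "z", "pvalue"])
    p, d, q = winner.order
    ar = np.array([params[names.index(f"ar.L{i}")] for i in range(1, p + 1)])
    ma = np.array([params[names.index(f"ma.L{i}")] for i in range(1, q + 1)])
    return ARIMAXResult(series.participant_id, winner.order, winner.aic,
                        exog_table, ar, ma, winner.converged, n,
                        series.dropped_regressors, candidates=candidates)


def summarize_cohort(results: list[ARIMAXResult],
                     alpha: float = 0.05) -> dict:
    """Cohort-level report over per-participant ARIMAX fits.

    Counts participants whose performance-over-time is predicted by any
    daily context variable (exogenous p < alpha), per-regressor significance
    counts, the mean/SD of significant coefficients per regressor, and an
    occurrence table of selected (p, d, q) orders.
    """
    if not results:
        raise ValueError("no results to summarize")
    fitted = [r for r in results if r.fitted]
    context_predicted = [r for r in fitted if r.significant_regressors(alpha)]

    per_reg_counts = {name: 0 for name in EXOG_COLUMNS}
    per_reg_coefs: dict[str, list[float]] = {name: [] for name in EXOG_COLUMNS}
    for r in fitted:
        for name in r.significant_regressors(alpha):
            per_reg_counts[name] += 1
            per_reg_coefs[name].append(float(r.exog_coefs.loc[name, "coef"]))

    order_counts: dict[str, int] = {}
    for r in fitted:
        key = "".join(str(v) for v in r.order)
        order_counts[key] = order_counts.get(key, 0) + 1
    model_table = (pd.DataFrame(
        [{"model": k, "ar": int(k[0]), "i": int(k[1]), "ma": int(k[2]),
          "n": v} for k, v in order_counts.items()])
        .sort_values(["ar", "i", "ma"]).reset_index(drop=True))

    coef_stats = {
        name: {"n": per_reg_counts[name],
               "mean_coef": float(np.mean(v)) if v else float("nan"),
               "sd_coef": float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")}
        for name, v in per_reg_coefs.items()
    }
    return {
        "n_participants": len(results),
        "n_fitted": len(fitted),
        "n_unfitted": len(results) - len(fitted),
        "n_context_predicted": len(context_predicted),
        "frac_context_predicted": (len(context_predicted) / len(fitted)
                                   if fitted else float("nan")),
        "n_ar_nonzero": sum(1 for r in fitted if r.order[0] > 0),
        "n_ma_nonzero": sum(1 for r in fitted if r.order[2] > 0),
        "n_differenced": sum(1 for r in fitted if r.order[1] > 0),
        "regressor_stats": coef_stats,
        "model_table": model_table,
    }
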