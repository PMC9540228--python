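"""Group-level statistics: stepwise and hierarchical regressions of learning
rates on cognitive and brain-volume covariates, and age-controlled partial
correlations.

All fits are ordinary least squares (statsmodels) on complete cases
(listwise deletion per analysis).  Stepwise selection alternates forward
entry of the lowest-p candidate with p < alpha_enter and backward removal of
included terms with p > alpha_remove until the model stabilises; ties in
entry p are broken toward the lower column index.  The hierarchical stage
fits two nested models and reports the step-2 R-squared change with an
F-change test.  Partial correlation residualises both variables on the
controls (plus intercept) and correlates the residuals, with
df = n - 2 - #controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionReport",
    "HierarchicalReport",
    "RavltScores",
    "aggregate_ravlt",
    "stepwise_regression",
    "hierarchical_regression",
    "partial_correlation",
    "sample_covariates",
    "COVARIATE_SPECS",
]


@dataclass(frozen=True)
class RavltScores:
    learning_total: float
    interference_cost: float
    delay_cost: float
    recognition_errors: float
    missing: tuple[str, ...] = ()


def aggregate_ravlt(trial_scores: Sequence[Optional[float]],
                    recognition_error_counts: Sequence[Optional[float]],
                    ) -> RavltScores:
    """Aggregate raw word-list recall scores into the four derived measures.

    ``trial_scores`` are the seven recall trials A1..A7 (five learning
    trials, post-interference recall A6, delayed recall A7);
    ``recognition_error_counts`` are the five recognition-error categories
    (source, semantic, phonetic, and the two compound categories).
    Aggregates depending on a missing trial are NaN and flagged.
    """
    if len(trial_scores) != 7:
        raise ValueError("expected seven trial scores A1..A7")
    if len(recognition_error_counts) != 5:
        raise ValueError("expected five recognition error categories")
    a = [float("nan") if v is None else float(v) for v in trial_scores]
    errs = [float("nan") if v is None else float(v)
            for v in recognition_error_counts]
    missing = []

    learning_total = sum(a[:5])
    if math.isnan(learning_total):
        missing.append("learning_total")
    interference_cost = a[4] - a[5]
    if math.isnan(interference_cost):
        missing.append("interference_cost")
    delay_cost = a[5] - a[6]
    if math.isnan(delay_cost):
        missing.append("delay_cost")
    recognition_errors = sum(errs)
    if math.isnan(recognition_errors):
        missing.append("recognition_errors")
    return RavltScores(learning_total, interference_cost, delay_cost,
                       recognition_errors, tuple(missing))


@dataclass
class RegressionReport:
    dependent: str
    terms: pd.DataFrame            # index term, cols beta/t/pvalue
    r2: float
    f_stat: float
    df_model: int
    df_resid: int
    model_pvalue: float
    n_obs: int
    step_history: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return self.terms.drop(index="const", errors="ignore").empty


@dataclass
class HierarchicalReport:
    dependent: str
    step1: RegressionReport
    step2: RegressionReport
    delta_r2: float
    f_change: float
    f_change_pvalue: float
    condition_warning: bool = False


def _complete_cases(y: pd.Series, X: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    data = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    return data["__y__"], data.drop(columns="__y__")


def _ols_report(y: pd.Series, X: pd.DataFrame, dependent: str,
                history: Optional[list[str]] = None) -> RegressionReport:
    fit = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    terms = pd.DataFrame({"beta": fit.params, "t": fit.tvalues,
                          "pvalue": fit.pvalues})
    return RegressionReport(
        dependent=dependent, terms=terms,
        r2=float(fit.rsquared) if X.shape[1] else 0.0,
        f_stat=float(fit.fvalue) if X.shape[1] else float("nan"),
        df_model=int(fit.df_model), df_resid=int(fit.df_resid),
        model_pvalue=float(fit.f_pvalue) if X.shape[1] else float("nan"),
        n_obs=int(fit.nobs), step_history=history or [])


def stepwise_regression(y: pd.Series, candidates: pd.DataFrame,
                        alpha_enter: float = 0.05,
                        alpha_remove: float = 0.05,
                        dependent: str = "y") -> RegressionReport:
    """Bidirectional stepwise OLS until only significant predictors remain.

    Forward step: among excluded candidates, refit with each added and enter
    the one with the smallest p-value if p < alpha_enter (ties broken by the
    lower column index).  Backward step: drop the included term with the
    largest p-value while p > alpha_remove.  Iterates to convergence; an
    empty model (no candidate enters) is a valid report, not an error.
    """
    y, X = _complete_cases(y, candidates)
    if len(y) <= X.shape[1] + 2:
        raise ValueError("too few complete cases for stepwise selection")
    cols = list(X.columns)
    included: list[str] = []
    history: list[str] = []
    while True:
        changed = False
        # forward entry (skipped once the fit is numerically perfect: any
        # further "predictor" would only be fitting floating-point residue)
        saturated = False
        if included:
            cur = sm.OLS(y, sm.add_constant(X[included])).fit()
            saturated = cur.rsquared > 1.0 - 1e-12
        best_p, best_col = None, None
        if not saturated:
            for col in cols:
                if col in included:
                    continue
                fit = sm.OLS(y, sm.add_constant(X[included + [col]])).fit()
                p = float(fit.pvalues[col])
                if p < alpha_enter and (best_p is None or p < best_p - 1e-15):
                    best_p, best_col = p, col
        if best_col is not None:
            included.append(best_col)
            history.append(f"enter {best_col} (p={best_p:.4g})")
            changed = True
        # backward removal
        while included:
            fit = sm.OLS(y, sm.add_constant(X[included])).fit()
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if float(pvals[worst]) > alpha_remove:
                included.remove(worst)
                history.append(f"remove {worst} (p={float(pvals[worst]):.4g})")
                changed = True
            else:
                break
        if not changed:
            break
    return _ols_report(y, X[included], dependent, history)


def hierarchical_regression(y: pd.Series, step1: pd.DataFrame,
                            step2: pd.DataFrame,
                            dependent: str = "y",
                            cond_threshold: float = 1e8) -> HierarchicalReport:
    """Two nested OLS fits with an R-squared-change F test for step 2."""
    X_full = pd.concat([step1, step2], axis=1)
    y, X_full = _complete_cases(y, X_full)
    X1 = X_full[list(step1.columns)]
    rep1 = _ols_report(y, X1, dependent)
    rep2 = _ols_report(y, X_full, dependent)

    m = X_full.shape[1] - X1.shape[1]
    n = len(y)
    df2 = n - X_full.shape[1] - 1
    delta = rep2.r2 - rep1.r2
    if m > 0 and df2 > 0 and rep2.r2 < 1.0:
        f_change = (delta / m) / ((1.0 - rep2.r2) / df2)
        p_change = float(stats.f.sf(f_change, m, df2))
    else:
        f_change, p_change = float("nan"), float("nan")

    design = sm.add_constant(X_full).to_numpy(dtype=float)
    cond = float(np.linalg.cond(design))
    return HierarchicalReport(dependent, rep1, rep2, float(delta),
                              float(f_change), p_change,
                              condition_warning=cond > cond_threshold)


def partial_correlation(x: Sequence[float], y: Sequence[float],
                        controls: Optional[pd.DataFrame] = None,
                        ) -> tuple[float, float, int]:
    """Correlation of x and y after partialling out the controls.

    Residualises both variables on the controls plus an intercept and
    correlates the residuals; with no controls this is the plain Pearson
    correlation.  Returns (r, two-sided p, df) with df = n - 2 - #controls.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None or controls.shape[1] == 0:
        Z = np.ones((len(x), 1))
        k = 0
    else:
        C = np.asarray(controls, dtype=float)
        mask = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
        x, y, C = x[mask], y[mask], C[mask]
        Z = np.column_stack([np.ones(len(x)), C])
        k = C.shape[1]
    n = len(x)
    if n <= k + 3:
        raise ValueError("too few complete cases for partial correlation")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("constant variable after residualization")
    r = float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - k
    r_clipped = max(min(r, 1.0 - 1e-15), -1.0 + 1e-15)
    t = r_clipped * math.sqrt(df / (1.0 - r_clipped ** 2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p, df


# means and SDs of the baseline covariates used by the synthetic cohort
# (age and cognitive scores from the study sample; regional volumes in mm^3
# at typical older-adult magnitudes)
COVARIATE_SPECS: dict[str, tuple[float, float]] = {
    "age": (71.57, 4.23),
    "etiv": (1.5e6, 1.5e5),
    "story_memory": (13.68, 5.52),
    "ravlt_learning_total": (48.51, 12.25),
    "ravlt_interference_cost": (2.12, 1.95),
    "ravlt_delay_cost": (0.27, 1.54),
    "ravlt_recognition_errors": (2.03, 3.0),
    "matrix_reasoning": (16.0, 4.06),
    "visual_puzzles": (12.51, 3.88),
    "criq": (130.66, 34.66),
    "left_ifg": (10600.0, 1200.0),
    "right_ifg": (10400.0, 1200.0),
    "left_sfg": (22000.0, 2500.0),
    "right_sfg": (22000.0, 2500.0),
    "left_mfg": (18000.0, 2200.0),
    "right_mfg": (18000.0, 2200.0),
    "left_acc": (4000.0, 600.0),
    "right_acc": (4000.0, 600.0),
    "left_precentral": (13000.0, 1500.0),
    "right_precentral": (13000.0, 1500.0),
    "left_mtg": (12000.0, 1500.0),
    "right_mtg": (12000.0, 1500.0),
    "left_hippocampus": (3800.0, 450.0),
    "right_hippocampus": (3900.0, 450.0),
    "left_striatum": (9000.0, 1000.0),
    "right_striatum": (9000.0, 1000.0),
}

_VOLUME_KEYS = [k for k in COVARIATE_SPECS
                if k.startswith(("left_", "right_")) or k == "etiv"]
_COGNITIVE_KEYS = ["story_memory", "ravlt_learning_total", "matrix_reasoning",
                   "visual_puzzles", "criq"]


def sample_covariates(n: int, seed: int | np.random.SeedSequence,
                      missing_rate: float = 0.0) -> pd.DataFrame:
    """Synthetic participant covariates with a plausible dependence structure.

    A latent general-cognition factor loads on the cognitive scores, a
    head-size factor on eTIV and all regional volumes, and age enters with a
    negative loading on both — so the fixture exhibits the collinearity
    patterns (volume ~ eTIV, cognition ~ age) that the regression stage must
    cope with.  ``missing_rate`` knocks out cells at random to exercise
    listwise deletion.
    """
    rng = np.random.default_rng(seed)
    age_z = rng.normal(size=n)
    g = -0.3 * age_z + math.sqrt(1 - 0.09) * rng.normal(size=n)
    head = rng.normal(size=n)

    data: dict[str, np.ndarray] = {}
    for name, (mean, sd) in COVARIATE_SPECS.items():
        if name == "age":
            z = age_z
        elif name in _COGNITIVE_KEYS:
            z = 0.55 * g + math.sqrt(1 - 0.55 ** 2) * rng.normal(size=n)
        elif name in ("ravlt_interference_cost", "ravlt_delay_cost",
                      "ravlt_recognition_errors"):
            z = -0.35 * g + math.sqrt(1 - 0.35 ** 2) * rng.normal(size=n)
        elif name in _VOLUME_KEYS:
            z = (0.5 * head - 0.3 * age_z
                 + math.sqrt(1 - 0.25 - 0.09) * rng.normal(size=n))
        else:
            z = rng.normal(size=n)
        data[name] = mean + sd * z
    df = pd.DataFrame(data)
    df.insert(0, "participant_id", [f"p{i + 1:03d}" for i in range(n)])
    if missing_rate > 0:
        cols = [c for c in df.columns if c != "participant_id"]
        mask = rng.random((n, len(cols))) < missing_rate
        df.loc[:, cols] = df[cols].mask(mask)
    return df
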