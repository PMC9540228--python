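"""Difficulty-weighted scoring and learning-rate estimation.

Each block's *Difficulty Level* counts the upward adaptive adjustments in
force (1..72): DL = 6 * epoch + n, where epoch indexes the d' threshold
(0.6 -> 0, 0.8 -> 1, ..., clamped at 11 once the 3.0 cap is reached) and n
is the number of contexts.  *Simple Score* = DL x unscaled accuracy
(hits + correct rejections, 0..80), so its range is 0..5760 with chance at
level 1 equal to 40.

Learning rates come from least-squares curve fits of Simple Score against
the global block index t: a logarithmic model Y = b0 + b1*ln(t) over all
blocks (overall rate) and over the early period, and linear slopes over the
middle and late periods.  Periods partition training time as half-open
intervals of the block's cumulative hours: early [0, 5), middle [5, 10),
late [10, inf).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoredBlock",
    "LearningRates",
    "difficulty_level",
    "simple_score",
    "score_blocks",
    "segment_periods",
    "fit_log_learning",
    "fit_linear_slope",
    "learning_rates",
    "cohort_learning_rates",
    "scored_series_with_log_growth",
    "MIN_BLOCKS_PER_PERIOD",
]

MIN_BLOCKS_PER_PERIOD = 10
PERIOD_BOUNDS_HOURS = (5.0, 10.0)

_DL_GRID_TOL = 1e-6


@dataclass(frozen=True)
class ScoredBlock:
    block_index: int
    difficulty_level: int
    unscaled_accuracy: int
    simple_score: float
    cumulative_hours: float


@dataclass(frozen=True)
class LearningRates:
    participant_id: str
    overall_b0: float
    overall_b1: float
    overall_r2: float
    overall_n: int
    early_b0: float
    early_b1: float
    early_r2: float
    early_n: int
    middle_slope: float
    middle_intercept: float
    middle_r2: float
    middle_n: int
    late_slope: float
    late_intercept: float
    late_r2: float
    late_n: int
    early_fittable: bool
    middle_fittable: bool
    late_fittable: bool


def difficulty_level(dprime_threshold: float, n: int,
                     dprime_start: float = 0.6, dprime_step: float = 0.2,
                     n_max: int = 6) -> int:
    """Ordinal difficulty 1..72 of a block: 6*epoch + n.

    The threshold must sit on the adaptive grid {0.6, 0.8, ..., 3.0}; the
    terminal 3.0 cap is clamped to epoch 11 so DL tops out at 72.
    """
    if not (1 <= n <= n_max):
        raise ValueError(f"n={n} outside 1..{n_max}")
    epoch_f = (dprime_threshold - dprime_start) / dprime_step
    if abs(epoch_f - round(epoch_f)) > _DL_GRID_TOL or epoch_f < -_DL_GRID_TOL:
        raise ValueError(f"dprime_threshold={dprime_threshold} off the adaptive grid")
    # 12 sub-cap epochs (0..11); the terminal cap epoch is clamped to 11
    epoch = min(int(round(epoch_f)), 11)
    return n_max * epoch + n


def simple_score(block: Mapping | object) -> ScoredBlock:
    """Difficulty-weight one block: Simple Score = DL x (hit + cr)."""
    get = (block.__getitem__ if isinstance(block, Mapping)
           else lambda k: getattr(block, k))
    dl = difficulty_level(float(get("dprime_threshold")), int(get("n")))
    acc = int(get("hit")) + int(get("cr"))
    return ScoredBlock(
        block_index=int(get("block_index")),
        difficulty_level=dl,
        unscaled_accuracy=acc,
        simple_score=float(dl * acc),
        cumulative_hours=float(get("cumulative_hours")),
    )


def score_blocks(block_log: pd.DataFrame) -> pd.DataFrame:
    """Vectorised scoring of a tidy block log (one row per block)."""
    if block_log.empty:
        raise ValueError("empty block log")
    epoch_f = (block_log["dprime_threshold"] - 0.6) / 0.2
    epoch = np.round(epoch_f).astype(int)
    if np.any(np.abs(epoch_f - epoch) > _DL_GRID_TOL) or np.any(epoch < 0):
        raise ValueError("block log contains off-grid d' thresholds")
    dl = 6 * np.minimum(epoch, 11) + block_log["n"].to_numpy()
    if np.any((dl < 1) | (dl > 72)):
        raise ValueError("difficulty level out of range 1..72")
    out = block_log.copy()
    out["difficulty_level"] = dl
    out["unscaled_accuracy"] = block_log["hit"] + block_log["cr"]
    out["simple_score"] = (dl * out["unscaled_accuracy"]).astype(float)
    return out


def segment_periods(scored: pd.DataFrame,
                    min_blocks: int = MIN_BLOCKS_PER_PERIOD) -> dict:
    """Split blocks into early/middle/late by cumulative hours at block end.

    Half-open intervals: early [0, 5), middle [5, 10), late [10, inf); a
    block ending at exactly 5.0 h belongs to the middle period.  A period is
    fittable only with at least ``min_blocks`` blocks.
    """
    if scored.empty:
        raise ValueError("empty scored log")
    hours = scored["cumulative_hours"].to_numpy()
    if np.any(np.diff(hours) < -1e-9):
        raise ValueError("cumulative_hours must be non-decreasing")
    lo, hi = PERIOD_BOUNDS_HOURS
    idx = scored.index.to_numpy()
    periods = {
        "early": idx[hours < lo],
        "middle": idx[(hours >= lo) & (hours < hi)],
        "late": idx[hours >= hi],
    }
    fittable = {name: len(ix) >= min_blocks for name, ix in periods.items()}
    return {"periods": periods, "fittable": fittable}


def _ols_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    if len(t) < 2 or np.ptp(t) == 0:
        raise ValueError("singular design: need >= 2 distinct t values")
    res = stats.linregress(t, y)
    return float(res.intercept), float(res.slope), float(res.rvalue ** 2)


def fit_log_learning(scored: pd.DataFrame,
                     index: Optional[Iterable] = None) -> tuple[float, float, float]:
    """OLS of Simple Score on ln(t) over the given blocks: (b0, b1, R^2).

    ``t`` is the global sequential block index (1-based), so period fits are
    nested views of one series.
    """
    sub = scored if index is None else scored.loc[index]
    t = sub["block_index"].to_numpy(dtype=float)
    if np.any(t < 1):
        raise ValueError("block_index must be >= 1")
    b0, b1, r2 = _ols_fit(np.log(t), sub["simple_score"].to_numpy(dtype=float))
    return b0, b1, r2


def fit_linear_slope(scored: pd.DataFrame,
                     index: Optional[Iterable] = None) -> tuple[float, float, float]:
    """OLS of Simple Score on t over the given blocks: (slope, intercept, R^2)."""
    sub = scored if index is None else scored.loc[index]
    t = sub["block_index"].to_numpy(dtype=float)
    b0, b1, r2 = _ols_fit(t, sub["simple_score"].to_numpy(dtype=float))
    return b1, b0, r2


def learning_rates(scored: pd.DataFrame, participant_id: str = "",
                   min_blocks: int = MIN_BLOCKS_PER_PERIOD) -> LearningRates:
    """All six learning-rate quantities for one participant's scored log.

    Periods without enough blocks are flagged unfittable and reported as NaN
    (short or discontinued training histories).
    """
    seg = segment_periods(scored, min_blocks=min_blocks)
    periods, fittable = seg["periods"], seg["fittable"]
    nan3 = (float("nan"),) * 3

    overall = fit_log_learning(scored) if len(scored) >= min_blocks else nan3
    early = (fit_log_learning(scored, periods["early"])
             if fittable["early"] else nan3)
    middle = (fit_linear_slope(scored, periods["middle"])
              if fittable["middle"] else nan3)
    late = (fit_linear_slope(scored, periods["late"])
            if fittable["late"] else nan3)

    return LearningRates(
        participant_id=participant_id,
        overall_b0=overall[0], overall_b1=overall[1], overall_r2=overall[2],
        overall_n=len(scored),
        early_b0=early[0], early_b1=early[1], early_r2=early[2],
        early_n=len(periods["early"]),
        middle_slope=middle[0], middle_intercept=middle[1], middle_r2=middle[2],
        middle_n=len(periods["middle"]),
        late_slope=late[0], late_intercept=late[1], late_r2=late[2],
        late_n=len(periods["late"]),
        early_fittable=fittable["early"],
        middle_fittable=fittable["middle"],
        late_fittable=fittable["late"],
    )


def cohort_learning_rates(scored: pd.DataFrame,
                          min_blocks: int = MIN_BLOCKS_PER_PERIOD) -> pd.DataFrame:
    """Per-participant learning rates, one row per participant."""
    rows = []
    for pid, sub in scored.groupby("participant_id", sort=True):
        rows.append(vars(learning_rates(sub.reset_index(drop=True), str(pid),
                                        min_blocks=min_blocks)))
    return pd.DataFrame(rows)


def scored_series_with_log_growth(b0: float, b1: float, n_blocks: int,
                                  noise_sd: float,
                                  rng: np.random.Generator,
                                  blocks_per_hour: float = 26.0) -> pd.DataFrame:
    """Synthetic scored log with exact log growth: Y = b0 + b1 ln(t) + noise.

    Ground-truth generator for learning-rate recovery studies; cumulative
    hours accrue at a constant block rate.
    """
    t = np.arange(1, n_blocks + 1, dtype=float)
    y = b0 + b1 * np.log(t) + rng.normal(0.0, noise_sd, size=n_blocks)
    return pd.DataFrame({
        "block_index": t.astype(int),
        "simple_score": y,
        "cumulative_hours": t / blocks_per_hour,
    })
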