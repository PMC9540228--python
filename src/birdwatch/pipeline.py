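"""End-to-end orchestration: simulate -> score -> fit-learning -> forecast ->
regress, with a reproducibility manifest.

All randomness flows from one root seed: per-participant simulation seeds
and the covariate-fixture seed are derived from it through a SeedSequence,
and are recorded in the manifest together with SHA-256 digests of every
output file.  Stage failures are recorded per stage without aborting later
stages that do not depend on them.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import agents, analysis, forecast, group, io
from .engine import EngineConfig

__all__ = ["simulate_cohort", "run_pipeline", "forecast_cohort",
           "regression_stage"]

log = logging.getLogger("birdwatch")

STEPWISE_PREDICTORS = ["ravlt_learning_total", "ravlt_interference_cost",
                       "ravlt_delay_cost", "ravlt_recognition_errors",
                       "story_memory", "matrix_reasoning", "visual_puzzles"]


def _participant_seeds(root_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(root_seed)
    return [int(s) for s in ss.generate_state(n + 1, dtype=np.uint32)[1:] % (2 ** 31)]


def simulate_cohort(config: EngineConfig, seed: int, n_participants: int,
                    context_sensitive_frac: float = 0.5,
                    base_params=None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Simulate a cohort; returns (block log, survey log, participant seeds)."""
    if n_participants <= 0:
        raise ValueError("participants must be a positive integer")
    cohort = agents.sample_cohort(n_participants, np.random.SeedSequence(seed),
                                  context_sensitive_frac=context_sensitive_frac,
                                  base_params=base_params)
    seeds = _participant_seeds(seed, n_participants)
    blocks, surveys = [], []
    seed_map: dict[str, int] = {}
    for i, (agent, pseed) in enumerate(zip(cohort, seeds)):
        pid = f"p{i + 1:03d}"
        seed_map[pid] = pseed
        b, s = agents.simulate_participant(agent, config, pseed,
                                           participant_id=pid)
        blocks.append(b)
        surveys.append(s)
        log.debug("simulated %s: %d blocks, %.1f h", pid, len(b),
                  b["cumulative_hours"].iloc[-1])
    return (pd.concat(blocks, ignore_index=True),
            pd.concat(surveys, ignore_index=True), seed_map)


def forecast_cohort(scored: pd.DataFrame, surveys: pd.DataFrame,
                    alpha: float = 0.05) -> tuple[list, dict]:
    """Per-participant daily ARIMAX fits plus the cohort summary."""
    results = []
    for pid in sorted(scored["participant_id"].unique()):
        series = forecast.aggregate_daily(scored, surveys, participant_id=pid)
        results.append(forecast.fit_arimax(series))
    return results, forecast.summarize_cohort(results, alpha=alpha)


def _forecast_json(results: list, summary: dict) -> dict:
    out = {"participants": {}, "cohort": {}}
    for r in results:
        out["participants"][r.participant_id] = {
            "order": list(r.order) if r.fitted else None,
            "aic": None if not r.fitted else r.aic,
            "converged": r.converged,
            "n_obs": r.n_obs,
            "dropped_regressors": r.dropped_regressors,
            "failure_reason": r.failure_reason,
            "exog_coefs": (r.exog_coefs.reset_index(names="regressor")
                           .to_dict(orient="records") if r.fitted else []),
            "ar_coefs": list(map(float, r.ar_coefs)),
            "ma_coefs": list(map(float, r.ma_coefs)),
        }
    cohort = {k: v for k, v in summary.items() if k != "model_table"}
    cohort["model_table"] = summary["model_table"].to_dict(orient="records")
    out["cohort"] = cohort
    return out


def regression_stage(rates: pd.DataFrame, covariates: pd.DataFrame) -> dict:
    """Group-level stage: stepwise, hierarchical, and partial correlations.

    Stepwise regressions of each learning variable on the cognitive
    predictors; a hierarchical regression of early learning on age + eTIV
    (step 1) and left IFG + story memory (step 2); and age-controlled
    partial correlations of the reserve index with each cognitive measure.
    """
    data = rates.merge(covariates, on="participant_id", how="inner")
    report: dict = {"stepwise": {}, "hierarchical": {}, "partial_correlations": {}}

    dependents = {"overall_learning": "overall_b1", "early_learning": "early_b1",
                  "middle_learning": "middle_slope", "late_learning": "late_slope"}
    for name, col in dependents.items():
        try:
            rep = group.stepwise_regression(data[col], data[STEPWISE_PREDICTORS],
                                            dependent=name)
            report["stepwise"][name] = {
                "terms": rep.terms.reset_index(names="term").to_dict(orient="records"),
                "r2": rep.r2, "f": rep.f_stat, "p": rep.model_pvalue,
                "n": rep.n_obs, "steps": rep.step_history,
                "empty_model": rep.empty,
            }
        except ValueError as exc:
            report["stepwise"][name] = {"error": str(exc)}

    for name, col in (("overall_learning", "overall_b1"),
                      ("early_learning", "early_b1")):
        try:
            h = group.hierarchical_regression(
                data[col], data[["age", "etiv"]],
                data[["left_ifg", "story_memory"]], dependent=name)
            report["hierarchical"][name] = {
                "step1_r2": h.step1.r2, "step2_r2": h.step2.r2,
                "delta_r2": h.delta_r2, "f_change": h.f_change,
                "f_change_p": h.f_change_pvalue, "n": h.step2.n_obs,
                "step2_terms": h.step2.terms.reset_index(names="term")
                .to_dict(orient="records"),
                "condition_warning": h.condition_warning,
            }
        except ValueError as exc:
            report["hierarchical"][name] = {"error": str(exc)}

    for measure in ("story_memory", "ravlt_learning_total", "matrix_reasoning",
                    "visual_puzzles"):
        try:
            r, p, df = group.partial_correlation(
                data["criq"], data[measure], data[["age"]])
            report["partial_correlations"][f"criq_vs_{measure}"] = {
                "r": r, "p": p, "df": df}
        except ValueError as exc:
            report["partial_correlations"][f"criq_vs_{measure}"] = {
                "error": str(exc)}
    return report


def run_pipeline(config: Optional[EngineConfig | str | Path], seed: int,
                 out_dir: str | Path, participants: int = 37) -> dict:
    """Run every stage and write all artifacts into ``out_dir``.

    Returns a status dict mapping stage name to "ok" or the error message.
    Later stages run whenever their inputs exist.
    """
    if participants <= 0:
        raise ValueError("participants must be a positive integer")
    if config is None or isinstance(config, (str, Path)):
        config = io.load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    outputs: dict[str, Path] = {}

    scored = rates = surveys = None
    seed_map: dict[str, int] = {}
    try:
        blocks, surveys, seed_map = simulate_cohort(config, seed, participants)
        outputs["blocks"] = io.write_block_log(blocks, out / "blocks.csv")
        outputs["surveys"] = io.write_survey_log(surveys, out / "surveys.csv")
        status["simulate"] = "ok"
    except Exception as exc:  # noqa: BLE001 - stage isolation
        status["simulate"] = f"error: {exc}"
        blocks = None

    if blocks is not None:
        try:
            scored = analysis.score_blocks(blocks)
            scored.to_csv(out / "scored.csv", index=False)
            outputs["scored"] = out / "scored.csv"
            status["score"] = "ok"
        except Exception as exc:
            status["score"] = f"error: {exc}"

    if scored is not None:
        try:
            rates = analysis.cohort_learning_rates(scored)
            rates.to_csv(out / "learning_rates.csv", index=False)
            outputs["learning_rates"] = out / "learning_rates.csv"
            status["fit-learning"] = "ok"
        except Exception as exc:
            status["fit-learning"] = f"error: {exc}"

        try:
            results, summary = forecast_cohort(scored, surveys)
            with open(out / "forecast.json", "w", encoding="utf-8") as fh:
                json.dump(_forecast_json(results, summary), fh, indent=2,
                          default=io._json_default)
            outputs["forecast"] = out / "forecast.json"
            summary["model_table"].to_csv(out / "forecast_models.csv", index=False)
            outputs["forecast_models"] = out / "forecast_models.csv"
            status["forecast"] = "ok"
        except Exception as exc:
            status["forecast"] = f"error: {exc}"

    if rates is not None:
        try:
            cov_seed = _participant_seeds(seed, participants + 1)[-1]
            covariates = group.sample_covariates(participants, cov_seed)
            covariates.to_csv(out / "covariates.csv", index=False)
            outputs["covariates"] = out / "covariates.csv"
            report = regression_stage(rates, covariates)
            with open(out / "regression_report.json", "w", encoding="utf-8") as fh:
                json.dump(report, fh, indent=2, default=io._json_default)
            outputs["regression_report"] = out / "regression_report.json"
            status["regress"] = "ok"
        except Exception as exc:
            status["regress"] = f"error: {exc}"

    manifest = io.build_manifest(config, seed, seed_map, outputs)
    manifest["stage_status"] = status
    io.write_manifest(manifest, out / "manifest.json")
    return status
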