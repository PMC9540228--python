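"""Log formats, configuration files, validation, and run manifests.

Block logs are tidy tables (one row per 80-trial block) serialised as either
CSV or JSONL (one JSON object per line); the two forms are interconvertible
without loss.  Survey logs are CSV.  Engine configuration is a flat YAML
mapping mirroring the EngineConfig fields.  Every simulation run writes a
manifest (JSON) recording the config snapshot and hash, the root seed and
derived per-participant seeds, and SHA-256 digests of the output files, so
a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .engine import EngineConfig

__all__ = [
    "BLOCK_COLUMNS",
    "SURVEY_COLUMNS",
    "read_block_log",
    "write_block_log",
    "read_survey_log",
    "write_survey_log",
    "load_config",
    "dump_config",
    "validate_logs",
    "build_manifest",
    "write_manifest",
    "file_digest",
]

BLOCK_COLUMNS = ["participant_id", "day_index", "block_index", "n",
                 "dprime_threshold", "maxrt", "hit", "cr", "miss", "fa",
                 "dprime", "score", "passed", "duration_seconds",
                 "cumulative_hours"]
SURVEY_COLUMNS = ["participant_id", "day_index", "wellbeing", "stress",
                  "busyness", "mood", "sleep_hours"]

_INT_BLOCK_COLS = ["day_index", "block_index", "n", "hit", "cr", "miss", "fa"]


def _order_columns(df: pd.DataFrame, spec: list[str]) -> pd.DataFrame:
    cols = [c for c in spec if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra]


def write_block_log(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a block log as CSV or JSONL depending on the file suffix."""
    path = Path(path)
    out = _order_columns(df, BLOCK_COLUMNS)
    if path.suffix == ".jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in out.to_dict(orient="records"):
                fh.write(json.dumps(rec, default=_json_default) + "\n")
    else:
        out.to_csv(path, index=False)
    return path


def read_block_log(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".jsonl":
        df = pd.read_json(path, lines=True)
    else:
        df = pd.read_csv(path)
    if "passed" in df.columns:
        df["passed"] = df["passed"].astype(bool)
    for col in _INT_BLOCK_COLS:
        if col in df.columns:
            df[col] = df[col].astype(int)
    return _order_columns(df, BLOCK_COLUMNS)


def write_survey_log(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    _order_columns(df, SURVEY_COLUMNS).to_csv(path, index=False)
    return path


def read_survey_log(path: str | Path) -> pd.DataFrame:
    return _order_columns(pd.read_csv(path), SURVEY_COLUMNS)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_config(path: Optional[str | Path]) -> EngineConfig:
    """Load an EngineConfig from a flat YAML mapping (defaults when None)."""
    if path is None:
        return EngineConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a flat key/value mapping")
    valid = {f.name for f in dataclasses.fields(EngineConfig)}
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return EngineConfig(**raw)


def load_cohort_spec(path: Optional[str | Path]) -> dict:
    """Load a cohort specification: agent-parameter overrides plus cohort-level
    keys (``context_sensitive_frac``).  Flat YAML mapping; unknown keys error.
    """
    from .agents import AgentParams  # local import to avoid a cycle

    if path is None:
        return {"base_params": AgentParams(), "context_sensitive_frac": 0.5}
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("cohort spec must be a flat key/value mapping")
    frac = raw.pop("context_sensitive_frac", 0.5)
    valid = {f.name for f in dataclasses.fields(AgentParams)}
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ValueError(f"unknown cohort spec keys: {unknown}")
    return {"base_params": AgentParams(**raw),
            "context_sensitive_frac": float(frac)}


def dump_config(config: EngineConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return path


def validate_logs(block_log: pd.DataFrame, survey_log: pd.DataFrame,
                  block_length: int = 80) -> list[dict]:
    """Schema and consistency checks; returns a machine-readable issue list.

    Checks: required columns, count conservation (hit+cr+miss+fa equals the
    block length), per-participant monotone cumulative hours, Likert ranges,
    sleep-hour bounds, and difficulty-grid bounds.
    """
    issues: list[dict] = []

    def issue(kind: str, message: str, row=None) -> None:
        issues.append({"kind": kind,
                       "row": None if row is None else int(row),
                       "message": message})

    for col in BLOCK_COLUMNS:
        if col not in block_log.columns:
            issue("schema", f"block log missing column {col!r}")
    for col in SURVEY_COLUMNS:
        if col not in survey_log.columns:
            issue("schema", f"survey log missing column {col!r}")
    if any(i["kind"] == "schema" for i in issues):
        return issues

    total = (block_log["hit"] + block_log["cr"] + block_log["miss"]
             + block_log["fa"])
    for row in block_log.index[total != block_length]:
        issue("count_conservation",
              f"hit+cr+miss+fa = {int(total[row])} != {block_length}", row)

    for pid, sub in block_log.groupby("participant_id"):
        hours = sub["cumulative_hours"].to_numpy()
        bad = np.nonzero(np.diff(hours) < -1e-9)[0]
        for i in bad:
            issue("cumulative_hours",
                  f"participant {pid}: cumulative_hours decreases", sub.index[i + 1])

    for row in block_log.index[(block_log["n"] < 1) | (block_log["n"] > 6)]:
        issue("difficulty_bounds", f"n = {int(block_log.loc[row, 'n'])} outside 1..6",
              row)
    epoch_f = (block_log["dprime_threshold"] - 0.6) / 0.2
    off_grid = (np.abs(epoch_f - np.round(epoch_f)) > 1e-6) | (epoch_f < -1e-6) \
        | (epoch_f > 12 + 1e-6)
    for row in block_log.index[off_grid]:
        issue("difficulty_bounds",
              f"d' threshold {block_log.loc[row, 'dprime_threshold']} off grid", row)

    for col in ("wellbeing", "stress", "busyness", "mood"):
        bad = (survey_log[col] < 1) | (survey_log[col] > 5)
        for row in survey_log.index[bad]:
            issue("likert_range",
                  f"{col} = {survey_log.loc[row, col]} outside 1..5", row)
    bad_sleep = (survey_log["sleep_hours"] < 0) | (survey_log["sleep_hours"] > 24)
    for row in survey_log.index[bad_sleep]:
        issue("sleep_range",
              f"sleep_hours = {survey_log.loc[row, 'sleep_hours']} outside 0..24",
              row)
    return issues


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(config: EngineConfig, root_seed: int,
                   participant_seeds: dict[str, int],
                   outputs: dict[str, str | Path]) -> dict:
    cfg = dataclasses.asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    return {
        "created": datetime.now(timezone.utc).isoformat(),
        "config": cfg,
        "config_sha256": cfg_hash,
        "root_seed": int(root_seed),
        "participant_seeds": {k: int(v) for k, v in participant_seeds.items()},
        "output_digests": {name: file_digest(p) for name, p in outputs.items()},
    }


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
        fh.write("\n")
    return path
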