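"""Trials-table CSV schema, config handling, logging and seed plumbing."""

from __future__ import annotations

import json
import logging
import os
import tempfile
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TRIALS_COLUMNS",
    "VALID_CONTRASTS",
    "SchemaError",
    "read_trials_table",
    "write_trials_table",
    "validate_trials",
    "load_config",
    "atomic_write_json",
    "setup_logging",
]

log = logging.getLogger("choicelab")

TRIALS_COLUMNS = ["lab_id", "mouse_id", "session_day", "trial_index",
                  "signed_contrast", "block_p_left", "choice", "correct",
                  "trial_duration_s", "is_repeat", "stage_id"]

VALID_CONTRASTS = frozenset({0.0, 6.25, -6.25, 12.5, -12.5, 25.0, -25.0,
                             50.0, -50.0, 100.0, -100.0})
VALID_P_LEFT = frozenset({0.5, 0.2, 0.8})

# config keys accepted in a RunConfig file, by section prefix
_KNOWN_CONFIG_KEYS = {
    "seed",
    "task.p_geometric", "task.block_min", "task.block_max",
    "task.first_block_len", "task.p_repeat", "task.session_max_min",
    "task.low_count_min", "task.low_count_threshold", "task.slowdown_factor",
    "cohort.n_labs", "cohort.n_mice_per_lab", "cohort.mode",
    "cohort.max_days", "cohort.continue_to_full", "cohort.n_full_days",
    "cohort.initial_scale", "cohort.trials_mean", "cohort.trials_sd",
    "cohort.duration_median", "cohort.duration_sigma",
    "fit.n_restarts", "fit.penalty_strength",
    "classify.classifier", "classify.n_per_lab", "classify.n_repeats",
    "classify.mode",
}


class SchemaError(ValueError):
    """A trials table violates the CSV schema."""


def _fail(msg: str, row: Optional[int] = None) -> None:
    raise SchemaError(msg if row is None else f"row {row}: {msg}")


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate, type, and deterministically sort a trials table."""
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        _fail(f"missing column(s): {missing}")

    out = df.copy()
    try:
        out["session_day"] = out["session_day"].astype(int)
        out["trial_index"] = out["trial_index"].astype(int)
        out["signed_contrast"] = out["signed_contrast"].astype(float)
        out["block_p_left"] = out["block_p_left"].astype(float)
        out["choice"] = out["choice"].astype(int)
        out["correct"] = out["correct"].astype(int)
        out["trial_duration_s"] = out["trial_duration_s"].astype(float)
        out["is_repeat"] = out["is_repeat"].astype(int)
        out["stage_id"] = out["stage_id"].astype(int)
    except (TypeError, ValueError) as e:
        _fail(f"type coercion failed: {e}")

    for i, v in out["signed_contrast"].items():
        if v not in VALID_CONTRASTS:
            _fail(f"signed_contrast {v} not in the contrast vocabulary", i)
    for i, v in out["block_p_left"].items():
        if v not in VALID_P_LEFT:
            _fail(f"block_p_left {v} not in {{0.5, 0.2, 0.8}}", i)
    for i, v in out["choice"].items():
        if v not in (-1, 0, 1):
            _fail(f"choice {v} not in {{-1, 0, 1}}", i)
    for i, v in out["correct"].items():
        if v not in (0, 1):
            _fail(f"correct {v} not binary", i)
    bad = out[(out["correct"] == 1) & (out["choice"] == 0)]
    if len(bad):
        _fail("correct = 1 with choice = 0 (no-response)", bad.index[0])
    if (out["trial_duration_s"] <= 0).any():
        i = out.index[out["trial_duration_s"] <= 0][0]
        _fail("trial_duration_s must be positive", i)
    if (out["trial_index"] < 1).any() or (out["session_day"] < 1).any():
        _fail("trial_index and session_day are 1-based")

    key = out[["lab_id", "mouse_id", "session_day", "trial_index"]]
    dup = key.duplicated()
    if dup.any():
        _fail("duplicate (lab, mouse, day, trial) key", out.index[dup][0])

    out = out.sort_values(["lab_id", "mouse_id", "session_day", "trial_index"],
                          kind="mergesort").reset_index(drop=True)
    return out[TRIALS_COLUMNS]


def read_trials_table(path) -> pd.DataFrame:
    """Read and validate a trials CSV."""
    df = pd.read_csv(path)
    return validate_trials(df)


def write_trials_table(df: pd.DataFrame, path) -> None:
    """Validate and write a trials CSV atomically."""
    out = validate_trials(df)
    _atomic_write_text(out.to_csv(index=False), path)


def _atomic_write_text(text: str, path) -> None:
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as f:
            f.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_json(obj, path) -> None:
    _atomic_write_text(json.dumps(obj, indent=2, default=_json_default), path)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_config(path=None, overrides: Optional[dict] = None) -> dict:
    """Load a flat key-value YAML config, rejecting unknown keys."""
    cfg: dict = {}
    if path is not None:
        with open(path) as f:
            loaded = yaml.safe_load(f) or {}
        cfg.update(_flatten(loaded))
    if overrides:
        cfg.update(overrides)
    unknown = set(cfg) - _KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return cfg


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, f"{key}."))
        else:
            out[key] = v
    return out


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler()  # stderr
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("choicelab")
    root.handlers[:] = [handler]
    root.setLevel(getattr(logging, level.upper()))
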