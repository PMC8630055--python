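"""Delimited-table input/output with schema validation.

Interchange format is plain CSV (header row, UTF-8, '.' decimal).  Readers
validate the schema and report violations with 1-based data row numbers;
writers are plain pandas round-trips, and a write-then-read cycle
reproduces the records exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .exceptions import SchemaError

logger = logging.getLogger(__name__)

TRIAL_SCHEMA = {
    "participant_id": str,
    "trial_index": int,
    "set_size": int,
    "click_correct": int,
}
VALID_SET_SIZES = {3, 5, 6, 7, 8}

ESTIMATE_COLUMNS = ["initial_accuracy", "rate_estimate", "final_accuracy",
                    "overall_accuracy"]


def read_trials(path) -> pd.DataFrame:
    """Read and validate a click-level trial table.

    Required columns: participant_id, trial_index, set_size, click_correct;
    optional: feedback, order, is_catch, click_index.  Unknown columns are
    preserved with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty input file") from None
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")

    missing = [c for c in TRIAL_SCHEMA if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    known = set(TRIAL_SCHEMA) | {"feedback", "order", "is_catch", "click_index"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("%s: unknown columns preserved: %s", path, unknown)

    bad = df.index[~df["click_correct"].isin([0, 1])]
    if len(bad):
        raise SchemaError(
            f"{path}: click_correct must be 0 or 1 (first bad data row "
            f"{int(bad[0]) + 1})")
    bad = df.index[~df["set_size"].isin(VALID_SET_SIZES)]
    if len(bad):
        raise SchemaError(
            f"{path}: set_size must be one of {sorted(VALID_SET_SIZES)} "
            f"(first bad data row {int(bad[0]) + 1})")
    bad = df.index[(df["trial_index"] < 1) | (df["trial_index"] > 68)]
    if len(bad):
        raise SchemaError(
            f"{path}: trial_index must be in 1..68 (first bad data row "
            f"{int(bad[0]) + 1})")
    return df


def write_trials(path, trials: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)


def write_estimates(path, estimates: pd.DataFrame) -> None:
    """Write the participant-estimate table (index = participant_id)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    estimates.to_csv(path, index=True, index_label="participant_id")


def read_estimates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ["participant_id", *ESTIMATE_COLUMNS]
               if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing estimate columns {missing}")
    return df.set_index("participant_id")


def read_gf(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("participant_id", "gf"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return df


def write_report(path, text: str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(text, encoding="utf-8")


def write_manifest(path, config: dict, seed: int, stages: list[str]) -> None:
    """Every run records its configuration, seed and package version."""
    from . import __version__
    payload = {"package": "wmlearn", "version": __version__, "seed": seed,
               "stages": stages, "config": config}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, default=str),
                          encoding="utf-8")


def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg
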