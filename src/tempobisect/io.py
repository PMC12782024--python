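"""CSV conventions and schema-validated readers/writers.

All tables are UTF-8 CSV with a header row, "." decimal, empty fields for
missing values and floats written with 9 significant digits.  Readers
validate the declared schema and raise ``SchemaError`` naming offending
columns or rows.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.12g"

SCHEDULE_COLUMNS = [
    "phase", "block", "trial", "condition_category", "condition_valence",
    "exemplar", "duration_s", "iti_s",
]
TRIAL_LOG_COLUMNS = [
    "participant_id", "group", "block", "trial", "semantic_category",
    "valence", "exemplar", "duration_s", "response",
]
COVARIATE_COLUMNS = ["participant_id", "group", "age", "tiv", "mmse"]
METRICS_COLUMNS = [
    "participant_id", "group", "semantic_category", "valence",
    "alpha", "beta", "gamma", "lam", "bp", "q25", "q75", "wr", "log_wr",
    "fit_ok", "message",
]
DELTA_COLUMNS = [
    "participant_id", "group", "condition", "control_mean_bp", "patient_bp",
    "delta", "overall_mean_delta",
]
ASSOC_COLUMNS = [
    "region", "condition", "slope", "t", "dof", "p_raw",
    "overall_mean_delta", "atrophy_direction", "p_fwe",
]

RESPONSE_TOKENS = {"short", "long"}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def write_schedule(schedule, path: str | Path) -> None:
    """Write a Schedule to CSV (durations with one decimal)."""
    rows = [
        {
            "phase": t.phase,
            "block": t.block_index,
            "trial": i,
            "condition_category": t.condition.semantic_category,
            "condition_valence": t.condition.valence,
            "exemplar": t.exemplar_id,
            "duration_s": f"{t.duration:.1f}",
            "iti_s": t.iti,
        }
        for i, t in enumerate(schedule.trials)
    ]
    pd.DataFrame(rows, columns=SCHEDULE_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_schedule(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, SCHEDULE_COLUMNS, path)
    return df


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def write_table(df: pd.DataFrame, path: str | Path, columns: list[str] | None = None) -> None:
    if columns is not None:
        extra = [c for c in df.columns if c not in columns]
        df = df[[c for c in columns if c in df.columns] + extra]
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trial_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, TRIAL_LOG_COLUMNS, path)
    bad = ~df["response"].isin(RESPONSE_TOKENS)
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(
            f"{path}: unknown response token {df.loc[row, 'response']!r} at row {row}"
        )
    return df


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, COVARIATE_COLUMNS, path)
    return df


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, METRICS_COLUMNS[:13], path)  # message column optional
    return df


def read_roi(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, COVARIATE_COLUMNS, path)
    regions = [c for c in df.columns if c not in COVARIATE_COLUMNS]
    if not regions:
        raise SchemaError(f"{path}: no region volume columns found")
    return df


def read_deltas(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, DELTA_COLUMNS[:6], path)
    return df
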