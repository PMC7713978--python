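"""Delimited-text formats for capture tables, abundance series and configs.

All files are comma-separated UTF-8 with a mandatory header row.  The
capture-history table has one row per captured individual::

    id,site,time,w1,w2,<covariate...>

with ``w1, w2`` in {0, 1} and 1-based integer time points; truth sidecar
files (which may contain never-captured rows) use the same layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .abundance import AbundanceSeries
from .exceptions import InputError

__all__ = [
    "read_capture_table",
    "write_capture_table",
    "read_series_table",
    "write_series_table",
    "load_config",
    "write_json_report",
]

REQUIRED_COLUMNS = ("id", "site", "time", "w1", "w2")


def read_capture_table(path, allow_uncaptured: bool = False) -> pd.DataFrame:
    """Read and validate a capture-history table.

    Raises :class:`~capdyn.exceptions.InputError` naming the offending
    column or line for schema and value problems.  With
    ``allow_uncaptured=False`` (the default, for fitting inputs) any
    (0,0) history is rejected; truth sidecars set it to True.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise InputError(f"{path}: cannot parse as CSV: {exc}") from exc
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    for col in ("w1", "w2"):
        vals = df[col]
        bad = ~vals.isin([0, 1])
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # header is line 1
            raise InputError(
                f"{path}: line {line}: {col}={vals.iloc[line - 2]!r} is not 0 or 1"
            )
    times = df["time"]
    if not pd.api.types.is_integer_dtype(times):
        try:
            conv = times.astype(int)
        except (TypeError, ValueError) as exc:
            raise InputError(f"{path}: 'time' must be integer") from exc
        if not (conv == times).all():
            raise InputError(f"{path}: 'time' must be integer")
        df["time"] = conv
    if (df["time"] < 1).any():
        line = int(np.nonzero((df["time"] < 1).to_numpy())[0][0]) + 2
        raise InputError(f"{path}: line {line}: time points must be >= 1")
    if not allow_uncaptured:
        zero = (df["w1"] == 0) & (df["w2"] == 0)
        if zero.any():
            line = int(np.nonzero(zero.to_numpy())[0][0]) + 2
            raise InputError(
                f"{path}: line {line}: capture history (0,0) is not a valid "
                "fitting input (use allow_uncaptured=True for truth sidecars)"
            )
    return df


def write_capture_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in REQUIRED_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in REQUIRED_COLUMNS
    ]
    df[cols].to_csv(path, index=False)


def write_series_table(series: AbundanceSeries, path) -> None:
    """Write an abundance series as ``site,series,time,n,N_hat,log_N_hat``."""
    series.to_frame().to_csv(path, index=False)


def read_series_table(path) -> AbundanceSeries:
    df = pd.read_csv(path)
    for col in ("site", "series", "time", "n", "N_hat"):
        if col not in df.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    return AbundanceSeries(
        site=str(df["site"].iloc[0]),
        series=str(df["series"].iloc[0]),
        time_points=df["time"].to_numpy(),
        n=df["n"].to_numpy(),
        N_hat=df["N_hat"].to_numpy(),
    )


def load_config(path) -> dict:
    """Load a YAML (or JSON) run configuration."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: configuration must be a mapping")
    return cfg


def write_json_report(obj: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")
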