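"""Reading and writing time-series matrices, forecasts and run configs.

On disk a series is delimited text (comma or tab, auto-detected) with one
header row of variable names and one row per time step; an optional first
column named ``time``/``t``/``step``/``index`` (case-insensitive) carries
time stamps.  In memory the matrix is transposed to variables x steps.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .benchmarks import TimeSeriesMatrix
from .errors import ParseError
from .windowing import ForecastTask

__all__ = ["read_series", "write_series", "write_forecast", "read_forecast",
           "write_run_config", "TIME_COLUMN_NAMES"]

TIME_COLUMN_NAMES = frozenset({"time", "t", "step", "index"})


def _detect_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_series(path) -> TimeSeriesMatrix:
    """Parse a delimited-text series file into a variables x steps matrix."""
    path = Path(path)
    sep = _detect_sep(path)
    header = path.open("r", encoding="utf-8").readline().rstrip("\n").split(sep)
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ParseError(f"{path}: duplicate variable names {dupes}")
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as one error type
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[0] < 2:
        raise ParseError(f"{path}: need at least 2 time steps")
    cols = [str(c) for c in df.columns]
    if cols and cols[0].lower() in TIME_COLUMN_NAMES:
        time_index = tuple(float(v) for v in df.iloc[:, 0])
        df = df.iloc[:, 1:]
        cols = cols[1:]
    else:
        time_index = tuple(float(i) for i in range(df.shape[0]))
    if df.shape[1] < 1:
        raise ParseError(f"{path}: no variable columns")
    if df.isna().any().any():
        rows = sorted(set(np.where(df.isna().to_numpy())[0] + 2))  # 1-based + header
        raise ParseError(f"{path}: missing/non-numeric cells (file rows {rows})")
    try:
        values = df.to_numpy(dtype=np.float64).T
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from exc
    return TimeSeriesMatrix(values, tuple(cols), time_index)


def write_series(series: TimeSeriesMatrix, path, sep: str = ",") -> None:
    """Write a series with full float precision (round-trips exactly)."""
    path = Path(path)
    df = pd.DataFrame(series.values.T, columns=list(series.variable_names))
    df.insert(0, "time", list(series.time_index))
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_forecast(predictions: np.ndarray, task: ForecastTask, path,
                   truth: np.ndarray | None = None,
                   metrics: dict | None = None) -> None:
    """Forecast CSV (step, predicted[, truth]) plus an optional JSON sidecar."""
    path = Path(path)
    preds = np.asarray(predictions, dtype=np.float64)
    steps = np.arange(task.M_train + 1, task.M_train + 1 + preds.size)
    cols = {"step": steps, "predicted": preds}
    if truth is not None:
        cols["truth"] = np.asarray(truth, dtype=np.float64)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    if metrics is not None:
        sidecar = path.with_suffix(path.suffix + ".metrics.json")
        sidecar.write_text(json.dumps(metrics, indent=2))


def read_forecast(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), float_precision="round_trip")


def write_run_config(config: dict, out_dir) -> Path:
    """Materialize every resolved setting of a run next to its outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    resolved = {
        k: (asdict(v) if is_dataclass(v) else v) for k, v in config.items()
    }
    p = out_dir / "run_config.json"
    p.write_text(json.dumps(resolved, indent=2, default=str))
    return p
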