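"""Forecast-quality metrics: Pearson correlation and normalized RMSE.

Both are evaluated on the L-1 predicted future values of the target
variable, matching how multi-step forecasts of short series are scored in
this literature.  NRMSE is the root mean squared error divided by the
population standard deviation of the truth, so NRMSE = 1 means errors as
large as the natural variability of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .benchmarks import TimeSeriesMatrix
from .errors import MetricError
from .windowing import ForecastTask, rolling_forecast

__all__ = ["pcc", "nrmse", "MetricReport", "score_forecast", "evaluate_forecast"]


def pcc(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length vectors."""
    p = np.asarray(predicted, dtype=np.float64).ravel()
    t = np.asarray(truth, dtype=np.float64).ravel()
    if p.size != t.size or p.size < 2:
        raise MetricError("pcc needs two vectors of equal length >= 2")
    sp, st = p.std(), t.std()
    if sp == 0 or st == 0:
        raise MetricError("pcc undefined for a constant vector")
    cov = np.mean((p - p.mean()) * (t - t.mean()))
    return float(np.clip(cov / (sp * st), -1.0, 1.0))


def nrmse(predicted: np.ndarray, truth: np.ndarray) -> float:
    """RMSE normalized by the population SD of the truth."""
    p = np.asarray(predicted, dtype=np.float64).ravel()
    t = np.asarray(truth, dtype=np.float64).ravel()
    if p.size != t.size or p.size < 1:
        raise MetricError("nrmse needs two vectors of equal length >= 1")
    st = t.std()
    if st == 0:
        raise MetricError("nrmse undefined for a constant truth vector")
    return float(np.sqrt(np.mean((p - t) ** 2)) / st)


@dataclass
class MetricReport:
    """Per-target scores and their across-target moments (population var)."""

    per_target: dict = field(default_factory=dict)
    mean_pcc: float = float("nan")
    var_pcc: float = float("nan")
    mean_nrmse: float = float("nan")
    var_nrmse: float = float("nan")

    @classmethod
    def from_scores(cls, per_target: dict) -> "MetricReport":
        # pcc is undefined (nan) for one-step horizons; aggregate what exists
        pccs = np.array([v["pcc"] for v in per_target.values()])
        pccs = pccs[np.isfinite(pccs)]
        nrs = np.array([v["nrmse"] for v in per_target.values()])
        return cls(
            per_target=dict(per_target),
            mean_pcc=float(pccs.mean()) if pccs.size else float("nan"),
            var_pcc=float(pccs.var()) if pccs.size else float("nan"),
            mean_nrmse=float(nrs.mean()),
            var_nrmse=float(nrs.var()),
        )

    def to_dict(self) -> dict:
        def _j(x):
            return x if np.isfinite(x) else None

        return {
            "per_target": self.per_target,
            "mean_pcc": _j(self.mean_pcc),
            "var_pcc": _j(self.var_pcc),
            "mean_nrmse": _j(self.mean_nrmse),
            "var_nrmse": _j(self.var_nrmse),
        }


def score_forecast(model, series: TimeSeriesMatrix, task: ForecastTask,
                   horizon: int | None = None,
                   stream_covariates: bool = False) -> dict:
    """Roll the forecast and score it against the held-out truth.

    The NRMSE normalizer is the SD of the target's full recorded series
    ("the true data"), not of the scored window alone: window-local SDs
    vanish near turning points (and for one-step horizons), which would
    make the score diverge even for near-perfect forecasts.
    """
    tgt = task.validate(series)
    preds = rolling_forecast(model, series, task, horizon=horizon,
                             stream_covariates=stream_covariates)
    h = task.horizon if horizon is None else int(horizon)
    truth = series.values[tgt, task.M_train : task.M_train + h]
    if truth.size < h:
        raise MetricError("series too short to score the full horizon")
    sigma_ref = series.values[tgt].std()
    if sigma_ref == 0:
        raise MetricError("nrmse undefined for a constant target series")
    result = {
        "pcc": pcc(preds, truth) if truth.size >= 2 else float("nan"),
        "nrmse": float(np.sqrt(np.mean((preds - truth) ** 2)) / sigma_ref),
        "predictions": preds.tolist(),
        "truth": truth.tolist(),
    }
    return result


def evaluate_forecast(series: TimeSeriesMatrix, tasks, model_config=None,
                      train_config=None) -> MetricReport:
    """Train one model per task, forecast, and aggregate across targets."""
    from .training import fit_forecaster  # local import avoids a cycle

    per_target = {}
    for task in tasks:
        model = fit_forecaster(series, task, model_config, train_config)
        scores = score_forecast(model, series, task)
        name = series.variable_names[task.validate(series)]
        per_target[name] = {"pcc": scores["pcc"], "nrmse": scores["nrmse"]}
    return MetricReport.from_scores(per_target)
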