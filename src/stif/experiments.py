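"""Scripted characteristic experiments on the synthetic benchmarks.

Each experiment is a pure function of (system, seeds, sizes): it generates
its own data, trains from scratch at every grid point with derived seeds,
and returns JSON-serializable results.  Problem sizes default to desk
scale — small enough to run on one CPU core in minutes.

Benchmark protocol: lifted pendulum M=80, D=64, train on the
first 63 steps; coupled Lorenz M=80, D=90, train on the first 61 steps.
The embedded dimension equals M - M_train + 1 (18 and 20 respectively), so
the rolling forecast scores every held-out step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .benchmarks import (
    TimeSeriesMatrix,
    add_noise,
    lorenz_benchmark,
    pendulum_benchmark,
)
from .errors import StifError
from .metrics import MetricReport, score_forecast
from .model import VARIANTS, StnnConfig
from .training import TrainConfig, fit_forecaster
from .windowing import ForecastTask

__all__ = [
    "SweepResult",
    "benchmark_series",
    "run_benchmark",
    "robustness_sweep",
    "embedded_dim_sweep",
    "scaling_sweeps",
    "ablation_suite",
]

#: observed steps and training split of the benchmark forecasting protocol
PROTOCOL = {
    "pendulum": {"M": 80, "M_train": 63},
    "lorenz": {"M": 80, "M_train": 61},
}


def benchmark_series(system: str, seed: int, n_steps: int = 80,
                     noise_sigma: float = 0.0, lift_dim: int = 64,
                     n_oscillators: int = 30) -> TimeSeriesMatrix:
    """Generate one benchmark trajectory by name."""
    if system == "pendulum":
        return pendulum_benchmark(n_steps=n_steps, lift_dim=lift_dim, seed=seed,
                                  noise_sigma=noise_sigma)
    if system == "lorenz":
        return lorenz_benchmark(n_steps=n_steps, n_oscillators=n_oscillators,
                                seed=seed, noise_sigma=noise_sigma)
    raise StifError(f"unknown system {system!r}")


def _pick_targets(n_vars: int, n_targets: int, seed: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(i) for i in rng.choice(n_vars, size=n_targets, replace=False)]


def _evaluate(series: TimeSeriesMatrix, targets, l: int, m_train: int,
              seed: int, variant: str = "stnn",
              train_config: TrainConfig | None = None,
              noisy_series: TimeSeriesMatrix | None = None,
              horizon: int | None = None,
              stream_covariates: bool = False) -> MetricReport:
    """Fit one model per target and aggregate metrics across targets.

    Training (and normalization) read `noisy_series` when given; scoring is
    always against the clean `series` truth.
    """
    fit_series = noisy_series if noisy_series is not None else series
    if train_config is None:
        train_config = TrainConfig(seed=seed)
    per_target = {}
    for tgt in targets:
        task = ForecastTask(target=int(tgt), L=l, M_train=m_train)
        config = StnnConfig(D=series.n_variables, L=l, variant=variant, seed=seed)
        model = fit_forecaster(fit_series, task, config, train_config)
        scores = score_forecast(model, series, task, horizon=horizon,
                                stream_covariates=stream_covariates)
        name = series.variable_names[int(tgt)]
        per_target[name] = {"pcc": scores["pcc"], "nrmse": scores["nrmse"]}
    return MetricReport.from_scores(per_target)


def run_benchmark(system: str, n_targets: int = 4, seed: int = 0,
                     variant: str = "stnn",
                     train_config: TrainConfig | None = None) -> MetricReport:
    """The benchmark forecasting protocol for one data/init seed."""
    proto = PROTOCOL[system]
    series = benchmark_series(system, seed=seed, n_steps=proto["M"])
    l = proto["M"] - proto["M_train"] + 1
    targets = _pick_targets(series.n_variables, n_targets, seed)
    return _evaluate(series, targets, l, proto["M_train"], seed, variant,
                     train_config)


@dataclass
class SweepResult:
    """Per-grid-point metric reports along one experimental axis."""

    axis: str  # noise_sigma | L | M | D
    grid: list = field(default_factory=list)
    metric_rows: list = field(default_factory=list)  # one dict per grid point
    areas: dict | None = None  # embedded-dimension partition, L axis only

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise StifError("sweep grid must be strictly increasing")

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "grid": list(self.grid),
            "metric_rows": self.metric_rows,
            "areas": self.areas,
        }


def _seed_rows(reports_by_seed: list[MetricReport]) -> dict:
    """Median-over-seeds summary plus the per-seed reports."""
    return {
        "per_seed": [r.to_dict() for r in reports_by_seed],
        "median_pcc": float(np.median([r.mean_pcc for r in reports_by_seed])),
        "median_nrmse": float(np.median([r.mean_nrmse for r in reports_by_seed])),
    }


def robustness_sweep(sigmas, system: str = "pendulum", seeds=(0, 1, 2),
                     n_targets: int = 4,
                     train_config: TrainConfig | None = None) -> SweepResult:
    """Corrupt the training data with noise of strength sigma; score clean."""
    proto = PROTOCOL[system]
    l = proto["M"] - proto["M_train"] + 1
    rows = []
    for i, sigma in enumerate(sigmas):
        reports = []
        for seed in seeds:
            series = benchmark_series(system, seed=seed, n_steps=proto["M"])
            noisy = add_noise(series, float(sigma), seed=seed + 7919)
            targets = _pick_targets(series.n_variables, n_targets, seed)
            tc = train_config or TrainConfig(seed=seed + i)
            reports.append(_evaluate(series, targets, l, proto["M_train"],
                                     seed + i, train_config=tc, noisy_series=noisy))
        rows.append(_seed_rows(reports))
    return SweepResult(axis="noise_sigma", grid=[float(s) for s in sigmas],
                       metric_rows=rows)


def partition_areas(grid, mean_nrmse, tol: float = 1.1) -> dict:
    """Split an L grid into areas I (falling), II (plateau), III (rising).

    The plateau is the contiguous span between the first and last grid
    points whose mean NRMSE is within `tol` times the grid minimum.
    """
    vals = np.asarray(mean_nrmse, dtype=np.float64)
    if len(grid) == 1:
        return {"I": [], "II": list(grid), "III": [],
                "boundary_I_II": None, "boundary_II_III": None}
    low = vals <= tol * vals.min()
    first, last = int(np.argmax(low)), int(len(low) - 1 - np.argmax(low[::-1]))
    return {
        "I": list(grid[:first]),
        "II": list(grid[first:last + 1]),
        "III": list(grid[last + 1:]),
        "boundary_I_II": grid[first],
        "boundary_II_III": grid[last],
    }


def embedded_dim_sweep(l_values, system: str = "pendulum", m: int = 80,
                       seeds=(0, 1), n_targets: int = 4,
                       train_config: TrainConfig | None = None) -> SweepResult:
    """Prediction error versus embedded dimension L at fixed M.

    The training split is the benchmark protocol's (scaled if m differs
    from 80), so every L is scored on the same held-out horizon: the
    forecast streams the non-target sensors through the test segment while
    the target itself is always the model's own autoregressive feedback.
    This keeps NRMSE comparable across L (a horizon that shrank with L
    would conflate window size with task difficulty).
    """
    proto = PROTOCOL[system]
    m_train = round(m * proto["M_train"] / proto["M"])
    horizon = m - m_train
    rows = []
    for i, l in enumerate(l_values):
        reports = []
        for seed in seeds:
            series = benchmark_series(system, seed=seed, n_steps=m)
            targets = _pick_targets(series.n_variables, n_targets, seed)
            tc = train_config or TrainConfig(seed=seed + i)
            reports.append(_evaluate(series, targets, int(l), m_train,
                                     seed + i, train_config=tc,
                                     horizon=horizon, stream_covariates=True))
        rows.append(_seed_rows(reports))
    grid = [int(l) for l in l_values]
    areas = partition_areas(grid, [r["median_nrmse"] for r in rows])
    return SweepResult(axis="L", grid=grid, metric_rows=rows, areas=areas)


def scaling_sweeps(axis: str, grid, system: str = "pendulum", seeds=(0, 1, 2),
                   n_targets: int = 2, l: int | None = None,
                   train_config: TrainConfig | None = None) -> SweepResult:
    """Error versus observed steps M (fixed D, L) or dimension D (fixed M, L).

    The M sweep keeps the forecast horizon fixed at L-1 and trains on the
    first M - L + 1 steps; the D sweep keeps the benchmark protocol and
    truncates the series to its first D variables.
    """
    proto = PROTOCOL[system]
    if l is None:
        l = proto["M"] - proto["M_train"] + 1
    rows = []
    for i, g in enumerate(grid):
        reports = []
        for seed in seeds:
            if axis == "M":
                m = int(g)
                series = benchmark_series(system, seed=seed, n_steps=m)
                m_train = m - l + 1
            elif axis == "D":
                series = benchmark_series(system, seed=seed,
                                          n_steps=proto["M"]).subset(int(g))
                m_train = proto["M_train"]
            else:
                raise StifError("axis must be 'M' or 'D'")
            targets = _pick_targets(series.n_variables, n_targets, seed)
            tc = train_config or TrainConfig(seed=seed + i)
            reports.append(_evaluate(series, targets, l, m_train, seed + i,
                                     train_config=tc))
        rows.append(_seed_rows(reports))
    return SweepResult(axis=axis, grid=[int(g) for g in grid], metric_rows=rows)


def ablation_suite(system: str, seeds=(0, 1, 2), n_targets: int = 4,
                   train_config: TrainConfig | None = None) -> dict:
    """All four model variants under the benchmark protocol.

    Returns {variant: {"per_seed": [...], "median_pcc": ..., "median_nrmse": ...}}.
    """
    out = {}
    for variant in VARIANTS:
        reports = [
            run_benchmark(system, n_targets=n_targets, seed=seed,
                             variant=variant, train_config=train_config)
            for seed in seeds
        ]
        out[variant] = _seed_rows(reports)
    return out
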