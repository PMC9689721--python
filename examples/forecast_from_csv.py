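"""Forecast a target variable from a delimited-text series file.

Writes a small synthetic multivariate series to CSV first (stand-in for
any real dataset in the rows-are-time-steps format), then reads it back,
trains, and prints the multi-step forecast.  Swap the writing block for
your own file to use real data.
"""

import tempfile
from pathlib import Path

import numpy as np

from stif import (
    ForecastTask,
    StnnConfig,
    TimeSeriesMatrix,
    TrainConfig,
    fit_forecaster,
    read_series,
    rolling_forecast,
    write_series,
)

# -- build a toy 6-variable coupled-oscillation series and write it out
t = np.arange(60) * 0.2
rng = np.random.default_rng(0)
phases = rng.uniform(0, 2 * np.pi, 6)
vals = np.stack([np.sin(t + p) + 0.05 * rng.standard_normal(t.size) for p in phases])
series = TimeSeriesMatrix(vals, tuple(f"s{i}" for i in range(6)),
                          tuple(map(float, t)))
path = Path(tempfile.mkdtemp()) / "sensors.csv"
write_series(series, path)

# -- the actual workflow: read, fit, forecast
series = read_series(path)
task = ForecastTask(target="s2", L=8, M_train=50)
model = fit_forecaster(series, task,
                       StnnConfig(D=6, L=8, seed=1),
                       TrainConfig(epochs=800, seed=1))
preds = rolling_forecast(model, series, task)
truth = series.values[series.variable_index("s2"), 50:57]

print(f"file: {path}")
print(f"{task.horizon}-step-ahead forecast of s2 from {task.M_train} observed steps:")
for i, (p, tr) in enumerate(zip(preds, truth)):
    print(f"  step {51 + i}: predicted {p:+.3f}   truth {tr:+.3f}")
print("each row is one further step into the unobserved future;")
print("agreement degrades gracefully as prediction error feeds back")
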