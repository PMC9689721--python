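"""Forecast one variable of the lifted-pendulum benchmark.

Builds the 64-dimensional pendulum series (80 steps), trains the model on
the first 63 steps and predicts the remaining 17 autoregressively.  The
printed PCC measures how well the forecast tracks the shape of the truth
(1 is perfect); NRMSE is the error in units of the signal's own standard
deviation (0 is perfect, 1 is as large as the signal's variability).
"""

import numpy as np

from stif import (
    ForecastTask,
    StnnConfig,
    TrainConfig,
    fit_forecaster,
    pendulum_benchmark,
    score_forecast,
)

series = pendulum_benchmark(n_steps=80, lift_dim=64, seed=0)
task = ForecastTask(target="v17", L=18, M_train=63)

model = fit_forecaster(
    series,
    task,
    StnnConfig(D=64, L=18, seed=0),
    TrainConfig(epochs=1500, seed=0),
)
scores = score_forecast(model, series, task)

print(f"trained on {task.M_train} steps, predicted {task.horizon} steps ahead")
print(f"PCC   = {scores['pcc']:.4f}")
print(f"NRMSE = {scores['nrmse']:.4f}")
print("step  predicted   truth")
for i, (p, t) in enumerate(zip(scores["predictions"], scores["truth"])):
    print(f"{task.M_train + 1 + i:4d}  {p:9.4f}  {t:9.4f}")
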