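"""Fitting the model: regularized least-squares objective and Adam.

The objective is the sum over all training windows of the squared
Euclidean error between predicted and true windows, plus an L2 penalty
lambda * sum of squared Frobenius norms of the weight matrices.  The
training set is tiny (M_train - L + 1 windows), so optimization is
full-batch Adam with early stopping on a training-loss plateau.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, value_of
from .benchmarks import TimeSeriesMatrix
from .errors import DimensionError, TrainingError
from .model import PENALIZED, StnnConfig, StnnParams, init_params, stnn_forward
from .windowing import (
    ForecastTask,
    Normalizer,
    make_training_triples,
    triples_as_arrays,
)

__all__ = ["TrainConfig", "TrainReport", "sti_loss", "train", "FittedStnn", "fit_forecaster"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 3000
    learning_rate: float = 1e-2
    lambda_reg: float = 1e-4
    batch: int | str = "full"
    seed: int = 0
    early_stop_patience: int | None = 200
    log_every: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise TrainingError("learning rate must be positive")
        if self.epochs < 1:
            raise TrainingError("epochs must be >= 1")


@dataclass
class TrainReport:
    loss_history: list[float] = field(default_factory=list)
    final_loss: float = float("nan")
    n_triples: int = 0
    seed: int = 0
    wall_time: float = 0.0


def sti_loss(predictions, targets, params: StnnParams | None = None,
             lambda_reg: float = 0.0):
    """Sum of squared window errors + lambda * sum ||W||_F^2.

    Works on ndarrays (returns float) or autodiff Tensors (returns Tensor),
    so the same definition is both the training objective and its oracle
    surface in tests.
    """
    pshape = value_of(predictions).shape
    tshape = np.asarray(targets, dtype=np.float64).shape
    if pshape != tshape:
        raise DimensionError(f"predictions {pshape} vs targets {tshape}")
    diff = predictions - np.asarray(targets, dtype=np.float64)
    loss = ad.tsum(diff * diff)
    if params is not None and lambda_reg:
        for name in PENALIZED:
            if name in params:
                w = params[name]
                loss = loss + lambda_reg * ad.tsum(w * w)
    return loss


def train(triples, model_config: StnnConfig, train_config: TrainConfig
          ) -> tuple[StnnParams, TrainReport]:
    """Full-batch Adam on the windowed training set; fully seeded."""
    if len(triples) < 1:
        raise TrainingError("need at least one training triple")
    x, dec, y = triples_as_arrays(triples)
    params = init_params(model_config).as_tensors()
    lr = train_config.learning_rate
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m_state = {k: np.zeros_like(v.value) for k, v in params.items()}
    v_state = {k: np.zeros_like(v.value) for k, v in params.items()}
    report = TrainReport(n_triples=len(triples), seed=train_config.seed)
    best = np.inf
    best_params = params.copy()
    since_best = 0
    t0 = time.perf_counter()
    for epoch in range(train_config.epochs):
        preds = stnn_forward(x, dec, params, model_config)
        loss = sti_loss(preds, y, params, train_config.lambda_reg)
        loss_val = float(value_of(loss))
        if not np.isfinite(loss_val):
            raise TrainingError(f"loss diverged at epoch {epoch}")
        report.loss_history.append(loss_val)
        if loss_val < best - 1e-12:
            best = loss_val
            best_params = params.copy()
            since_best = 0
        else:
            since_best += 1
            if (train_config.early_stop_patience is not None
                    and since_best >= train_config.early_stop_patience):
                break
        loss.backward()
        t = epoch + 1
        for k, p in params.items():
            g = p.grad
            if g is None:  # parameter unused by this variant
                continue
            m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
            v_state[k] = beta2 * v_state[k] + (1 - beta2) * g * g
            mhat = m_state[k] / (1 - beta1**t)
            vhat = v_state[k] / (1 - beta2**t)
            p.value = p.value - lr * mhat / (np.sqrt(vhat) + eps)
            p.grad = None
    report.final_loss = best
    report.wall_time = time.perf_counter() - t0
    return best_params, report


@dataclass
class FittedStnn:
    """A trained model bound to its task's normalization."""

    params: StnnParams
    config: StnnConfig
    normalizer: Normalizer
    report: TrainReport | None = None

    def predict_window(self, x_state: np.ndarray, decoder_input: np.ndarray) -> np.ndarray:
        """One forward pass on normalized inputs -> normalized (L,) window."""
        return stnn_forward(x_state, decoder_input, self.params.values_only(), self.config)


def fit_forecaster(series: TimeSeriesMatrix, task: ForecastTask,
                   model_config: StnnConfig | None = None,
                   train_config: TrainConfig | None = None) -> FittedStnn:
    """Normalize on the training segment, window, and fit one model."""
    if model_config is None:
        model_config = StnnConfig(D=series.n_variables, L=task.L)
    if train_config is None:
        train_config = TrainConfig()
    if model_config.D != series.n_variables or model_config.L != task.L:
        raise TrainingError("model config does not match series/task dimensions")
    norm = Normalizer(series, task.M_train)
    triples = make_training_triples(series, task, values=norm.transform(series.values))
    params, report = train(triples, model_config, train_config)
    return FittedStnn(params.values_only(), model_config, norm, report)
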