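"""Delay-embedding windows and the autoregressive rolling forecast.

The transformation at the heart of the method maps the full D-dimensional
system state X_t at one time step to the next L values of a single target
variable, Y_t = (y_t, ..., y_{t+L-1}).  A series of M_train observed steps
therefore yields M_train - L + 1 supervised samples — the sample-size
expansion that makes short series learnable.

During training the decoder is teacher-forced with the zero-prefixed window
Ybar_t = (0, y_t, ..., y_{t+L-2}); the leading zero keeps the map causal.
At forecast time the model's own predictions are fed back into Ybar
(autoregressive rolling forecast), producing the L-1 unobserved values
y_{M+1}, ..., y_{M+L-1}.

Indexing note: the implementation is 0-based throughout; a triple with
``t = k`` covers observed steps k .. k+L-1 (the field convention writes the
same triple with t = k+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .benchmarks import TimeSeriesMatrix
from .errors import ConfigurationError, WindowError

__all__ = [
    "ForecastTask",
    "TrainingTriple",
    "Normalizer",
    "make_training_triples",
    "triples_as_arrays",
    "rolling_forecast",
]


@dataclass(frozen=True)
class ForecastTask:
    """Which variable to predict, with what window, from how much data."""

    target: int | str
    L: int
    M_train: int

    def __post_init__(self):
        if self.L < 2:
            raise WindowError("embedded dimension L must be >= 2")
        if self.L > self.M_train:
            raise WindowError(f"L={self.L} exceeds M_train={self.M_train}")

    @property
    def horizon(self) -> int:
        """Number of predicted future steps (window length minus one)."""
        return self.L - 1

    def validate(self, series: TimeSeriesMatrix) -> int:
        """Check the task against a series; returns the target row index."""
        if self.M_train > series.n_steps:
            raise WindowError(
                f"M_train={self.M_train} exceeds series length {series.n_steps}"
            )
        return series.variable_index(self.target)


@dataclass(frozen=True)
class TrainingTriple:
    """One supervised sample (X_t, Ybar_t, Y_t) at 0-based start step t."""

    x_state: np.ndarray  # (D,) all variables at step t
    decoder_input: np.ndarray  # (L,) = (0, y_t, ..., y_{t+L-2})
    target_window: np.ndarray  # (L,) = (y_t, ..., y_{t+L-1})
    t: int


class Normalizer:
    """Per-variable min-max map onto [0, 1], fitted on the training segment.

    The output head ends in an ELU, whose range is (-1, inf): any target
    value at or below -1 would be unreachable.  Scaling each variable's
    training range onto [0, 1] keeps every reachable target comfortably
    inside the head's range (z-scoring would not — standardized
    oscillations routinely cross -1).  Test information never leaks because
    the extrema come from the first M_train steps alone.
    """

    def __init__(self, series: TimeSeriesMatrix, m_train: int):
        seg = series.values[:, :m_train]
        self.lo = seg.min(axis=1, keepdims=True)
        span = seg.max(axis=1, keepdims=True) - self.lo
        self.span = np.where(span > 0, span, 1.0)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.lo) / self.span

    def inverse_target(self, y: np.ndarray, target_idx: int) -> np.ndarray:
        return y * self.span[target_idx, 0] + self.lo[target_idx, 0]


def make_training_triples(
    series: TimeSeriesMatrix, task: ForecastTask, values: np.ndarray | None = None
) -> list[TrainingTriple]:
    """All M_train - L + 1 teacher-forced samples from the observed segment.

    `values` optionally overrides the raw matrix (e.g. with its normalized
    version); shape must match ``series.values``.
    """
    tgt = task.validate(series)
    vals = series.values if values is None else np.asarray(values, dtype=np.float64)
    if vals.shape != series.values.shape:
        raise ConfigurationError("values override must match series shape")
    y = vals[tgt]
    l, m = task.L, task.M_train
    triples = []
    for t in range(m - l + 1):
        window = y[t : t + l].copy()
        dec = np.concatenate([[0.0], window[:-1]])
        triples.append(TrainingTriple(vals[:, t].copy(), dec, window, t))
    return triples


def triples_as_arrays(triples: list[TrainingTriple]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack triples into (T,D), (T,L), (T,L) batches for vectorized training."""
    x = np.stack([tr.x_state for tr in triples])
    dec = np.stack([tr.decoder_input for tr in triples])
    y = np.stack([tr.target_window for tr in triples])
    return x, dec, y


def rolling_forecast(model, series: TimeSeriesMatrix, task: ForecastTask,
                     horizon: int | None = None,
                     stream_covariates: bool = False) -> np.ndarray:
    """Predict y beyond step M_train (raw scale), autoregressively.

    `model` must expose ``predict_window(x_state, decoder_input) -> (L,)``
    operating on normalized values, plus a fitted ``normalizer``.  Each
    roll forms a window ending one step further into the future, fills the
    unobserved tail of the decoder input with earlier predictions, and
    keeps the last element of the output window as the new prediction.

    By default the horizon is L-1 and only data up to M_train is ever read
    from the series (every encoder window then ends inside the observed
    segment).  ``horizon`` may extend the forecast across a longer held-out
    stretch, which requires ``stream_covariates=True``: encoder states for
    steps beyond M_train are taken from the series as if the non-target
    sensors kept streaming, while the target's own future values are always
    replaced by the model's predictions — the quantity being forecast is
    never observed.
    """
    tgt = task.validate(series)
    l, m = task.L, task.M_train
    h = task.horizon if horizon is None else int(horizon)
    if getattr(model, "config", None) is not None:
        if model.config.D != series.n_variables or model.config.L != l:
            raise ConfigurationError(
                f"model built for D={model.config.D}, L={model.config.L}; "
                f"task has D={series.n_variables}, L={l}"
            )
    if h > task.horizon and not stream_covariates:
        raise ConfigurationError(
            f"horizon {h} > L-1 = {task.horizon} requires streaming covariates"
        )
    if stream_covariates and m + h > series.n_steps:
        raise ConfigurationError("series too short for the requested horizon")
    norm = model.normalizer
    n_obs = m + h if stream_covariates else m
    vals = norm.transform(series.values[:, :n_obs]).copy()
    y_obs = vals[tgt, :m].copy()
    vals[tgt, m:] = 0.0  # the target's future never enters the encoder
    preds: list[float] = []  # normalized-scale predictions beyond step m-1
    for k in range(1, h + 1):
        t = m + k - l  # 0-based window start; window covers t .. t+l-1
        hist = []
        for j in range(t, t + l - 1):  # decoder sees y at steps t .. t+l-2
            hist.append(y_obs[j] if j < m else preds[j - m])
        dec = np.concatenate([[0.0], hist])
        x_state = vals[:, t].copy()
        if t >= m:  # streamed covariate column: patch in the predicted target
            x_state[tgt] = preds[t - m]
        out = model.predict_window(x_state, dec)
        preds.append(float(out[-1]))
    return norm.inverse_target(np.asarray(preds), tgt)
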