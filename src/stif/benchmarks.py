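"""Synthetic benchmark dynamical systems.

Two textbook systems serve as fully reproducible stand-ins for real
high-dimensional short-term recordings:

* a frictionless nonlinear pendulum (intrinsic state ``(theta, omega)``)
  lifted to a high-dimensional ambient space by a random orthogonal map,
  mimicking many redundant sensors observing a low-dimensional manifold;
* a chain of unidirectionally coupled Lorenz oscillators, a standard
  chaotic benchmark (3 state variables per oscillator).

Both are integrated with a fixed-step classical 4th-order Runge-Kutta
scheme and are pure functions of their :class:`SimulationSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, IntegrationError, StifError

__all__ = [
    "SimulationSpec",
    "TimeSeriesMatrix",
    "simulate_pendulum",
    "simulate_coupled_lorenz",
    "orthogonal_lift",
    "add_noise",
    "pendulum_benchmark",
    "lorenz_benchmark",
]


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """D variables observed at M time steps (values has shape D x M)."""

    values: np.ndarray
    variable_names: tuple[str, ...]
    time_index: tuple[float, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise DimensionError("values must be a 2-D (D x M) matrix")
        d, m = v.shape
        if d < 1 or m < 2:
            raise DimensionError(f"need D >= 1 and M >= 2, got {d} x {m}")
        if len(self.variable_names) != d:
            raise DimensionError("one name per variable required")
        if len(set(self.variable_names)) != d:
            raise StifError("variable names must be unique")
        if len(self.time_index) != m:
            raise DimensionError("one time stamp per step required")
        if not np.all(np.isfinite(v)):
            raise StifError("series contains missing/non-finite values")

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    def variable_index(self, target) -> int:
        """Resolve a variable given by name or integer position."""
        if isinstance(target, (int, np.integer)):
            if not 0 <= target < self.n_variables:
                raise StifError(f"variable index {target} out of range")
            return int(target)
        try:
            return self.variable_names.index(target)
        except ValueError:
            raise StifError(f"unknown variable {target!r}") from None

    def subset(self, n_first: int) -> "TimeSeriesMatrix":
        """Keep the first `n_first` variables (used by dimension sweeps)."""
        if not 1 <= n_first <= self.n_variables:
            raise DimensionError(f"cannot keep {n_first} of {self.n_variables} variables")
        return TimeSeriesMatrix(
            self.values[:n_first].copy(),
            self.variable_names[:n_first],
            self.time_index,
        )


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to reproduce one benchmark trajectory."""

    system: str  # "pendulum" | "coupled_lorenz"
    n_steps: int = 80
    dt: float = 0.02
    record_every: int = 1
    init: tuple[float, ...] | None = None
    seed: int = 0
    g_over_l: float = 1.0  # pendulum restoring coefficient
    lift_dim: int = 64  # pendulum ambient dimension
    n_oscillators: int = 30  # coupled_lorenz
    coupling: float = 0.1  # coupled_lorenz chain coupling
    sigma: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    transient: int = 0  # integration steps discarded before recording

    def __post_init__(self):
        if self.system not in ("pendulum", "coupled_lorenz"):
            raise StifError(f"unknown system {self.system!r}")
        if self.n_steps < 2:
            raise StifError("n_steps must be >= 2")
        if self.dt <= 0:
            raise StifError("dt must be positive")
        if self.record_every < 1:
            raise StifError("record_every must be >= 1")
        if self.system == "coupled_lorenz" and self.n_oscillators < 1:
            raise StifError("need at least one oscillator")


def _rk4(deriv, state: np.ndarray, dt: float, n_substeps: int, label: str) -> np.ndarray:
    """Advance `state` by n_substeps fixed RK4 steps of size dt."""
    y = state
    # blow-ups surface as one typed error, not a stream of numpy warnings
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(n_substeps):
            k1 = deriv(y)
            k2 = deriv(y + 0.5 * dt * k1)
            k3 = deriv(y + 0.5 * dt * k2)
            k4 = deriv(y + dt * k3)
            y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if not np.all(np.isfinite(y)):
                raise IntegrationError(f"{label}: non-finite state at substep {k}")
    return y


def _integrate(deriv, init: np.ndarray, spec: SimulationSpec, label: str) -> np.ndarray:
    state = np.asarray(init, dtype=np.float64)
    if spec.transient:
        state = _rk4(deriv, state, spec.dt, spec.transient, label)
    out = np.empty((state.size, spec.n_steps))
    out[:, 0] = state
    for i in range(1, spec.n_steps):
        state = _rk4(deriv, state, spec.dt, spec.record_every, label)
        out[:, i] = state
    return out


def _default_init(spec: SimulationSpec, size: int) -> np.ndarray:
    if spec.init is not None:
        init = np.asarray(spec.init, dtype=np.float64)
        if init.size != size:
            raise DimensionError(f"init must have {size} entries, got {init.size}")
        return init
    rng = np.random.default_rng(spec.seed)
    return rng.uniform(-1.0, 1.0, size=size)


def simulate_pendulum(spec: SimulationSpec) -> TimeSeriesMatrix:
    """Frictionless pendulum theta'' = -(g/l) sin(theta), RK4 integrated.

    Returns the intrinsic 2 x M state matrix (rows theta, omega); use
    :func:`orthogonal_lift` for the high-dimensional observation model.
    """
    if spec.system != "pendulum":
        raise StifError("spec.system must be 'pendulum'")
    gl = spec.g_over_l

    def deriv(y):
        return np.array([y[1], -gl * np.sin(y[0])])

    init = _default_init(spec, 2)
    vals = _integrate(deriv, init, spec, "pendulum")
    times = tuple(np.arange(spec.n_steps) * spec.dt * spec.record_every)
    return TimeSeriesMatrix(vals, ("theta", "omega"), times)


def pendulum_energy(series: TimeSeriesMatrix, g_over_l: float = 1.0) -> np.ndarray:
    """Hamiltonian omega^2/2 - (g/l) cos(theta) per recorded step."""
    theta, omega = series.values
    return 0.5 * omega**2 - g_over_l * np.cos(theta)


def simulate_coupled_lorenz(spec: SimulationSpec) -> TimeSeriesMatrix:
    """Chain of Lorenz units coupled unidirectionally through the x equation.

    Unit i >= 1 receives c * x_{i-1} in its x' equation; unit 0 is free, so
    with c=0 every unit is an independent classical Lorenz system.
    """
    if spec.system != "coupled_lorenz":
        raise StifError("spec.system must be 'coupled_lorenz'")
    n = spec.n_oscillators
    sg, rho, beta, c = spec.sigma, spec.rho, spec.beta, spec.coupling

    def deriv(y):
        s = y.reshape(n, 3)
        x, yy, z = s[:, 0], s[:, 1], s[:, 2]
        dx = sg * (yy - x)
        dx[1:] += c * x[:-1]
        dy = x * (rho - z) - yy
        dz = x * yy - beta * z
        return np.column_stack([dx, dy, dz]).ravel()

    init = _default_init(spec, 3 * n)
    vals = _integrate(deriv, init, spec, "coupled_lorenz")
    names = tuple(f"{ax}{i}" for i in range(n) for ax in ("x", "y", "z"))
    times = tuple(np.arange(spec.n_steps) * spec.dt * spec.record_every)
    return TimeSeriesMatrix(vals, names, times)


def orthogonal_lift(states: TimeSeriesMatrix, lift_dim: int, seed: int) -> TimeSeriesMatrix:
    """Embed a d0 x M state matrix into lift_dim dimensions isometrically.

    The lift matrix U (lift_dim x d0) has orthonormal columns obtained by QR
    of a seeded standard-normal draw, so per-snapshot Euclidean norms and
    pairwise inner products are preserved and U' recovers the input.
    """
    d0 = states.n_variables
    if lift_dim < d0:
        raise DimensionError(f"lift_dim {lift_dim} < intrinsic dimension {d0}")
    u = lift_matrix(lift_dim, d0, seed)
    lifted = u @ states.values
    names = tuple(f"v{i}" for i in range(lift_dim))
    return TimeSeriesMatrix(lifted, names, states.time_index)


def lift_matrix(lift_dim: int, d0: int, seed: int) -> np.ndarray:
    """The seeded orthonormal-column lift matrix itself (for inversion)."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((lift_dim, d0))
    q, r = np.linalg.qr(a)
    # fix the sign convention so the map is deterministic across LAPACK builds
    q = q * np.sign(np.diag(r))
    return q


def add_noise(x: TimeSeriesMatrix, sigma: float, seed: int) -> TimeSeriesMatrix:
    """Add seeded Gaussian noise, per-variable SD = sigma * SD(variable)."""
    if sigma < 0:
        raise StifError("noise strength must be non-negative")
    if sigma == 0:
        return x
    rng = np.random.default_rng(seed)
    scale = x.values.std(axis=1, keepdims=True)
    noisy = x.values + sigma * scale * rng.standard_normal(x.values.shape)
    return TimeSeriesMatrix(noisy, x.variable_names, x.time_index)


def pendulum_benchmark(
    n_steps: int = 80,
    lift_dim: int = 64,
    seed: int = 0,
    dt: float = 0.25,
    noise_sigma: float = 0.0,
) -> TimeSeriesMatrix:
    """The lifted-pendulum benchmark series (lift_dim x n_steps).

    The 0.25 time-unit recording interval makes 80 steps span roughly three
    oscillation periods, so held-out windows stay inside the dynamical
    regime seen during training.
    """
    spec = SimulationSpec(system="pendulum", n_steps=n_steps, dt=dt, seed=seed, lift_dim=lift_dim)
    series = orthogonal_lift(simulate_pendulum(spec), lift_dim, seed=seed + 1)
    if noise_sigma:
        series = add_noise(series, noise_sigma, seed=seed + 2)
    return series


def lorenz_benchmark(
    n_steps: int = 80,
    n_oscillators: int = 30,
    seed: int = 0,
    dt: float = 0.01,
    coupling: float = 0.1,
    transient: int = 1000,
    noise_sigma: float = 0.0,
) -> TimeSeriesMatrix:
    """The coupled-Lorenz benchmark series (3*n_oscillators x n_steps).

    A 1000-step transient is discarded so recording starts on the attractor.
    """
    spec = SimulationSpec(
        system="coupled_lorenz",
        n_steps=n_steps,
        dt=dt,
        seed=seed,
        n_oscillators=n_oscillators,
        coupling=coupling,
        transient=transient,
    )
    series = simulate_coupled_lorenz(spec)
    if noise_sigma:
        series = add_noise(series, noise_sigma, seed=seed + 2)
    return series
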