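"""Continuous driving signals on a uniform time grid.

The driver of the observed oscillator is an Ornstein-Uhlenbeck (OU) process

    dp = -(p / tau) dt + epsilon sqrt(2 / tau) dW,

a stationary Gaussian process with autocovariance
``<p(t) p(t')> = epsilon^2 exp(-|t - t'| / tau)``: ``epsilon`` sets the
amplitude and ``tau`` the correlation time.  A white-noise driver with
dt-independent integrated intensity is provided as the short-correlation
limit.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .exceptions import GridMismatchError, InvalidParameterError

__all__ = [
    "TimeGrid",
    "NoiseConfig",
    "DrivingSignal",
    "generate_ou",
    "generate_white",
    "generate",
]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid t_i = t0 + i dt, i = 0..n_samples-1."""

    t0: float
    dt: float
    n_samples: int

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise InvalidParameterError(f"dt must be positive, got {self.dt}")
        if self.n_samples < 2:
            raise InvalidParameterError(
                f"need at least 2 samples, got {self.n_samples}")

    @classmethod
    def from_duration(cls, t_sim: float, dt: float, t0: float = 0.0) -> "TimeGrid":
        """Grid covering [t0, t0 + t_sim] inclusive of both endpoints."""
        return cls(t0=t0, dt=dt, n_samples=int(round(t_sim / dt)) + 1)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.n_samples - 1)

    @property
    def duration(self) -> float:
        return self.dt * (self.n_samples - 1)


@dataclass(frozen=True)
class NoiseConfig:
    """Driver parameters: amplitude ``epsilon``, correlation time ``tau``
    (OU only), RNG ``seed`` and ``kind`` in {"ou", "white"}."""

    epsilon: float
    tau: float | None = None
    seed: int = 0
    kind: str = "ou"

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise InvalidParameterError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.kind not in ("ou", "white"):
            raise InvalidParameterError(f"unknown noise kind {self.kind!r}")
        if self.kind == "ou" and (self.tau is None or not self.tau > 0):
            raise InvalidParameterError(
                f"OU noise requires tau > 0, got {self.tau}")


@dataclass
class DrivingSignal:
    """A sampled driver p(t) plus the grid and generator metadata."""

    grid: TimeGrid
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_samples,):
            raise GridMismatchError(
                f"signal length {self.values.shape} does not match grid "
                f"({self.grid.n_samples} samples)")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("driving signal contains non-finite values")

    # -- CSV round trip (two columns, '# meta:' JSON header) ----------------

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            meta = dict(self.meta)
            meta.update(t0=self.grid.t0, dt=self.grid.dt,
                        n_samples=self.grid.n_samples)
            fh.write("# meta: " + json.dumps(meta) + "\n")
            fh.write("time,p\n")
            t = self.grid.times
            buf = io.StringIO()
            np.savetxt(buf, np.column_stack([t, self.values]),
                       fmt="%.17g", delimiter=",")
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "DrivingSignal":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# meta:"):
                raise InvalidParameterError(
                    f"{path}: missing '# meta:' header line")
            meta = json.loads(first[len("# meta:"):])
            data = np.loadtxt(fh, delimiter=",", skiprows=1, ndmin=2)
        grid = TimeGrid(t0=meta.pop("t0"), dt=meta.pop("dt"),
                        n_samples=meta.pop("n_samples"))
        return cls(grid=grid, values=data[:, 1], meta=meta)


def generate_ou(config: NoiseConfig, grid: TimeGrid) -> DrivingSignal:
    """Sample an OU path with the exact Gauss-Markov update.

    The one-step transition p_{i+1} = p_i e^{-dt/tau} + epsilon
    sqrt(1 - e^{-2 dt/tau}) N(0, 1) has the exact marginals of the continuous
    process at any dt, so no discretization bias enters downstream
    experiments.  The initial condition is drawn from the stationary law
    N(0, epsilon^2).
    """
    if config.kind != "ou":
        raise InvalidParameterError(f"expected kind='ou', got {config.kind!r}")
    rng = np.random.default_rng(config.seed)
    n = grid.n_samples
    if config.epsilon == 0.0:
        values = np.zeros(n)
    else:
        rho = np.exp(-grid.dt / config.tau)
        innovation_sd = config.epsilon * np.sqrt(1.0 - rho * rho)
        z = rng.standard_normal(n)
        # AR(1) recursion p_i = rho p_{i-1} + e_i as a linear filter
        e = innovation_sd * z
        e[0] = config.epsilon * z[0]
        values = lfilter([1.0], [1.0, -rho], e)
    meta = {"kind": "ou", "epsilon": config.epsilon, "tau": config.tau,
            "seed": config.seed}
    return DrivingSignal(grid=grid, values=values, meta=meta)


def generate_white(config: NoiseConfig, grid: TimeGrid) -> DrivingSignal:
    """Sample a discrete white-noise driver.

    Values are i.i.d. N(0, (epsilon / sqrt(dt))^2), so integrals of p over a
    fixed window have dt-independent variance epsilon^2 * window: the sampled
    signal approximates white noise of intensity epsilon.
    """
    if config.kind != "white":
        raise InvalidParameterError(f"expected kind='white', got {config.kind!r}")
    rng = np.random.default_rng(config.seed)
    if config.epsilon == 0.0:
        values = np.zeros(grid.n_samples)
    else:
        values = rng.normal(0.0, config.epsilon / np.sqrt(grid.dt),
                            grid.n_samples)
    meta = {"kind": "white", "epsilon": config.epsilon, "seed": config.seed}
    return DrivingSignal(grid=grid, values=values, meta=meta)


def generate(config: NoiseConfig, grid: TimeGrid) -> DrivingSignal:
    """Dispatch on ``config.kind``."""
    if config.kind == "ou":
        return generate_ou(config, grid)
    return generate_white(config, grid)
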