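"""Test oscillators driven by a continuous signal.

Three systems are provided:

* the pure phase model  d(phi)/dt = omega + Z(phi) p(t), with parametric
  type-I / type-II phase response curves;
* the Morris-Lecar conductance-based neuron, forced through the voltage
  equation;
* the van der Pol oscillator x'' - 2 (1 - x^2) x' + x = p(t).

For the planar models time is rescaled so that the unperturbed period is 1
(natural frequency 2 pi): the autonomous vector field is multiplied by the
unperturbed period T0, and the driver acts additively on the forced
component in rescaled time.  All integrations use classical fixed-step RK4
on the driver grid with the driver held piecewise-linear between samples, so
events and driver samples stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable

import numpy as np

from . import _kernels as K
from .exceptions import (IntegrationError, InvalidParameterError,
                         NotOscillatingError)
from .sections import EventTimes
from .signals import DrivingSignal, TimeGrid

__all__ = [
    "ParametricPRC",
    "PhaseModel",
    "MorrisLecarParams",
    "PlanarModel",
    "SimulationResult",
    "TimeRescaling",
    "morris_lecar_model",
    "van_der_pol_model",
    "harmonic_model",
    "simulate_phase_model",
    "simulate_morris_lecar",
    "simulate_van_der_pol",
    "unperturbed_period",
    "normalize_frequency",
    "effective_drive_strength",
]

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# phase response curves (closed-form test shapes)
# ---------------------------------------------------------------------------

def _type1(phi):
    return (1.0 - np.cos(phi)) * np.exp(3.0 * (np.cos(phi - np.pi / 3.0) - 1.0))


def _type2(phi):
    return -np.sin(phi) * np.exp(3.0 * (np.cos(phi - 0.9 * np.pi) - 1.0))


@dataclass
class ParametricPRC:
    """A closed-form 2 pi - periodic phase response curve Z(phi).

    ``type1`` is non-negative (every excitatory input advances the phase);
    ``type2`` changes sign, so an input may advance or delay depending on
    the phase at which it arrives.
    """

    form: str
    func: Callable[[np.ndarray], np.ndarray]

    @classmethod
    def type1(cls) -> "ParametricPRC":
        return cls(form="type1", func=_type1)

    @classmethod
    def type2(cls) -> "ParametricPRC":
        return cls(form="type2", func=_type2)

    @classmethod
    def from_callable(cls, func: Callable) -> "ParametricPRC":
        return cls(form="custom", func=func)

    def __call__(self, phi):
        return self.func(np.asarray(phi, dtype=float))


_EMPTY = np.empty(0)


def prc_numba_spec(prc) -> tuple[int, np.ndarray, np.ndarray]:
    """(code, ca, cb) triple consumed by the compiled kernels."""
    from .inference import FourierPRC  # local import to avoid a cycle

    if isinstance(prc, ParametricPRC):
        if prc.form == "type1":
            return 0, _EMPTY, _EMPTY
        if prc.form == "type2":
            return 1, _EMPTY, _EMPTY
        table = prc(np.linspace(0.0, TWO_PI, 8192, endpoint=False))
        return 3, np.ascontiguousarray(table, dtype=float), _EMPTY
    if isinstance(prc, FourierPRC):
        ca = np.concatenate(([prc.a0], prc.a))
        cb = np.concatenate(([0.0], prc.b))
        return 2, ca, cb
    if callable(prc):
        table = np.asarray(prc(np.linspace(0.0, TWO_PI, 8192, endpoint=False)),
                           dtype=float)
        return 3, np.ascontiguousarray(table), _EMPTY
    raise InvalidParameterError(f"cannot interpret {prc!r} as a PRC")


# ---------------------------------------------------------------------------
# model descriptions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseModel:
    """Pure phase oscillator: d(phi)/dt = omega + Z(phi) p(t)."""

    prc: ParametricPRC
    omega: float = TWO_PI

    def __post_init__(self):
        if not self.omega > 0:
            raise InvalidParameterError(f"omega must be positive, got {self.omega}")


@dataclass(frozen=True)
class MorrisLecarParams:
    """Morris-Lecar conductance model constants (dimensionless units)."""

    I: float = 0.07
    g_L: float = 0.5
    g_K: float = 2.0
    g_Ca: float = 1.33
    V1: float = -0.01
    V2: float = 0.15
    V3: float = 0.1
    V4: float = 0.145
    V_L: float = -0.5
    V_K: float = -0.7
    V_Ca: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.I, self.g_L, self.g_K, self.g_Ca, self.V1,
                         self.V2, self.V3, self.V4, self.V_L, self.V_K,
                         self.V_Ca])


@dataclass(frozen=True)
class PlanarModel:
    """A two-dimensional limit-cycle oscillator usable by the kernels.

    ``forced`` is the state component receiving the additive driver (V for
    Morris-Lecar, x' for van der Pol); ``observable`` is the component
    reported as the measured signal x(t).
    """

    name: str
    code: int
    params: tuple
    forced: int
    observable: int
    default_state: tuple

    @property
    def params_array(self) -> np.ndarray:
        return np.asarray(self.params, dtype=float)


def morris_lecar_model(params: MorrisLecarParams | None = None) -> PlanarModel:
    params = params or MorrisLecarParams()
    return PlanarModel(name="morris_lecar", code=0,
                       params=tuple(params.as_array()), forced=0,
                       observable=0, default_state=(0.0, 0.0))


def van_der_pol_model() -> PlanarModel:
    return PlanarModel(name="vanderpol", code=1, params=(), forced=1,
                       observable=0, default_state=(2.0, 0.0))


def harmonic_model() -> PlanarModel:
    """x'' = -x; period 2 pi.  Useful as an analytic check."""
    return PlanarModel(name="harmonic", code=2, params=(), forced=1,
                       observable=0, default_state=(1.0, 0.0))


# ---------------------------------------------------------------------------
# results and rescaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeRescaling:
    """Multiplicative time-scale making the unperturbed period 1."""

    factor: float

    def __post_init__(self):
        if not self.factor > 0:
            raise InvalidParameterError(
                f"rescaling factor must be positive, got {self.factor}")


def normalize_frequency(unperturbed_period: float) -> TimeRescaling:
    """Rescaling that maps a measured unperturbed period T0 to 1 (omega = 2 pi)."""
    if not unperturbed_period > 0:
        raise InvalidParameterError(
            f"period must be positive, got {unperturbed_period}")
    return TimeRescaling(factor=1.0 / unperturbed_period)


def effective_drive_strength(prc_norm: float, target: float) -> float:
    """Driver amplitude epsilon realizing a requested drive strength
    epsilon * ||Z||, given the L2 norm of the oscillator's PRC."""
    if not prc_norm > 0:
        raise InvalidParameterError(f"PRC norm must be positive, got {prc_norm}")
    return target / prc_norm


@dataclass
class SimulationResult:
    """One driven run: observable, optional true phase/state, driver, events."""

    grid: TimeGrid
    driver: DrivingSignal
    observable: np.ndarray | None = None
    true_phase: np.ndarray | None = None
    state: np.ndarray | None = None
    events: "EventTimes | None" = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_phase_model(prc, omega: float, driver: DrivingSignal,
                         ) -> SimulationResult:
    """Integrate the phase model on the driver grid and emit zero-phase events.

    Events are the instants phi(t_m) = m 2 pi (m >= 1), located by linear
    interpolation between the bracketing samples of the first passage.
    """
    if not omega > 0:
        raise InvalidParameterError(f"omega must be positive, got {omega}")
    code, ca, cb = prc_numba_spec(prc)
    grid = driver.grid
    phi = K.simulate_phase_rk4(omega, code, ca, cb, driver.values, grid.dt, 0.0)
    if not np.all(np.isfinite(phi)):
        raise IntegrationError("phase trajectory diverged")
    steps = np.diff(phi)
    if np.any(np.abs(steps) > np.pi):
        raise IntegrationError(
            "phase advanced more than pi in one step; decrease dt")
    events = _phase_events(grid, phi)
    meta = {"model": "phase", "omega": omega,
            "prc": getattr(prc, "form", "fourier")}
    return SimulationResult(grid=grid, driver=driver, true_phase=phi,
                            events=events, meta=meta)


def _phase_events(grid: TimeGrid, phi: np.ndarray) -> EventTimes:
    """First-passage times of the levels m * 2 pi, linearly interpolated."""
    runmax = np.maximum.accumulate(phi)
    n_levels = int(np.floor(runmax[-1] / TWO_PI))
    if n_levels < 1:
        return EventTimes(times=np.empty(0))
    levels = TWO_PI * np.arange(1, n_levels + 1)
    idx = np.searchsorted(runmax, levels)
    ok = (idx > 0) & (idx < phi.shape[0])
    idx = idx[ok]
    levels = levels[ok]
    lo = phi[idx - 1]
    hi = phi[idx]
    frac = (levels - lo) / (hi - lo)
    times = grid.t0 + grid.dt * (idx - 1 + frac)
    return EventTimes(times=times)


@lru_cache(maxsize=32)
def _cached_period(model: PlanarModel, dt: float) -> float:
    return _measure_period(model, dt=dt)


def unperturbed_period(model: PlanarModel, dt: float = 2e-4) -> float:
    """Period T0 of the autonomous limit cycle (original time units).

    Measured by long integration past the transient, then averaging several
    Poincare returns to a mid-range section of the observable, each crossing
    landed exactly with the Henon time-exchange step.
    """
    return _cached_period(model, dt)


def _measure_period(model: PlanarModel, dt: float, transient: float = 300.0,
                    probe: float = 120.0, n_returns: int = 9) -> float:
    params = model.params_array
    u0, u1 = model.default_state
    u0, u1 = K.integrate_autonomous(model.code, params, 1.0, u0, u1, dt,
                                    int(round(transient / dt)))
    vmin, vmax, u0, u1 = K.autonomous_range(model.code, params, 1.0, u0, u1,
                                            dt, int(round(probe / dt)),
                                            model.observable)
    if vmax - vmin <= 1e-12:
        raise NotOscillatingError(
            f"{model.name}: observable is constant; no limit cycle found")
    thr = 0.5 * (vmin + vmax)
    max_steps = int(round((n_returns + 2) * probe / dt))
    times, _, count = K.section_returns(model.code, params, 1.0, u0, u1, thr,
                                        model.observable, True, dt, n_returns,
                                        max_steps)
    if count < n_returns:
        raise NotOscillatingError(
            f"{model.name}: only {count} section returns found")
    periods = np.diff(times[:count])
    T0 = float(np.mean(periods))
    spread = float(np.max(np.abs(periods - T0)) / T0)
    if spread > 1e-7:
        raise IntegrationError(
            f"{model.name}: period not constant (relative spread {spread:.2e})")
    return T0


def _simulate_planar(model: PlanarModel, driver: DrivingSignal,
                     initial_state: tuple | None, transient: float,
                     ) -> SimulationResult:
    params = model.params_array
    T0 = unperturbed_period(model)
    scale = T0  # vector field multiplier: rescaled period is 1
    dt = driver.grid.dt
    u0, u1 = initial_state if initial_state is not None else model.default_state
    # relax to the cycle without driving (transient in rescaled time units,
    # i.e. in unperturbed periods), then drive
    u0, u1 = K.integrate_autonomous(model.code, params, scale, u0, u1, dt,
                                    int(round(transient / dt)))
    traj = K.simulate_driven(model.code, params, scale, model.forced, u0, u1,
                             driver.values, dt)
    if not np.all(np.isfinite(traj)):
        raise IntegrationError(f"{model.name}: trajectory diverged")
    meta = {"model": model.name, "T0": T0, "rescaling_factor": 1.0 / T0,
            "transient": transient, "params": list(model.params)}
    return SimulationResult(grid=driver.grid, driver=driver,
                            observable=traj[:, model.observable],
                            state=traj, meta=meta)


def simulate_morris_lecar(driver: DrivingSignal,
                          params: MorrisLecarParams | None = None,
                          initial_state: tuple | None = None,
                          transient: float = 10.0) -> SimulationResult:
    """Driven Morris-Lecar run; observable is the membrane voltage V."""
    return _simulate_planar(morris_lecar_model(params), driver, initial_state,
                            transient)


def simulate_van_der_pol(driver: DrivingSignal,
                         initial_state: tuple | None = None,
                         transient: float = 10.0) -> SimulationResult:
    """Driven van der Pol run; observable is x."""
    return _simulate_planar(van_der_pol_model(), driver, initial_state,
                            transient)
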