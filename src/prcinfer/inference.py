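"""Iterative inference of (omega, Z) from events and the driving signal.

The phase model d(phi)/dt = omega + Z(phi) p(t), with Z expanded as a finite
Fourier series

    Z(phi) = a0 + sum_n [a_n cos(n phi) + b_n sin(n phi)],

is integrated over each inter-event interval [t_m, t_{m+1}] (where the phase
gain is by definition 2 pi), which turns the nonlinear fitting problem into
an overdetermined *linear* system in the unknowns
(omega, a0, a_1..a_N, b_1..b_N):

    2 pi = omega T_m + a0 I_m + sum_n [a_n C_{m,n} + b_n S_{m,n}],

with I, C, S integrals of p(t), p(t) cos(n phi(t)), p(t) sin(n phi(t)) over
the interval.  The integrals need the unknown phase, so the scheme iterates:
start from the linear interpolation phi(t) = 2 pi (t - t_m)/T_m, solve the
system by least squares, re-integrate the phase per interval with the fitted
(omega, Z) evaluated on the previous iterate, rescale each interval so it
ends exactly at 2 pi, and repeat.  The raw endpoints psi_m before rescaling
measure how well the current model reproduces the data; their RMS deviation
from 2 pi (Delta_psi) is recorded per iteration and is the built-in
convergence/goodness monitor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from . import _kernels as K
from .exceptions import (GridMismatchError, InsufficientEventsError,
                         IterationDivergenceError, UnderdeterminedSystemError)
from .sections import EventTimes
from .signals import DrivingSignal, TimeGrid

__all__ = [
    "FourierPRC",
    "InferenceConfig",
    "PhaseEstimate",
    "LinearSystem",
    "IterationRecord",
    "PhaseModelFit",
    "initial_phase",
    "assemble_system",
    "solve_system",
    "refine_phase",
    "fit",
]

TWO_PI = 2.0 * np.pi


@dataclass
class FourierPRC:
    """Finite Fourier series phase response curve."""

    a0: float
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.a.shape != self.b.shape:
            raise ValueError("a and b must have the same length")

    @property
    def n_harmonics(self) -> int:
        return int(self.a.size)

    def __call__(self, phi):
        phi = np.asarray(phi, dtype=float)
        n = np.arange(1, self.n_harmonics + 1)
        ang = np.multiply.outer(phi, n)
        return (self.a0 + np.cos(ang) @ self.a + np.sin(ang) @ self.b)

    def curve(self, n_points: int = 512) -> tuple[np.ndarray, np.ndarray]:
        """(phi, Z) on a uniform grid over [0, 2 pi)."""
        phi = np.linspace(0.0, TWO_PI, n_points, endpoint=False)
        return phi, self(phi)

    @classmethod
    def from_coefficients(cls, coeffs: np.ndarray) -> "FourierPRC":
        """From the solution vector [omega, a0, a_1.., b_1..] minus omega."""
        n = (coeffs.size - 1) // 2
        return cls(a0=float(coeffs[0]), a=coeffs[1:1 + n], b=coeffs[1 + n:])

    def to_dict(self) -> dict:
        return {"a0": self.a0, "a": self.a.tolist(), "b": self.b.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FourierPRC":
        return cls(a0=d["a0"], a=np.asarray(d["a"]), b=np.asarray(d["b"]))


@dataclass(frozen=True)
class InferenceConfig:
    """Knobs of the iterative fit.

    n_harmonics: Fourier order N of the PRC expansion.
    n_iterations: fixed number k of solve/refine rounds (no early stopping;
        the Delta_psi trace is exposed instead).
    n_periods: intervals spanning n consecutive periods, with the phase gain
        n 2 pi on the left-hand side; 1 is the standard single-period form.
    ridge: optional Tikhonov penalty on the Fourier coefficients (0 = plain
        least squares).
    min_interval_samples: intervals covering fewer driver samples are dropped
        from the linear system (their quadrature is meaningless).
    self_consistent: evaluate Z on the phase being re-integrated instead of
        on the previous iterate.
    """

    n_harmonics: int = 10
    n_iterations: int = 10
    n_periods: int = 1
    ridge: float = 0.0
    min_interval_samples: int = 5
    self_consistent: bool = False


@dataclass
class PhaseEstimate:
    """Per-interval phase on the driver grid.

    ``phi`` holds, at every grid point inside the event span, the phase since
    the start of its interval (0 at t_m, exactly 2 pi at t_{m+1} after
    rescaling); points outside the span are NaN.  ``psi`` are the raw
    endpoints before rescaling (None for the initial linear interpolation,
    where they are 2 pi by construction).
    """

    events: EventTimes
    phi: np.ndarray
    psi: np.ndarray | None = None


@dataclass
class LinearSystem:
    """Assembled rows of the integrated phase equation."""

    matrix: np.ndarray
    rhs: np.ndarray
    n_harmonics: int
    n_dropped: int = 0


@dataclass
class IterationRecord:
    omega: float
    prc: FourierPRC
    delta_psi: float


@dataclass
class PhaseModelFit:
    """Result of the iterative fit: final (omega, PRC), the per-interval
    phase, and the per-iteration trace."""

    omega: float
    prc: FourierPRC
    phase: PhaseEstimate
    trace: list[IterationRecord]
    config: InferenceConfig

    @property
    def delta_psi_trace(self) -> np.ndarray:
        return np.array([rec.delta_psi for rec in self.trace])

    def to_json(self, path) -> None:
        payload = {
            "omega": self.omega,
            **self.prc.to_dict(),
            "n_harmonics": self.config.n_harmonics,
            "n_iterations": self.config.n_iterations,
            "n_periods": self.config.n_periods,
            "delta_psi_trace": self.delta_psi_trace.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _check_events(events: EventTimes, grid: TimeGrid, minimum: int = 2) -> None:
    if len(events) < minimum:
        raise InsufficientEventsError(
            f"need at least {minimum} events, got {len(events)}")
    if events.times[0] < grid.t0 - 1e-12 or events.times[-1] > grid.t_end + 1e-12:
        raise GridMismatchError("events fall outside the driver grid")


def initial_phase(events: EventTimes, grid: TimeGrid) -> PhaseEstimate:
    """Zeroth approximation: linear interpolation between events,
    phi(t) = 2 pi (t - t_m) / T_m."""
    _check_events(events, grid)
    t = grid.times
    ev = events.times
    phi = np.full(grid.n_samples, np.nan)
    inside = (t >= ev[0]) & (t <= ev[-1])
    m = np.clip(np.searchsorted(ev, t[inside], side="right") - 1, 0,
                len(ev) - 2)
    phi[inside] = TWO_PI * (t[inside] - ev[m]) / (ev[m + 1] - ev[m])
    return PhaseEstimate(events=events, phi=phi, psi=None)


def assemble_system(phase: PhaseEstimate, driver: DrivingSignal,
                    events: EventTimes | None = None, n_harmonics: int = 10,
                    n_periods: int = 1, min_interval_samples: int = 5,
                    ) -> LinearSystem:
    """Build the overdetermined linear system from the current phase.

    Row m: [T_m, int p dt, int p cos(n phi) dt, int p sin(n phi) dt] over
    [t_m, t_{m+n_periods}], trapezoidal quadrature on the driver grid with
    fractional first/last sub-intervals; right-hand side 2 pi n_periods.
    """
    events = events or phase.events
    grid = driver.grid
    _check_events(events, grid, minimum=n_periods + 1)
    A, keep = K.assemble_kernel(phase.phi, driver.values, grid.t0, grid.dt,
                                events.times, n_harmonics, n_periods,
                                min_interval_samples)
    n_dropped = int(np.sum(~keep))
    A = A[keep]
    n_unknowns = 2 * n_harmonics + 2
    if A.shape[0] < n_unknowns:
        raise UnderdeterminedSystemError(
            f"{A.shape[0]} usable intervals < {n_unknowns} unknowns "
            f"(N={n_harmonics}); use more data or fewer harmonics")
    rhs = np.full(A.shape[0], TWO_PI * n_periods)
    return LinearSystem(matrix=A, rhs=rhs, n_harmonics=n_harmonics,
                        n_dropped=n_dropped)


def solve_system(system: LinearSystem, ridge: float = 0.0,
                 ) -> tuple[float, FourierPRC]:
    """Least-squares solution via rank-revealing QR (column pivoting).

    Rank deficiency (e.g. a very slowly varying driver makes the integral
    columns nearly collinear with T_m) triggers a conditioning warning and
    returns the minimum-norm solution.
    """
    A = system.matrix
    rhs = system.rhs
    if ridge > 0.0:
        n_coeff = A.shape[1] - 1  # regularize PRC coefficients, not omega
        reg = np.zeros((n_coeff, A.shape[1]))
        reg[:, 1:] = np.sqrt(ridge) * np.eye(n_coeff)
        A = np.vstack([A, reg])
        rhs = np.concatenate([rhs, np.zeros(n_coeff)])
    sol, _, rank, _ = scipy.linalg.lstsq(A, rhs, lapack_driver="gelsd")
    if rank < A.shape[1]:
        warnings.warn(
            f"linear system is rank deficient ({rank}/{A.shape[1]}); "
            "returning the minimum-norm solution", RuntimeWarning,
            stacklevel=2)
    omega = float(sol[0])
    return omega, FourierPRC.from_coefficients(sol[1:])


def refine_phase(omega: float, prc: FourierPRC, driver: DrivingSignal,
                 events: EventTimes, phase: PhaseEstimate,
                 self_consistent: bool = False) -> PhaseEstimate:
    """Re-integrate the phase per interval with the fitted model.

    Solves d(phi)/dt = omega + Z(phi_prev(t)) p(t) from phi(t_m) = 0 on each
    interval (Z evaluated on the *previous* iterate's phase, which makes the
    right-hand side a known function of time), records the raw endpoints
    psi_m, then rescales phi -> 2 pi phi / psi_m so every interval ends at
    exactly 2 pi.
    """
    if not (np.isfinite(omega) and np.all(np.isfinite(prc.a))
            and np.all(np.isfinite(prc.b)) and np.isfinite(prc.a0)):
        raise IterationDivergenceError("non-finite fit parameters")
    grid = driver.grid
    if self_consistent:
        phi_new, psi = K.refine_selfconsistent_kernel(
            driver.values, grid.t0, grid.dt, events.times, omega, prc.a0,
            prc.a, prc.b)
    else:
        phi_new, psi = K.refine_kernel(
            phase.phi, driver.values, grid.t0, grid.dt, events.times, omega,
            prc.a0, prc.a, prc.b)
    n_bad = int(np.sum(psi <= 0.0))
    if n_bad:
        # isolated unscalable intervals keep the previous phase and degrade
        # Delta_psi honestly; a widespread pathology means the fit diverged
        if n_bad > 0.1 * psi.size:
            raise IterationDivergenceError(
                f"{n_bad}/{psi.size} intervals ended at psi <= 0; "
                "the fitted model is pathological (driving too strong?)")
        warnings.warn(
            f"{n_bad}/{psi.size} intervals ended at psi <= 0 and were not "
            "rescaled", RuntimeWarning, stacklevel=2)
    return PhaseEstimate(events=events, phi=phi_new, psi=psi)


def _rms_psi_deviation(psi: np.ndarray) -> float:
    return float(np.sqrt(np.mean((psi - TWO_PI) ** 2)))


def fit(events: EventTimes, driver: DrivingSignal,
        config: InferenceConfig | None = None) -> PhaseModelFit:
    """Full iterative procedure: initial linear phase, then k rounds of
    [assemble -> least squares -> phase refinement with rescaling]."""
    config = config or InferenceConfig()
    phase = initial_phase(events, driver.grid)
    trace: list[IterationRecord] = []
    omega = np.nan
    prc: FourierPRC | None = None
    for _ in range(config.n_iterations):
        system = assemble_system(phase, driver, events,
                                 n_harmonics=config.n_harmonics,
                                 n_periods=config.n_periods,
                                 min_interval_samples=config.min_interval_samples)
        omega, prc = solve_system(system, ridge=config.ridge)
        phase = refine_phase(omega, prc, driver, events, phase,
                             self_consistent=config.self_consistent)
        trace.append(IterationRecord(omega=omega, prc=prc,
                                     delta_psi=_rms_psi_deviation(phase.psi)))
    return PhaseModelFit(omega=omega, prc=prc, phase=phase, trace=trace,
                         config=config)
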