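"""Poincare sections: from a continuous observable to zero-phase events.

Zero-phase events t_m are crossings of a section of the (reconstructed)
phase portrait.  The simplest section is a horizontal threshold on the
observable, parameterized by the relative level theta in (0, 1):
``s_thr = s_min + theta (s_max - s_min)`` with the extrema taken from the
analyzed record.  A better section is generally an *inclined* line in the
derivative embedding (x, x_hat): rotating the embedded cycle by an angle
alpha and thresholding the vertical projection

    s_aux(t) = -x(t) sin(alpha) + x_hat(t) cos(alpha)

lets the section align with the local isochrone.  The convention is anchored
so that alpha = -pi/2 gives s_aux = x, i.e. plain thresholding of the
observable.

Because a badly placed section contaminates every inter-event interval, the
module also provides a search over (theta, alpha) that minimizes the
reconstruction error Delta_psi reported by the iterative fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (InsufficientEventsError, InvalidParameterError,
                         SectionSearchError)
from .signals import DrivingSignal, TimeGrid

__all__ = [
    "SectionSpec",
    "EventTimes",
    "detect_threshold_events",
    "embed_derivative",
    "detect_inclined_events",
    "section_search",
]


@dataclass(frozen=True)
class SectionSpec:
    """Threshold position ``theta`` in (0, 1), optional inclination ``alpha``
    (radians; None = plain threshold on the observable) and crossing sense."""

    theta: float
    alpha: float | None = None
    direction: str = "downward"

    def __post_init__(self):
        if not 0.0 < self.theta < 1.0:
            raise InvalidParameterError(
                f"theta must lie in (0, 1), got {self.theta}")
        if self.direction not in ("downward", "upward"):
            raise InvalidParameterError(
                f"direction must be 'downward' or 'upward', got {self.direction!r}")


@dataclass
class EventTimes:
    """Strictly increasing zero-phase instants t_m."""

    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("event times must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        """Inter-event intervals T_m = t_{m+1} - t_m."""
        return np.diff(self.times)

    def __len__(self) -> int:
        return int(self.times.size)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("t_event\n")
            for t in self.times:
                fh.write(f"{t:.17g}\n")

    @classmethod
    def from_csv(cls, path) -> "EventTimes":
        with open(path) as fh:
            lines = fh.read().splitlines()[1:]
        return cls(times=np.array([float(s) for s in lines if s.strip()]))


def detect_threshold_events(grid: TimeGrid, signal: np.ndarray,
                            spec: SectionSpec, debounce: bool = True,
                            ) -> EventTimes:
    """Threshold crossings of a sampled signal, linearly interpolated.

    The threshold is relative to the observed extrema, so detection is
    invariant under affine rescaling of the signal.  With ``debounce`` a
    minimum separation of a quarter of the median interval suppresses
    noise-induced double crossings near the threshold.
    """
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("signal contains non-finite values")
    s_min = float(np.min(x))
    s_max = float(np.max(x))
    if s_max - s_min <= 0.0:
        raise InsufficientEventsError("signal is constant; no crossings")
    thr = s_min + spec.theta * (s_max - s_min)
    a = x[:-1]
    b = x[1:]
    if spec.direction == "downward":
        hit = (a > thr) & (b <= thr)
    else:
        hit = (a < thr) & (b >= thr)
    idx = np.nonzero(hit)[0]
    if idx.size < 3:
        raise InsufficientEventsError(
            f"only {idx.size} crossings at theta={spec.theta}")
    frac = (thr - a[idx]) / (b[idx] - a[idx])
    times = grid.t0 + grid.dt * (idx + frac)
    if debounce and times.size >= 3:
        times = _debounce(times)
    if times.size < 3:
        raise InsufficientEventsError(
            f"only {times.size} events after debouncing at theta={spec.theta}")
    return EventTimes(times=times)


def _debounce(times: np.ndarray) -> np.ndarray:
    """Greedy minimum-separation filter at 0.25 x median interval."""
    min_sep = 0.25 * float(np.median(np.diff(times)))
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= min_sep:
            kept.append(t)
    return np.asarray(kept)


def embed_derivative(grid: TimeGrid, signal: np.ndarray) -> np.ndarray:
    """Derivative estimate via the five-point central difference.

    x_hat_i = (-x_{i+2} + 8 x_{i+1} - 8 x_{i-1} + x_{i-2}) / (12 dt); exact
    for quartic polynomials, with O(dt^4) error for smooth signals.  The two
    one-sided points at each end are returned as NaN and must be excluded
    from event detection.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 5:
        raise InvalidParameterError("need at least 5 samples for the embedding")
    xhat = np.full_like(x, np.nan)
    xhat[2:-2] = (-x[4:] + 8.0 * x[3:-1] - 8.0 * x[1:-3] + x[:-4]) / (12.0 * grid.dt)
    return xhat


def detect_inclined_events(grid: TimeGrid, signal: np.ndarray,
                           spec: SectionSpec, debounce: bool = True,
                           ) -> EventTimes:
    """Events from an inclined section in the (x, x_hat) embedding.

    Builds s_aux = -x sin(alpha) + x_hat cos(alpha) and thresholds it like a
    plain signal.  alpha = -pi/2 reduces exactly to thresholding x.
    """
    if spec.alpha is None:
        return detect_threshold_events(grid, signal, spec, debounce=debounce)
    x = np.asarray(signal, dtype=float)
    xhat = embed_derivative(grid, x)
    s_aux = -x * np.sin(spec.alpha) + xhat * np.cos(spec.alpha)
    interior = slice(2, -2)
    sub_grid = TimeGrid(t0=grid.t0 + 2 * grid.dt, dt=grid.dt,
                        n_samples=grid.n_samples - 4)
    return detect_threshold_events(sub_grid, s_aux[interior], spec,
                                   debounce=debounce)


def section_search(grid: TimeGrid, signal: np.ndarray, driver: DrivingSignal,
                   theta_grid=None, alpha_grid=None, config=None,
                   direction: str = "downward",
                   ) -> tuple[SectionSpec, pd.DataFrame]:
    """Scan sections and pick the one minimizing Delta_psi.

    For every (theta, alpha) grid point events are detected, the full
    iterative fit is run on (events, driver), and the final Delta_psi is
    recorded.  Grid points with too few events (the section misses the
    cycle) are marked invalid.  Returns the argmin spec and a tidy error
    surface with columns (theta, alpha, delta_psi, valid).
    """
    from .inference import InferenceConfig, fit  # deferred: avoids a cycle

    if theta_grid is None:
        theta_grid = np.arange(0.05, 0.951, 0.05)
    alphas = [None] if alpha_grid is None else list(alpha_grid)
    config = config or InferenceConfig()

    rows = []
    best = None
    best_err = np.inf
    for theta in theta_grid:
        for alpha in alphas:
            spec = SectionSpec(theta=float(theta),
                               alpha=None if alpha is None else float(alpha),
                               direction=direction)
            try:
                events = detect_inclined_events(grid, signal, spec)
                result = fit(events, driver, config)
                dpsi = result.trace[-1].delta_psi
                valid = True
            except Exception:
                dpsi = np.nan
                valid = False
            rows.append({"theta": spec.theta,
                         "alpha": np.nan if alpha is None else spec.alpha,
                         "delta_psi": dpsi, "valid": valid})
            if valid and dpsi < best_err:
                best_err = dpsi
                best = spec
    surface = pd.DataFrame(rows)
    if best is None:
        raise SectionSearchError("no valid section on the search grid")
    return best, surface
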