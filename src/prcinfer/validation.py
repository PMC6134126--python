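"""Ground truth and error measures.

Reconstruction quality is judged by three numbers:

* Delta_Z = ||Z_true - Z_rec|| / ||Z_true|| (L2 norm over one period) —
  requires the true PRC, so it is available only for test models;
* Delta_psi = RMS of (psi_m - 2 pi), where psi_m is the re-integrated phase
  at the end of interval m before rescaling — computable from data alone;
* Delta_psi_T = RMS of (<omega> T_m - 2 pi) with <omega> = <2 pi / T_m> —
  the Delta_psi of the trivial constant-frequency predictor, the benchmark
  against which Delta_psi must be small.

The true PRC of a simulated oscillator is measured with the standard
perturbative protocol: land exactly on the zero-phase section (Henon's
time-exchange step), deliver an instantaneous weak kick at a known phase,
and convert the transient shortening/lengthening of the next n periods into
a phase shift per unit kick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .exceptions import (InvalidParameterError, NotOscillatingError,
                         PerturbationTooStrongError)
from .inference import InferenceConfig, fit
from .oscillators import (ParametricPRC, PhaseModel, PlanarModel,
                          effective_drive_strength, morris_lecar_model,
                          prc_numba_spec, simulate_phase_model,
                          unperturbed_period, van_der_pol_model,
                          _simulate_planar)
from .sections import EventTimes, SectionSpec, detect_inclined_events
from .signals import NoiseConfig, TimeGrid, generate

__all__ = [
    "TruePRC",
    "ErrorReport",
    "l2_norm",
    "delta_Z",
    "delta_psi",
    "delta_psi_T",
    "henon_period",
    "true_prc_perturbation",
    "error_report",
    "run_sweep",
]

TWO_PI = 2.0 * np.pi


@dataclass
class TruePRC:
    """Directly measured PRC on a grid of stimulation phases."""

    phases: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __call__(self, phi):
        """Periodic linear interpolation."""
        phi = np.asarray(phi, dtype=float) % TWO_PI
        xp = np.concatenate([self.phases, [self.phases[0] + TWO_PI]])
        fp = np.concatenate([self.values, [self.values[0]]])
        return np.interp(phi, xp, fp)

    def to_csv(self, path) -> None:
        pd.DataFrame({"phi": self.phases, "Z_true": self.values}).to_csv(
            path, index=False, float_format="%.17g")


@dataclass
class ErrorReport:
    """Error measures of one reconstruction."""

    delta_Z: float
    delta_psi: float
    delta_psi_T: float
    mean_omega: float

    @property
    def ratio(self) -> float:
        """Delta_psi / Delta_psi_T; reconstruction is good when << 1."""
        return self.delta_psi / self.delta_psi_T


def l2_norm(curve, n_points: int = 4096) -> float:
    """L2 functional norm [int_0^{2 pi} f^2 d phi]^{1/2} by composite
    trapezoidal quadrature on a uniform phase grid."""
    phi = np.linspace(0.0, TWO_PI, n_points + 1)
    f = np.asarray(curve(phi), dtype=float)
    return float(np.sqrt(np.trapezoid(f * f, phi)))


def delta_Z(true_prc, fitted, n_points: int = 2048) -> float:
    """Relative L2 distance ||Z_true - Z_rec|| / ||Z_true||."""
    norm_true = l2_norm(true_prc, n_points)
    if norm_true == 0.0:
        raise InvalidParameterError("true PRC has zero norm; Delta_Z undefined")
    diff = lambda phi: np.asarray(true_prc(phi)) - np.asarray(fitted(phi))
    return l2_norm(diff, n_points) / norm_true


def delta_psi(psi: np.ndarray) -> float:
    """RMS deviation of the raw interval endpoints psi_m from 2 pi."""
    psi = np.asarray(psi, dtype=float)
    if psi.size < 1:
        raise InvalidParameterError("need at least one endpoint")
    return float(np.sqrt(np.mean((psi - TWO_PI) ** 2)))


def delta_psi_T(events: EventTimes) -> float:
    """Event irregularity: Delta_psi of the constant-mean-frequency
    predictor, <(<omega> T_m - 2 pi)^2>^{1/2} with <omega> = <2 pi / T_m>."""
    T = events.intervals if isinstance(events, EventTimes) else np.asarray(events)
    if T.size < 2:
        raise InvalidParameterError("need at least 2 intervals")
    mean_omega = float(np.mean(TWO_PI / T))
    return float(np.sqrt(np.mean((mean_omega * T - TWO_PI) ** 2)))


def henon_period(model, dt: float = 2e-4) -> float:
    """Unperturbed period T0.

    For a planar model: integrate the autonomous flow past the transient and
    land every section crossing exactly by exchanging the roles of time and
    the section coordinate for the final step (Henon's method).  For a pure
    phase model the period is 2 pi / omega exactly.
    """
    if isinstance(model, PhaseModel):
        return TWO_PI / model.omega
    if isinstance(model, PlanarModel):
        return unperturbed_period(model, dt=dt)
    raise InvalidParameterError(f"unsupported model {model!r}")


def true_prc_perturbation(model, epsilon: float | None = None, n: int = 5,
                          n_phases: int = 64,
                          section: SectionSpec | None = None,
                          dt: float = 1e-3,
                          extrapolate: bool = True) -> TruePRC:
    """Measure the PRC with the direct perturbation protocol.

    For each stimulation phase phi (proportional to the time from the cycle
    start, i.e. from the zero-phase section crossing) an instantaneous
    additive kick of size ``epsilon`` is applied to the forced variable and
    the next periods T_1..T_n are measured:

        Z(phi) = 2 pi (n T0 - sum_i T_i) / (epsilon T0).

    The result is checked for stability under n -> n + 2 and a warning is
    issued if relaxation was incomplete.  Because the PRC is defined in the
    limit of infinitesimal kicks, with ``extrapolate`` (default) the curve is
    measured at both epsilon and epsilon/2 and Richardson-extrapolated to
    epsilon -> 0 (2 Z_{eps/2} - Z_eps), removing the leading finite-kick
    nonlinearity; set it to False for the raw single-amplitude measurement.
    For the pure phase model the kick acts on the phase itself — a delta
    pulse of area epsilon transports the phase along d(phi)/ds = Z(phi) —
    and the protocol reduces to Z_meas = (phase shift) / epsilon, which
    converges to Z as epsilon -> 0.
    """
    phases = np.linspace(0.0, TWO_PI, n_phases, endpoint=False)
    if isinstance(model, PhaseModel):
        eps = 0.01 if epsilon is None else epsilon
        code, ca, cb = prc_numba_spec(model.prc)
        values = np.array([
            (K.kick_phase(code, ca, cb, phi, eps, 64) - phi) / eps
            for phi in phases])
        meta = {"model": "phase", "epsilon": eps, "n": n}
        return TruePRC(phases=phases, values=values, meta=meta)
    if not isinstance(model, PlanarModel):
        raise InvalidParameterError(f"unsupported model {model!r}")
    return _true_prc_planar(model, epsilon, n, phases, section, dt, extrapolate)


def _true_prc_planar(model: PlanarModel, epsilon, n, phases, section, dt,
                     extrapolate):
    section = section or SectionSpec(theta=0.9, direction="downward")
    params = model.params_array
    T0_orig = unperturbed_period(model)
    scale = T0_orig  # work in rescaled time: period 1, omega 2 pi
    # relax onto the cycle and find the section threshold from cycle extrema
    u0, u1 = model.default_state
    u0, u1 = K.integrate_autonomous(model.code, params, scale, u0, u1, dt,
                                    int(round(20.0 / dt)))
    vmin, vmax, u0, u1 = K.autonomous_range(model.code, params, scale, u0, u1,
                                            dt, int(round(3.0 / dt)),
                                            model.observable)
    thr = vmin + section.theta * (vmax - vmin)
    downward = section.direction == "downward"
    times, states, count = K.section_returns(
        model.code, params, scale, u0, u1, thr, model.observable, downward,
        dt, 3, int(round(8.0 / dt)))
    if count < 3:
        raise NotOscillatingError(f"{model.name}: section not crossed")
    T0 = float(times[2] - times[1])  # rescaled period, ~1 by construction
    u_sec = states[2]

    if epsilon is None:
        # kick ~1% of the cycle's extent in the forced variable
        fmin, fmax, _, _ = K.autonomous_range(
            model.code, params, scale, u_sec[0], u_sec[1], dt,
            int(round(1.5 / dt)), model.forced)
        epsilon = 0.01 * (fmax - fmin)

    n_meas = n + 2  # measure two extra periods for the relaxation check
    max_steps = int(round((n_meas + 3) * T0 / dt))

    def measure(eps):
        vals = np.empty(phases.size)
        vals_n2 = np.empty(phases.size)
        for j, phi in enumerate(phases):
            t_kick = phi / TWO_PI * T0
            cross, count = K.kicked_return_times(
                model.code, params, scale, u_sec[0], u_sec[1], t_kick, eps,
                model.forced, thr, model.observable, downward, dt, n_meas,
                max_steps, 0.5 * T0)
            if count < n_meas:
                raise PerturbationTooStrongError(
                    f"{model.name}: trajectory lost after kick at phase {phi:.3f}")
            vals[j] = TWO_PI * (n * T0 - cross[n - 1]) / (eps * T0)
            vals_n2[j] = TWO_PI * (n_meas * T0 - cross[n_meas - 1]) / (eps * T0)
        return vals, vals_n2

    values, values_n2 = measure(epsilon)
    if extrapolate:
        values_half, values_half_n2 = measure(0.5 * epsilon)
        values = 2.0 * values_half - values
        values_n2 = 2.0 * values_half_n2 - values_n2
    drift = float(np.max(np.abs(values - values_n2)))
    tol = 1e-3 * max(1.0, float(np.max(np.abs(values))))
    if drift > tol:
        warnings.warn(
            f"{model.name}: true PRC changed by {drift:.2e} between n={n} "
            f"and n={n + 2}; relaxation may be incomplete", RuntimeWarning,
            stacklevel=2)
    meta = {"model": model.name, "epsilon": epsilon, "n": n, "T0": T0_orig,
            "theta": section.theta}
    return TruePRC(phases=phases, values=values, meta=meta)


def error_report(true_prc, fit_result, events: EventTimes) -> ErrorReport:
    """Bundle the three error measures for one reconstruction."""
    dz = np.nan if true_prc is None else delta_Z(true_prc, fit_result.prc)
    dpsi = fit_result.trace[-1].delta_psi
    dpsiT = delta_psi_T(events)
    mean_omega = float(np.mean(TWO_PI / events.intervals))
    return ErrorReport(delta_Z=dz, delta_psi=dpsi, delta_psi_T=dpsiT,
                       mean_omega=mean_omega)


# ---------------------------------------------------------------------------
# sweep harness
# ---------------------------------------------------------------------------

_PHASE_MODELS = {"phase1": ParametricPRC.type1, "phase2": ParametricPRC.type2}
_PLANAR_MODELS = {"morris_lecar": morris_lecar_model,
                  "vanderpol": van_der_pol_model}


def _resolve_model(name: str):
    if name in _PHASE_MODELS:
        return PhaseModel(prc=_PHASE_MODELS[name]())
    if name in _PLANAR_MODELS:
        return _PLANAR_MODELS[name]()
    raise InvalidParameterError(
        f"unknown model {name!r}; choose from "
        f"{sorted(_PHASE_MODELS) + sorted(_PLANAR_MODELS)}")


def single_run(model_name: str, drive_strength: float, tau: float,
               t_sim: float, seed: int, dt: float = 1e-3,
               theta: float = 0.9, kind: str = "ou",
               config: InferenceConfig | None = None,
               true_prc=None, prc_norm: float | None = None,
               transient: float = 10.0) -> tuple[ErrorReport, "PhaseModelFit"]:
    """One simulate -> detect -> fit -> score pipeline run.

    ``drive_strength`` is the paper-style epsilon * ||Z|| convention;
    ``true_prc``/``prc_norm`` may be supplied to avoid recomputing the
    ground truth (they are derived from the model otherwise).
    """
    config = config or InferenceConfig()
    model = _resolve_model(model_name)
    section = SectionSpec(theta=theta, direction="downward")
    if true_prc is None:
        if isinstance(model, PhaseModel):
            true_prc = model.prc
        else:
            true_prc = true_prc_perturbation(model, section=section, dt=dt)
    if prc_norm is None:
        prc_norm = l2_norm(true_prc)
    epsilon = effective_drive_strength(prc_norm, drive_strength)
    grid = TimeGrid.from_duration(t_sim, dt)
    driver = generate(NoiseConfig(epsilon=epsilon, tau=tau, seed=seed,
                                  kind=kind), grid)
    if isinstance(model, PhaseModel):
        sim = simulate_phase_model(model.prc, model.omega, driver)
        events = sim.events
    else:
        sim = _simulate_planar(model, driver, None, transient)
        events = detect_inclined_events(grid, sim.observable, section)
    fit_result = fit(events, driver, config)
    return error_report(true_prc, fit_result, events), fit_result


def run_sweep(experiment: str, grid_values, n_seeds: int, base_config: dict,
              seed: int = 0) -> pd.DataFrame:
    """Run a parameter sweep and return a tidy results table.

    ``experiment`` selects the varied parameter: "amplitude" (drive strength
    epsilon ||Z||), "correlation" (tau), "duration" (t_sim) or "theta"
    (threshold position).  ``base_config`` holds the fixed keys accepted by
    :func:`single_run` (model, drive_strength, tau, t_sim, dt, theta, ...).
    Individual failures are recorded as flagged rows and the sweep continues.
    """
    varied = {"amplitude": "drive_strength", "correlation": "tau",
              "duration": "t_sim", "theta": "theta"}
    if experiment not in varied:
        raise InvalidParameterError(
            f"unknown experiment {experiment!r}; choose from {sorted(varied)}")
    key = varied[experiment]
    base = dict(base_config)
    model_name = base.pop("model")
    inf_kwargs = {k: base.pop(k) for k in
                  ("n_harmonics", "n_iterations", "n_periods")
                  if k in base}
    config = InferenceConfig(**inf_kwargs)
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_seeds)

    # ground truth depends on theta for planar models; cache per theta
    cache: dict[float, tuple] = {}

    def truth(theta):
        if theta not in cache:
            model = _resolve_model(model_name)
            if isinstance(model, PhaseModel):
                tp = model.prc
            else:
                tp = true_prc_perturbation(
                    model, section=SectionSpec(theta=theta),
                    dt=base.get("dt", 1e-3))
            cache[theta] = (tp, l2_norm(tp))
        return cache[theta]

    rows = []
    for value in grid_values:
        run_kwargs = dict(base)
        run_kwargs[key] = value
        theta = run_kwargs.get("theta", 0.9)
        for s in seeds:
            row = {"parameter": value, "seed": int(s)}
            try:
                tp, norm = truth(theta)
                report, _ = single_run(model_name, config=config,
                                       seed=int(s), true_prc=tp,
                                       prc_norm=norm, **run_kwargs)
                row.update(delta_Z=report.delta_Z,
                           delta_psi=report.delta_psi,
                           delta_psi_T=report.delta_psi_T,
                           ratio=report.ratio,
                           mean_omega=report.mean_omega, failed=False,
                           message="")
            except Exception as exc:  # noqa: BLE001 - record and continue
                row.update(delta_Z=np.nan, delta_psi=np.nan,
                           delta_psi_T=np.nan, ratio=np.nan,
                           mean_omega=np.nan, failed=True,
                           message=f"{type(exc).__name__}: {exc}")
            rows.append(row)
    return pd.DataFrame(rows)
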