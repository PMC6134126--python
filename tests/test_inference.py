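"""The iterative linear-system fit: exact reductions, oracle recovery,
pass-through consistency and determinism."""

import numpy as np
import pytest

from prcinfer import (EventTimes, FourierPRC, InferenceConfig, NoiseConfig,
                      ParametricPRC, TimeGrid, UnderdeterminedSystemError,
                      assemble_system, fit, generate_ou, initial_phase,
                      refine_phase, simulate_phase_model, solve_system)
from prcinfer.inference import LinearSystem, PhaseEstimate
from prcinfer.signals import DrivingSignal

from conftest import drive_epsilon

TWO_PI = 2.0 * np.pi


def zero_driver(t_sim=12.0, dt=0.001):
    grid = TimeGrid.from_duration(t_sim, dt)
    return DrivingSignal(grid=grid, values=np.zeros(grid.n_samples),
                         meta={"kind": "const"})


def integer_events(n=12):
    return EventTimes(times=np.arange(n, dtype=float))


def exact_phase_from_simulation(sim):
    """Per-interval phase (0 at each event) from a phase-model run."""
    ev = sim.events.times
    t = sim.grid.times
    phi = np.full_like(sim.true_phase, np.nan)
    inside = (t >= ev[0]) & (t <= ev[-1])
    m = np.clip(np.searchsorted(ev, t[inside], side="right") - 1, 0,
                len(ev) - 2)
    phi[inside] = sim.true_phase[inside] - TWO_PI * (m + 1)
    return PhaseEstimate(events=sim.events, phi=phi, psi=None)


# -- initial phase ----------------------------------------------------------

def test_initial_phase_linear_interpolation():
    grid = TimeGrid.from_duration(3.0, 0.001)
    phase = initial_phase(EventTimes(times=np.array([0.0, 1.0, 3.0])), grid)
    i = lambda t: int(round(t / grid.dt))
    assert phase.phi[i(0.0)] == pytest.approx(0.0)
    assert phase.phi[i(0.5)] == pytest.approx(np.pi)
    assert phase.phi[i(2.0)] == pytest.approx(np.pi)  # second interval midpoint
    assert phase.phi[i(0.999)] == pytest.approx(TWO_PI * 0.999, rel=1e-9)


# -- assemble ---------------------------------------------------------------

def test_assemble_unperturbed_reduces_to_omega_column():
    driver = zero_driver()
    events = integer_events()
    system = assemble_system(initial_phase(events, driver.grid), driver,
                             n_harmonics=2)
    assert np.allclose(system.matrix[:, 0], 1.0)
    assert np.allclose(system.matrix[:, 1:], 0.0)
    assert np.allclose(system.rhs, TWO_PI)


def test_assemble_constant_drive_orthogonality():
    """With exact linear phase, int c cos(n phi) dt over a full cycle
    vanishes; only the T and int p columns survive."""
    grid = TimeGrid.from_duration(12.0, 0.001)
    c = 0.7
    driver = DrivingSignal(grid=grid, values=np.full(grid.n_samples, c),
                           meta={"kind": "const"})
    events = integer_events()
    system = assemble_system(initial_phase(events, grid), driver,
                             n_harmonics=3)
    assert np.allclose(system.matrix[:, 0], 1.0)
    assert np.allclose(system.matrix[:, 1], c * 1.0, rtol=1e-9)
    assert np.max(np.abs(system.matrix[:, 2:])) < 1e-6  # quadrature error


def test_assemble_matches_oversampled_quadrature(type2_prc):
    """Trapezoidal integrals on the driver grid agree with a 10x finer
    quadrature of the same integrand to O(dt^2)."""
    eps = drive_epsilon(type2_prc, 3.0)
    grid = TimeGrid.from_duration(30.0, 0.001)
    driver = generate_ou(NoiseConfig(epsilon=eps, tau=0.1, seed=31), grid)
    sim = simulate_phase_model(type2_prc, TWO_PI, driver)
    phase = exact_phase_from_simulation(sim)
    system = assemble_system(phase, driver, n_harmonics=3)

    ev = sim.events.times
    t = grid.times
    row = 5
    ta, tb = ev[row], ev[row + 1]
    fine_t = np.linspace(ta, tb, 10_001)
    p_f = np.interp(fine_t, t, driver.values)
    # interpolate the phase from nodes of this interval only (it resets
    # across events): endpoints carry exactly 0 and 2 pi
    inner = (t > ta) & (t < tb)
    nodes = np.concatenate([[ta], t[inner], [tb]])
    vals = np.concatenate([[0.0], phase.phi[inner], [TWO_PI]])
    phi_f = np.interp(fine_t, nodes, vals)
    expected = np.trapezoid(p_f * np.cos(phi_f), fine_t)
    assert system.matrix[row, 2] == pytest.approx(expected, abs=5e-5)


def test_assemble_underdetermined_raises():
    driver = zero_driver(t_sim=5.0)
    events = EventTimes(times=np.arange(5, dtype=float))
    with pytest.raises(UnderdeterminedSystemError):
        assemble_system(initial_phase(events, driver.grid), driver,
                        n_harmonics=10)


# -- solve ------------------------------------------------------------------

def test_solve_unperturbed_recovers_omega_with_zero_prc():
    driver = zero_driver()
    system = assemble_system(initial_phase(integer_events(), driver.grid),
                             driver, n_harmonics=2)
    with pytest.warns(RuntimeWarning, match="rank deficient"):
        omega, prc = solve_system(system)
    assert omega == pytest.approx(TWO_PI, rel=1e-12)
    assert prc.a0 == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(prc.a, 0.0) and np.allclose(prc.b, 0.0)


def test_solve_invariant_under_row_duplication(type2_prc):
    eps = drive_epsilon(type2_prc, 3.0)
    grid = TimeGrid.from_duration(40.0, 0.001)
    driver = generate_ou(NoiseConfig(epsilon=eps, tau=0.1, seed=13), grid)
    sim = simulate_phase_model(type2_prc, TWO_PI, driver)
    system = assemble_system(initial_phase(sim.events, grid), driver,
                             n_harmonics=3)
    omega1, prc1 = solve_system(system)
    doubled = LinearSystem(matrix=np.vstack([system.matrix, system.matrix]),
                           rhs=np.concatenate([system.rhs, system.rhs]),
                           n_harmonics=3)
    omega2, prc2 = solve_system(doubled)
    assert omega1 == pytest.approx(omega2, rel=1e-10)
    assert np.allclose(prc1.a, prc2.a, rtol=1e-8, atol=1e-12)


def test_oracle_recovery_with_true_phase():
    """When the generator PRC is an exact order-N Fourier polynomial and the
    true phase is supplied, all 2N+2 parameters come back to < 1e-3
    relative (quadrature-limited)."""
    gen = FourierPRC(a0=0.3, a=[0.2, -0.1, 0.05], b=[-0.15, 0.08, 0.02])
    grid = TimeGrid.from_duration(200.0, 0.001)
    driver = generate_ou(NoiseConfig(epsilon=1.0, tau=0.1, seed=11), grid)
    sim = simulate_phase_model(gen, TWO_PI, driver)
    phase = exact_phase_from_simulation(sim)
    system = assemble_system(phase, driver, n_harmonics=3)
    omega, prc = solve_system(system)

    truth = np.concatenate([[TWO_PI, gen.a0], gen.a, gen.b])
    fitted = np.concatenate([[omega, prc.a0], prc.a, prc.b])
    assert np.linalg.norm(fitted - truth) / np.linalg.norm(truth) < 1e-3


# -- refine -----------------------------------------------------------------

def test_refine_unperturbed_identity():
    driver = zero_driver()
    events = integer_events()
    phase = initial_phase(events, driver.grid)
    prc = FourierPRC(a0=0.0, a=[0.0], b=[0.0])
    refined = refine_phase(TWO_PI, prc, driver, events, phase)
    assert np.allclose(refined.psi, TWO_PI, atol=1e-12)
    inside = ~np.isnan(refined.phi)
    assert np.allclose(refined.phi[inside], phase.phi[inside], atol=1e-9)


def test_refine_ground_truth_pass_through(type2_prc):
    """Exact (omega, Z, phi) from the simulator reproduce psi_m = 2 pi
    within integration tolerance."""
    gen = FourierPRC(a0=0.3, a=[0.2, -0.1, 0.05], b=[-0.15, 0.08, 0.02])
    grid = TimeGrid.from_duration(100.0, 0.001)
    driver = generate_ou(NoiseConfig(epsilon=1.0, tau=0.1, seed=19), grid)
    sim = simulate_phase_model(gen, TWO_PI, driver)
    phase = exact_phase_from_simulation(sim)
    refined = refine_phase(TWO_PI, gen, driver, sim.events, phase)
    assert np.max(np.abs(refined.psi - TWO_PI)) < 1e-3


def test_refine_rescaled_endpoints_are_exactly_two_pi(type2_prc):
    eps = drive_epsilon(type2_prc, 5.0)
    grid = TimeGrid.from_duration(50.0, 0.001)
    driver = generate_ou(NoiseConfig(epsilon=eps, tau=0.1, seed=23), grid)
    sim = simulate_phase_model(type2_prc, TWO_PI, driver)
    result = fit(sim.events, driver, InferenceConfig(n_iterations=2))
    phi = result.phase.phi
    ev = sim.events.times
    grid_t = grid.times
    for tb in ev[1:-1]:
        j = int(np.floor((tb - grid_t[0]) / grid.dt + 1e-9))
        # last grid point of the interval ending at tb carries ~2 pi
        assert phi[j] <= TWO_PI * (1 + 1e-9)
        assert phi[j] > TWO_PI * 0.99


# -- fit --------------------------------------------------------------------

def test_fit_unperturbed_events_give_omega_and_zero_error():
    driver = zero_driver(t_sim=30.0)
    events = EventTimes(times=np.arange(30, dtype=float))
    with pytest.warns(RuntimeWarning, match="rank deficient"):
        result = fit(events, driver, InferenceConfig(n_harmonics=2,
                                                     n_iterations=3))
    assert result.omega == pytest.approx(TWO_PI, rel=1e-12)
    assert result.trace[-1].delta_psi < 1e-12


def test_fit_is_deterministic(type2_prc):
    eps = drive_epsilon(type2_prc, 5.0)
    grid = TimeGrid.from_duration(50.0, 0.001)
    driver = generate_ou(NoiseConfig(epsilon=eps, tau=0.1, seed=29), grid)
    sim = simulate_phase_model(type2_prc, TWO_PI, driver)
    r1 = fit(sim.events, driver)
    r2 = fit(sim.events, driver)
    assert r1.omega == r2.omega
    assert np.array_equal(r1.prc.a, r2.prc.a)
    assert np.array_equal(r1.delta_psi_trace, r2.delta_psi_trace)


def test_fit_iterations_improve_strong_driving(type2_prc):
    """At eps ||Z|| = 5 the first-iteration PRC is visibly off and later
    iterations improve it."""
    from prcinfer import delta_Z
    eps = drive_epsilon(type2_prc, 5.0)
    grid = TimeGrid.from_duration(500.0, 0.001)
    driver = generate_ou(NoiseConfig(epsilon=eps, tau=0.1, seed=41), grid)
    sim = simulate_phase_model(type2_prc, TWO_PI, driver)
    result = fit(sim.events, driver)
    dz = [delta_Z(type2_prc, rec.prc) for rec in result.trace]
    assert dz[-1] < dz[0]
    assert dz[-1] < 0.3


def test_fit_multi_period_variant(type2_prc):
    """n_periods = 2 integrates over T_m^(2) with phase gain 4 pi and still
    recovers the PRC on clean data."""
    from prcinfer import delta_Z
    eps = drive_epsilon(type2_prc, 3.0)
    grid = TimeGrid.from_duration(200.0, 0.001)
    driver = generate_ou(NoiseConfig(epsilon=eps, tau=0.1, seed=43), grid)
    sim = simulate_phase_model(type2_prc, TWO_PI, driver)
    phase = initial_phase(sim.events, grid)
    system = assemble_system(phase, driver, n_harmonics=10, n_periods=2)
    assert np.allclose(system.rhs, 2 * TWO_PI)
    result = fit(sim.events, driver, InferenceConfig(n_periods=2))
    assert delta_Z(type2_prc, result.prc) < 0.5


def test_fit_self_consistent_variant_close_to_default(type2_prc):
    eps = drive_epsilon(type2_prc, 3.0)
    grid = TimeGrid.from_duration(100.0, 0.001)
    driver = generate_ou(NoiseConfig(epsilon=eps, tau=0.1, seed=47), grid)
    sim = simulate_phase_model(type2_prc, TWO_PI, driver)
    default = fit(sim.events, driver)
    sc = fit(sim.events, driver, InferenceConfig(self_consistent=True))
    assert sc.omega == pytest.approx(default.omega, rel=1e-3)
    phi = np.linspace(0, TWO_PI, 256, endpoint=False)
    scale = np.max(np.abs(default.prc(phi)))
    assert np.max(np.abs(sc.prc(phi) - default.prc(phi))) < 0.1 * scale
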