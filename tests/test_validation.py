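"""Error measures, Henon-trick period, direct PRC protocol, sweep harness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prcinfer import (EventTimes, FourierPRC, InvalidParameterError,
                      ParametricPRC, PhaseModel, delta_Z, delta_psi,
                      delta_psi_T, harmonic_model, henon_period, l2_norm,
                      run_sweep, true_prc_perturbation, van_der_pol_model)

TWO_PI = 2.0 * np.pi


# -- norms and metrics ------------------------------------------------------

def test_l2_norm_analytic_values():
    assert l2_norm(np.sin) == pytest.approx(np.sqrt(np.pi), rel=1e-6)
    assert l2_norm(lambda phi: np.ones_like(phi)) == pytest.approx(
        np.sqrt(TWO_PI), rel=1e-9)


def test_delta_Z_reference_points():
    true = ParametricPRC.type1()
    assert delta_Z(true, true) == pytest.approx(0.0, abs=1e-12)
    zero = FourierPRC(a0=0.0, a=[0.0], b=[0.0])
    assert delta_Z(true, zero) == pytest.approx(1.0, rel=1e-9)
    double = lambda phi: 2.0 * true(phi)
    assert delta_Z(true, double) == pytest.approx(1.0, rel=1e-9)
    with pytest.raises(InvalidParameterError):
        delta_Z(zero, true)


def test_delta_psi_arithmetic():
    assert delta_psi(np.full(10, TWO_PI)) == 0.0
    assert delta_psi(np.array([TWO_PI + 0.1, TWO_PI - 0.1])) == pytest.approx(0.1)


def test_delta_psi_T_hand_computed():
    ev = EventTimes(times=np.array([0.0, 0.9, 2.0]))
    T = np.array([0.9, 1.1])
    mean_omega = np.mean(TWO_PI / T)
    expected = np.sqrt(np.mean((mean_omega * T - TWO_PI) ** 2))
    assert delta_psi_T(ev) == pytest.approx(expected, rel=1e-12)
    assert delta_psi_T(EventTimes(times=np.arange(5.0))) == 0.0


@settings(derandomize=True, max_examples=20)
@given(scale=st.floats(0.01, 100.0))
def test_delta_psi_T_scale_invariant(scale):
    times = np.array([0.0, 0.8, 2.1, 2.9, 4.2])
    a = delta_psi_T(EventTimes(times=times))
    b = delta_psi_T(EventTimes(times=scale * times))
    assert a == pytest.approx(b, rel=1e-9)


# -- Henon period -----------------------------------------------------------

def test_henon_period_phase_model_exact():
    model = PhaseModel(prc=ParametricPRC.type2(), omega=TWO_PI)
    assert henon_period(model) == 1.0


def test_henon_period_harmonic_oscillator():
    assert henon_period(harmonic_model()) == pytest.approx(TWO_PI, rel=1e-8)


def test_henon_period_van_der_pol_self_consistent():
    """Successive Henon-landed returns agree to < 1e-8 relative (asserted
    internally by the period measurement); two calls agree exactly."""
    a = henon_period(van_der_pol_model())
    b = henon_period(van_der_pol_model())
    assert a == b
    assert 7.0 < a < 8.5  # the mu = 2 relaxation cycle


# -- direct perturbation protocol ------------------------------------------

def test_true_prc_phase_model_converges_with_epsilon():
    """The kick protocol on the pure phase model recovers the generator PRC,
    with sup-norm error decreasing as the kick weakens."""
    prc = ParametricPRC.type2()
    model = PhaseModel(prc=prc)
    errors = []
    for eps in (0.1, 0.01, 0.001):
        curve = true_prc_perturbation(model, epsilon=eps, n_phases=64)
        errors.append(np.max(np.abs(curve.values - prc(curve.phases))))
    assert errors[0] > errors[1] > errors[2]
    assert errors[2] < 1e-3


def test_true_prc_zero_sensitivity_gives_zero_curve():
    prc = ParametricPRC.from_callable(lambda phi: np.zeros_like(phi))
    curve = true_prc_perturbation(PhaseModel(prc=prc), epsilon=0.05)
    assert np.allclose(curve.values, 0.0, atol=1e-12)


def test_true_prc_kick_linearity_van_der_pol(vdp_true_prc):
    """Halving the kick changes the raw (non-extrapolated) curve by a few
    per cent at most: the kick sits in the linear-response regime."""
    model = van_der_pol_model()
    from prcinfer import SectionSpec
    spec = SectionSpec(theta=0.7)
    eps = vdp_true_prc.meta["epsilon"]
    raw1 = true_prc_perturbation(model, epsilon=eps, section=spec,
                                 extrapolate=False)
    raw2 = true_prc_perturbation(model, epsilon=eps / 2, section=spec,
                                 extrapolate=False)
    scale = np.max(np.abs(raw1.values))
    assert np.max(np.abs(raw1.values - raw2.values)) < 0.05 * scale


def test_true_prc_extrapolation_tightens_vdp(vdp_true_prc):
    """The extrapolated curve is stable: recomputing at half the base kick
    moves it by much less than the raw finite-kick difference."""
    model = van_der_pol_model()
    from prcinfer import SectionSpec
    spec = SectionSpec(theta=0.7)
    eps = vdp_true_prc.meta["epsilon"]
    again = true_prc_perturbation(model, epsilon=eps / 2, section=spec)
    scale = np.max(np.abs(vdp_true_prc.values))
    assert np.max(np.abs(vdp_true_prc.values - again.values)) < 0.02 * scale


def test_true_prc_interpolation_is_periodic(vdp_true_prc):
    assert vdp_true_prc(0.0) == pytest.approx(vdp_true_prc(TWO_PI), rel=1e-12)


# -- sweep harness ----------------------------------------------------------

def test_run_sweep_reproducible_single_seed():
    base = {"model": "phase2", "drive_strength": 3.0, "tau": 0.1,
            "t_sim": 50.0}
    a = run_sweep("amplitude", [1.0, 3.0], n_seeds=1, base_config=base, seed=5)
    b = run_sweep("amplitude", [1.0, 3.0], n_seeds=1, base_config=base, seed=5)
    assert a.equals(b)
    assert set(a.columns) >= {"parameter", "seed", "delta_Z", "delta_psi",
                              "delta_psi_T", "failed"}
    assert not a["failed"].any()


def test_run_sweep_records_failures_and_continues():
    base = {"model": "phase2", "drive_strength": 3.0, "tau": 0.1,
            "t_sim": 50.0, "n_harmonics": 20}
    # 5 time units give ~5 intervals, far fewer than the 42 unknowns
    table = run_sweep("duration", [5.0, 50.0], n_seeds=1, base_config=base)
    assert table[table["parameter"] == 5.0]["failed"].all()
    assert not table[table["parameter"] == 50.0]["failed"].any()
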