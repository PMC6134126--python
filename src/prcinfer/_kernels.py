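"""Numba-compiled inner loops.

Everything here operates on plain float64 arrays; the public modules wrap
these kernels with the domain types.  Conventions shared by all kernels:

* driving signals are sampled on a uniform grid with step ``dt`` and are
  treated as piecewise-linear between samples;
* planar (2-D) oscillator models are identified by an integer code
  (0 = Morris-Lecar, 1 = van der Pol, 2 = harmonic oscillator) with a flat
  parameter vector, and their autonomous vector field may be multiplied by a
  time-rescaling factor ``scale`` so that the unperturbed period becomes 1;
* phase response curves are identified by an integer code
  (0 = parametric type I, 1 = parametric type II, 2 = Fourier series,
  3 = uniform lookup table on [0, 2pi)).
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# phase response curve evaluation
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _prc_scalar(code, ca, cb, phi):
    if code == 0:
        # type I: non-negative, spike-advancing for any input sign
        return (1.0 - np.cos(phi)) * np.exp(3.0 * (np.cos(phi - np.pi / 3.0) - 1.0))
    elif code == 1:
        # type II: sign-changing
        return -np.sin(phi) * np.exp(3.0 * (np.cos(phi - 0.9 * np.pi) - 1.0))
    elif code == 2:
        # finite Fourier series; ca[0] = a0, ca[n] = a_n, cb[n] = b_n
        c1 = np.cos(phi)
        s1 = np.sin(phi)
        c = c1
        s = s1
        out = ca[0]
        for n in range(1, ca.shape[0]):
            out += ca[n] * c + cb[n] * s
            cn = c * c1 - s * s1
            sn = s * c1 + c * s1
            c = cn
            s = sn
        return out
    else:
        # periodic linear interpolation of a table sampled uniformly on [0, 2pi)
        npts = ca.shape[0]
        x = (phi % TWO_PI) / TWO_PI * npts
        i = int(np.floor(x))
        frac = x - i
        i0 = i % npts
        i1 = (i + 1) % npts
        return ca[i0] * (1.0 - frac) + ca[i1] * frac


@njit(cache=True)
def prc_eval_array(code, ca, cb, phis):
    out = np.empty(phis.shape[0])
    for i in range(phis.shape[0]):
        out[i] = _prc_scalar(code, ca, cb, phis[i])
    return out


# ---------------------------------------------------------------------------
# phase model integration
# ---------------------------------------------------------------------------

@njit(cache=True)
def simulate_phase_rk4(omega, code, ca, cb, p, dt, phi0):
    """Integrate d(phi)/dt = omega + Z(phi) p(t) with classical RK4.

    ``p`` is held piecewise-linear between samples, so the half-step value is
    the midpoint average.  Returns the (unwrapped) phase at every grid point.
    """
    n = p.shape[0]
    phi = np.empty(n)
    phi[0] = phi0
    for i in range(n - 1):
        p0 = p[i]
        p1 = p[i + 1]
        pm = 0.5 * (p0 + p1)
        x = phi[i]
        k1 = omega + _prc_scalar(code, ca, cb, x) * p0
        k2 = omega + _prc_scalar(code, ca, cb, x + 0.5 * dt * k1) * pm
        k3 = omega + _prc_scalar(code, ca, cb, x + 0.5 * dt * k2) * pm
        k4 = omega + _prc_scalar(code, ca, cb, x + dt * k3) * p1
        phi[i + 1] = x + dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
    return phi


@njit(cache=True)
def kick_phase(code, ca, cb, phi0, eps, n_steps):
    """Effect of a delta pulse of area ``eps`` on the phase model.

    Through an instantaneous pulse the phase obeys d(phi)/ds = Z(phi) with
    s in [0, eps]; solved with RK4 in the pulse-area variable.
    """
    h = eps / n_steps
    x = phi0
    for _ in range(n_steps):
        k1 = _prc_scalar(code, ca, cb, x)
        k2 = _prc_scalar(code, ca, cb, x + 0.5 * h * k1)
        k3 = _prc_scalar(code, ca, cb, x + 0.5 * h * k2)
        k4 = _prc_scalar(code, ca, cb, x + h * k3)
        x += h * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
    return x


# ---------------------------------------------------------------------------
# planar oscillator models
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _field(code, params, u0, u1):
    """Autonomous vector field of planar model ``code`` at state (u0, u1)."""
    if code == 0:
        # Morris-Lecar: u0 = V, u1 = w
        I = params[0]
        gL = params[1]
        gK = params[2]
        gCa = params[3]
        V1 = params[4]
        V2 = params[5]
        V3 = params[6]
        V4 = params[7]
        VL = params[8]
        VK = params[9]
        VCa = params[10]
        m_inf = 0.5 * (1.0 + np.tanh((u0 - V1) / V2))
        w_inf = 0.5 * (1.0 + np.tanh((u0 - V3) / V4))
        lam = np.cosh((u0 - V3) / (2.0 * V4)) / 3.0
        f0 = I - gL * (u0 - VL) - gK * u1 * (u0 - VK) - gCa * m_inf * (u0 - VCa)
        f1 = lam * (w_inf - u1)
        return f0, f1
    elif code == 1:
        # van der Pol: u0 = x, u1 = dx/dt
        return u1, 2.0 * (1.0 - u0 * u0) * u1 - u0
    else:
        # harmonic oscillator (testing aid)
        return u1, -u0


@njit(cache=True, inline="always")
def _rk4_auto(code, params, scale, u0, u1, h):
    a0, a1 = _field(code, params, u0, u1)
    b0, b1 = _field(code, params, u0 + 0.5 * h * scale * a0, u1 + 0.5 * h * scale * a1)
    c0, c1 = _field(code, params, u0 + 0.5 * h * scale * b0, u1 + 0.5 * h * scale * b1)
    d0, d1 = _field(code, params, u0 + h * scale * c0, u1 + h * scale * c1)
    n0 = u0 + h * scale * (a0 + 2.0 * b0 + 2.0 * c0 + d0) / 6.0
    n1 = u1 + h * scale * (a1 + 2.0 * b1 + 2.0 * c1 + d1) / 6.0
    return n0, n1


@njit(cache=True)
def integrate_autonomous(code, params, scale, u0, u1, dt, n_steps):
    for _ in range(n_steps):
        u0, u1 = _rk4_auto(code, params, scale, u0, u1, dt)
    return u0, u1


@njit(cache=True)
def autonomous_range(code, params, scale, u0, u1, dt, n_steps, comp):
    """Track min/max of one state component along an autonomous run."""
    vmin = u0 if comp == 0 else u1
    vmax = vmin
    for _ in range(n_steps):
        u0, u1 = _rk4_auto(code, params, scale, u0, u1, dt)
        v = u0 if comp == 0 else u1
        if v < vmin:
            vmin = v
        if v > vmax:
            vmax = v
    return vmin, vmax, u0, u1


@njit(cache=True)
def simulate_driven(code, params, scale, forced, u0, u1, p, dt):
    """Integrate the (possibly time-rescaled) planar model with additive
    forcing p(t) on component ``forced``; p piecewise-linear between samples.
    """
    n = p.shape[0]
    traj = np.empty((n, 2))
    traj[0, 0] = u0
    traj[0, 1] = u1
    for i in range(n - 1):
        p0 = p[i]
        p1 = p[i + 1]
        pm = 0.5 * (p0 + p1)
        # RK4 with stage-dependent forcing
        a0, a1 = _field(code, params, u0, u1)
        a0 *= scale
        a1 *= scale
        if forced == 0:
            a0 += p0
        else:
            a1 += p0
        b0, b1 = _field(code, params, u0 + 0.5 * dt * a0, u1 + 0.5 * dt * a1)
        b0 *= scale
        b1 *= scale
        if forced == 0:
            b0 += pm
        else:
            b1 += pm
        c0, c1 = _field(code, params, u0 + 0.5 * dt * b0, u1 + 0.5 * dt * b1)
        c0 *= scale
        c1 *= scale
        if forced == 0:
            c0 += pm
        else:
            c1 += pm
        d0, d1 = _field(code, params, u0 + dt * c0, u1 + dt * c1)
        d0 *= scale
        d1 *= scale
        if forced == 0:
            d0 += p1
        else:
            d1 += p1
        u0 = u0 + dt * (a0 + 2.0 * b0 + 2.0 * c0 + d0) / 6.0
        u1 = u1 + dt * (a1 + 2.0 * b1 + 2.0 * c1 + d1) / 6.0
        traj[i + 1, 0] = u0
        traj[i + 1, 1] = u1
    return traj


@njit(cache=True)
def _henon_step(code, params, scale, t, u0, u1, thr, comp):
    """Single RK4 step with the section coordinate as independent variable.

    Starting from a state just *before* a crossing of component ``comp``
    through ``thr``, exchange the roles of time and the section coordinate
    (Henon's trick) and step exactly onto the section.  Returns the crossing
    time and the full state on the section.
    """
    c = u0 if comp == 0 else u1
    dc = thr - c

    # derivatives with respect to the section coordinate
    f0, f1 = _field(code, params, u0, u1)
    fc = scale * (f0 if comp == 0 else f1)
    go = scale * (f1 if comp == 0 else f0)
    k1t = 1.0 / fc
    k1o = go / fc

    o = u1 if comp == 0 else u0

    def_o = o + 0.5 * dc * k1o
    if comp == 0:
        f0, f1 = _field(code, params, c + 0.5 * dc, def_o)
        fc = scale * f0
        go = scale * f1
    else:
        f0, f1 = _field(code, params, def_o, c + 0.5 * dc)
        fc = scale * f1
        go = scale * f0
    k2t = 1.0 / fc
    k2o = go / fc

    def_o = o + 0.5 * dc * k2o
    if comp == 0:
        f0, f1 = _field(code, params, c + 0.5 * dc, def_o)
        fc = scale * f0
        go = scale * f1
    else:
        f0, f1 = _field(code, params, def_o, c + 0.5 * dc)
        fc = scale * f1
        go = scale * f0
    k3t = 1.0 / fc
    k3o = go / fc

    def_o = o + dc * k3o
    if comp == 0:
        f0, f1 = _field(code, params, c + dc, def_o)
        fc = scale * f0
        go = scale * f1
    else:
        f0, f1 = _field(code, params, def_o, c + dc)
        fc = scale * f1
        go = scale * f0
    k4t = 1.0 / fc
    k4o = go / fc

    t_cross = t + dc * (k1t + 2.0 * k2t + 2.0 * k3t + k4t) / 6.0
    o_cross = o + dc * (k1o + 2.0 * k2o + 2.0 * k3o + k4o) / 6.0
    if comp == 0:
        return t_cross, thr, o_cross
    return t_cross, o_cross, thr


@njit(cache=True)
def section_returns(code, params, scale, u0, u1, thr, comp, downward,
                    dt, n_returns, max_steps):
    """Times and states of the first ``n_returns`` section crossings.

    Crossing sense: downward means the component passes from above ``thr``
    to (at or) below it.  Crossing instants are refined with Henon's trick.
    Time starts at 0 at the initial state.  Returns (times, states, count).
    """
    times = np.zeros(n_returns)
    states = np.zeros((n_returns, 2))
    count = 0
    t = 0.0
    cprev = u0 if comp == 0 else u1
    for _ in range(max_steps):
        v0, v1 = _rk4_auto(code, params, scale, u0, u1, dt)
        c = v0 if comp == 0 else v1
        crossed = (cprev > thr and c <= thr) if downward else (cprev < thr and c >= thr)
        if crossed:
            tc, s0, s1 = _henon_step(code, params, scale, t, u0, u1, thr, comp)
            times[count] = tc
            states[count, 0] = s0
            states[count, 1] = s1
            count += 1
            if count == n_returns:
                return times, states, count
        u0, u1 = v0, v1
        cprev = c
        t += dt
    return times, states, count


@njit(cache=True)
def kicked_return_times(code, params, scale, u0, u1, t_kick, kick, forced,
                        thr, comp, downward, dt, n_returns, max_steps,
                        min_sep):
    """Perturbation protocol for the direct (ground-truth) PRC measurement.

    Integrate the autonomous model from a zero-phase state, deliver an
    instantaneous additive kick to component ``forced`` at ``t_kick``, and
    record the times (from run start) of the next ``n_returns`` section
    crossings.  A refractory guard ``min_sep`` (typically half a period,
    counted from the run start, which is itself on the section) rejects the
    spurious re-crossing produced when a kick delivered right after the
    zero-phase instant pushes the state back across the section.
    Returns (times, count).
    """
    # advance to the kick instant: full steps then one partial step
    n_full = int(np.floor(t_kick / dt))
    rem = t_kick - n_full * dt
    for _ in range(n_full):
        u0, u1 = _rk4_auto(code, params, scale, u0, u1, dt)
    if rem > 0.0:
        u0, u1 = _rk4_auto(code, params, scale, u0, u1, rem)
    if forced == 0:
        u0 += kick
    else:
        u1 += kick

    times = np.zeros(n_returns)
    count = 0
    t = t_kick
    t_last = 0.0  # run start sits on the section
    cprev = u0 if comp == 0 else u1
    for _ in range(max_steps):
        v0, v1 = _rk4_auto(code, params, scale, u0, u1, dt)
        c = v0 if comp == 0 else v1
        crossed = (cprev > thr and c <= thr) if downward else (cprev < thr and c >= thr)
        if crossed:
            tc, _, _ = _henon_step(code, params, scale, t, u0, u1, thr, comp)
            if tc - t_last >= min_sep:
                times[count] = tc
                t_last = tc
                count += 1
                if count == n_returns:
                    return times, count
        u0, u1 = v0, v1
        cprev = c
        t += dt
    return times, count


# ---------------------------------------------------------------------------
# inference inner loops
# ---------------------------------------------------------------------------

@njit(cache=True)
def assemble_kernel(phi, p, t0, dt, ev, n_harm, n_periods, min_samples):
    """Rows of the integrated linear system.

    For each inter-event interval (of ``n_periods`` consecutive periods) the
    row holds [T_m, int p, int p cos(n phi), int p sin(n phi), n = 1..N];
    the integrals run over [t_m, t_{m+n}] with trapezoidal quadrature on the
    driver grid, the first and last fractional sub-intervals handled with the
    integrand linearly interpolated at the event instants (where the phase is
    exactly 0 resp. 2 pi n, so cos terms take the driver value and sin terms
    vanish).  Intervals covering fewer than ``min_samples`` grid points are
    flagged invalid.
    """
    n_ev = ev.shape[0]
    m_rows = n_ev - n_periods
    ncol = 2 * n_harm + 2
    A = np.zeros((m_rows, ncol))
    keep = np.zeros(m_rows, np.bool_)
    gprev = np.empty(ncol - 1)
    gcur = np.empty(ncol - 1)
    for m in range(m_rows):
        ta = ev[m]
        tb = ev[m + n_periods]
        jl = int(np.ceil((ta - t0) / dt - 1e-9))
        jr = int(np.floor((tb - t0) / dt + 1e-9))
        if jr - jl < min_samples:
            continue
        acc = np.zeros(ncol)
        acc[0] = tb - ta

        # integrand at grid point jl
        _point_integrand(phi[jl], p[jl], n_harm, gprev)

        # left fractional piece [ta, t_jl]; phase at ta is exactly 0
        tjl = t0 + jl * dt
        wl = tjl - ta
        if wl > 0.0 and jl > 0:
            frac = (ta - (tjl - dt)) / dt
            pa = p[jl - 1] * (1.0 - frac) + p[jl] * frac
            # g(ta): p-column pa, cos-columns pa, sin-columns 0
            acc[1] += 0.5 * (pa + gprev[0]) * wl
            for nh in range(n_harm):
                acc[2 + nh] += 0.5 * (pa + gprev[1 + nh]) * wl
                acc[2 + n_harm + nh] += 0.5 * gprev[1 + n_harm + nh] * wl

        # interior trapezoids
        for i in range(jl, jr):
            _point_integrand(phi[i + 1], p[i + 1], n_harm, gcur)
            for jcol in range(ncol - 1):
                acc[1 + jcol] += 0.5 * (gprev[jcol] + gcur[jcol]) * dt
            tmp = gprev
            gprev = gcur
            gcur = tmp

        # right fractional piece [t_jr, tb]; phase at tb is exactly 2 pi n
        tjr = t0 + jr * dt
        wr = tb - tjr
        if wr > 0.0 and jr + 1 < p.shape[0]:
            frac = (tb - tjr) / dt
            pb = p[jr] * (1.0 - frac) + p[jr + 1] * frac
            acc[1] += 0.5 * (gprev[0] + pb) * wr
            for nh in range(n_harm):
                acc[2 + nh] += 0.5 * (gprev[1 + nh] + pb) * wr
                acc[2 + n_harm + nh] += 0.5 * gprev[1 + n_harm + nh] * wr

        A[m] = acc
        keep[m] = True
    return A, keep


@njit(cache=True, inline="always")
def _point_integrand(phi_i, p_i, n_harm, out):
    """out = [p, p cos(n phi), ..., p sin(n phi), ...] at one grid point."""
    c1 = np.cos(phi_i)
    s1 = np.sin(phi_i)
    out[0] = p_i
    c = c1
    s = s1
    for nh in range(n_harm):
        out[1 + nh] = p_i * c
        out[1 + n_harm + nh] = p_i * s
        cn = c * c1 - s * s1
        sn = s * c1 + c * s1
        c = cn
        s = sn


@njit(cache=True, inline="always")
def _fourier_scalar(a0, an, bn, phi):
    c1 = np.cos(phi)
    s1 = np.sin(phi)
    out = a0
    c = c1
    s = s1
    for n in range(an.shape[0]):
        out += an[n] * c + bn[n] * s
        cn = c * c1 - s * s1
        sn = s * c1 + c * s1
        c = cn
        s = sn
    return out


@njit(cache=True)
def refine_kernel(phi_prev, p, t0, dt, ev, omega, a0, an, bn):
    """One phase-refinement pass.

    Integrates d(phi)/dt = omega + Z(phi_prev(t)) p(t) over each inter-event
    interval from phi(t_m) = 0.  Because Z is evaluated on the previous
    iterate's phase, the right-hand side is a known function of time and the
    integration reduces to cumulative trapezoidal quadrature (equivalent to
    RK4 with the integrand held piecewise-linear).  Raw interval endpoints
    psi_m are recorded, then the phase is rescaled to end exactly at 2 pi.
    Grid points outside the event span are set to NaN.  An interval whose
    raw endpoint is non-positive cannot be rescaled; its phase falls back to
    the previous iterate (which ends at exactly 2 pi) and its raw psi_m is
    still reported so the pathology shows up in Delta_psi.
    """
    n = p.shape[0]
    n_ev = ev.shape[0]
    m_rows = n_ev - 1
    phi_new = np.full(n, np.nan)
    psi = np.empty(m_rows)
    z0 = _fourier_scalar(a0, an, bn, 0.0)  # = Z(2 pi) as well
    for m in range(m_rows):
        ta = ev[m]
        tb = ev[m + 1]
        jl = int(np.ceil((ta - t0) / dt - 1e-9))
        jr = int(np.floor((tb - t0) / dt + 1e-9))

        # left fractional piece
        tjl = t0 + jl * dt
        wl = tjl - ta
        qjl = _fourier_scalar(a0, an, bn, phi_prev[jl]) * p[jl]
        val = 0.0
        if wl > 0.0 and jl > 0:
            frac = (ta - (tjl - dt)) / dt
            pa = p[jl - 1] * (1.0 - frac) + p[jl] * frac
            val = omega * wl + 0.5 * (z0 * pa + qjl) * wl
        phi_new[jl] = val

        qprev = qjl
        for i in range(jl, jr):
            qcur = _fourier_scalar(a0, an, bn, phi_prev[i + 1]) * p[i + 1]
            val += omega * dt + 0.5 * (qprev + qcur) * dt
            phi_new[i + 1] = val
            qprev = qcur

        # right fractional piece
        tjr = t0 + jr * dt
        wr = tb - tjr
        if wr > 0.0 and jr + 1 < n:
            frac = (tb - tjr) / dt
            pb = p[jr] * (1.0 - frac) + p[jr + 1] * frac
            val += omega * wr + 0.5 * (qprev + z0 * pb) * wr
        psi[m] = val

        # rescale so the interval ends exactly at 2 pi
        if val > 0.0:
            fac = TWO_PI / val
            for i in range(jl, jr + 1):
                phi_new[i] *= fac
        else:
            for i in range(jl, jr + 1):
                phi_new[i] = phi_prev[i]
    return phi_new, psi


@njit(cache=True)
def refine_selfconsistent_kernel(p, t0, dt, ev, omega, a0, an, bn):
    """Self-consistent variant: integrate d(phi)/dt = omega + Z(phi) p(t)
    (Z evaluated on the phase being integrated) per interval with RK4."""
    n = p.shape[0]
    n_ev = ev.shape[0]
    m_rows = n_ev - 1
    phi_new = np.full(n, np.nan)
    psi = np.empty(m_rows)
    for m in range(m_rows):
        ta = ev[m]
        tb = ev[m + 1]
        jl = int(np.ceil((ta - t0) / dt - 1e-9))
        jr = int(np.floor((tb - t0) / dt + 1e-9))

        # step from ta to grid point jl
        tjl = t0 + jl * dt
        wl = tjl - ta
        x = 0.0
        if wl > 0.0 and jl > 0:
            frac = (ta - (tjl - dt)) / dt
            pa = p[jl - 1] * (1.0 - frac) + p[jl] * frac
            pm = 0.5 * (pa + p[jl])
            x = _rk4_phase_step(x, omega, a0, an, bn, pa, pm, p[jl], wl)
        phi_new[jl] = x

        for i in range(jl, jr):
            pm = 0.5 * (p[i] + p[i + 1])
            x = _rk4_phase_step(x, omega, a0, an, bn, p[i], pm, p[i + 1], dt)
            phi_new[i + 1] = x

        tjr = t0 + jr * dt
        wr = tb - tjr
        if wr > 0.0 and jr + 1 < n:
            frac = (tb - tjr) / dt
            pb = p[jr] * (1.0 - frac) + p[jr + 1] * frac
            pm = 0.5 * (p[jr] + pb)
            x = _rk4_phase_step(x, omega, a0, an, bn, p[jr], pm, pb, wr)
        psi[m] = x

        if x > 0.0:
            fac = TWO_PI / x
            for i in range(jl, jr + 1):
                phi_new[i] *= fac
        else:
            # unscalable interval: fall back to linear interpolation
            for i in range(jl, jr + 1):
                phi_new[i] = TWO_PI * (t0 + i * dt - ta) / (tb - ta)
    return phi_new, psi


@njit(cache=True, inline="always")
def _rk4_phase_step(x, omega, a0, an, bn, p0, pm, p1, h):
    k1 = omega + _fourier_scalar(a0, an, bn, x) * p0
    k2 = omega + _fourier_scalar(a0, an, bn, x + 0.5 * h * k1) * pm
    k3 = omega + _fourier_scalar(a0, an, bn, x + 0.5 * h * k2) * pm
    k4 = omega + _fourier_scalar(a0, an, bn, x + h * k3) * p1
    return x + h * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
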