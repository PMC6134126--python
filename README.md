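# prcinfer

Inference of a limit-cycle oscillator's **phase response curve (PRC)** and
natural frequency from *passive observation*: no isolation of the system, no
designed stimulus — only the oscillator's output events and a recording of
the continuous signal that happens to drive it.

## The problem and the method

A stable limit-cycle oscillator under weak forcing `p(t)` reduces to the
phase model

    dφ/dt = ω + Z(φ) p(t),

where `ω` is the natural frequency and `Z(φ)` the 2π-periodic PRC — the
phase sensitivity to a perturbation arriving at phase `φ`. The classical way
to measure `Z` is to kick the isolated oscillator with weak pulses at
controlled phases. In many settings (neurons in a network, circadian and
cardiorespiratory rhythms) isolation is impossible; what can be observed is
one well-defined event per cycle (a spike, a marker, a threshold crossing)
at times `t_m`, together with the driving signal.

Writing `Z` as a finite Fourier series
`Z(φ) = a₀ + Σₙ (aₙ cos nφ + bₙ sin nφ)` and integrating the phase equation
over each inter-event interval `T_m = t_{m+1} − t_m` (where the phase gain
is by definition 2π) yields one *linear* equation per interval in the
unknowns `(ω, a₀, a₁..a_N, b₁..b_N)`:

    2π = ω T_m + a₀ ∫ p dt + Σₙ [ aₙ ∫ p cos(nφ) dt + bₙ ∫ p sin(nφ) dt ].

The integrals require the unknown phase φ(t), so the scheme iterates:
start from the linear interpolation `φ(t) = 2π (t − t_m)/T_m`, solve the
overdetermined system by least squares, re-integrate the phase per interval
with the fitted model, rescale each interval so it ends at exactly 2π, and
repeat (defaults: N = 10 harmonics, k = 10 iterations). The raw interval
endpoints `ψ_m` before rescaling give a built-in goodness measure computable
from data alone,

    Δ_ψ = ⟨(ψ_m − 2π)²⟩^{1/2},

to be compared with the event irregularity `Δ_ψT` (the same quantity for a
constant-frequency predictor): the reconstruction is trustworthy when
`Δ_ψ ≪ Δ_ψT`. With known ground truth, accuracy is reported as
`Δ_Z = ‖Z_true − Z_fit‖ / ‖Z_true‖` (L2 norm over one period).

The package ships everything needed to exercise the method end to end:

* `signals` — Ornstein–Uhlenbeck driver (exact Gauss–Markov discretization,
  amplitude ε, correlation time τ) and its white-noise limit;
* `oscillators` — phase-model, Morris–Lecar and van der Pol simulators on
  the driver grid, time-rescaled so the unperturbed period is 1 (ω = 2π),
  with driving strength specified as ε‖Z‖;
* `sections` — zero-phase event detection by relative thresholding
  (`s_thr = s_min + θ (s_max − s_min)`), inclined Poincaré sections in the
  `(x, x̂)` derivative embedding, and a search for the section minimizing
  Δ_ψ;
* `inference` — the iterative fit itself;
* `validation` — Δ_Z / Δ_ψ / Δ_ψT, Hénon-trick period measurement, the
  direct kick protocol for ground-truth PRCs, and a sweep harness;
* a CLI (`prc-infer simulate | detect-events | fit | true-prc | sweep |
  reproduce`).

## Worked example

Reconstruct a type-II PRC (sign-changing, as in neuronal models) from 500
periods of a phase oscillator driven by fairly strong colored noise
(ε‖Z‖ = 5, τ = 0.1):

```python
import numpy as np
from prcinfer import (ParametricPRC, NoiseConfig, TimeGrid, generate_ou,
                      simulate_phase_model, fit, l2_norm, delta_Z,
                      delta_psi_T, effective_drive_strength)

prc = ParametricPRC.type2()
epsilon = effective_drive_strength(l2_norm(prc), 5.0)   # eps*||Z|| = 5
grid = TimeGrid.from_duration(500.0, 0.001)
driver = generate_ou(NoiseConfig(epsilon=epsilon, tau=0.1, seed=1), grid)
sim = simulate_phase_model(prc, 2 * np.pi, driver)       # 479 events

result = fit(sim.events, driver)                         # N = 10, k = 10
print(result.omega)                                      # 6.2791  (true: 2 pi)
print(result.delta_psi_trace[[0, -1]])                   # 0.3661 -> 0.1104
print(delta_Z(prc, result.prc))                          # 0.1635
print(result.trace[-1].delta_psi / delta_psi_T(sim.events))  # 0.1276
```

The first iteration (linear phase) is visibly off (Δ_ψ = 0.37); ten
iterations bring the PRC within Δ_Z ≈ 0.16 of the truth, and
Δ_ψ/Δ_ψT ≈ 0.13 ≪ 1 confirms — from the data alone — that the fitted model
explains the event times far better than a perfectly periodic oscillator.

For a full-state oscillator the zero-phase section matters. The section
scan for the van der Pol oscillator,

```sh
prc-infer reproduce fig5 --scale reduced --out out/
```

shows a clear minimum of Δ_ψ at threshold parameter θ = 0.7 — the simple
threshold that locally aligns with an isochrone.

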