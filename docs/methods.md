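# Methods

## Model and scope of validity

The package fits the phase reduction of a stable limit-cycle oscillator,

    dφ/dt = ω + Z(φ) p(t),

to observed event times `t_m` (zero-phase instants, one per cycle) and the
sampled driver `p(t)`. The reduction assumes (i) a stable limit cycle,
(ii) forcing weak enough that amplitude deviations relax fast compared to
their excitation, and (iii) events that are genuine returns to a surface of
constant asymptotic phase. All three can fail gracefully and observably:
the built-in residual Δ_ψ grows toward the event irregularity Δ_ψT as the
fit stops explaining the data, which is the intended diagnostic for "the
phase model no longer holds" (very strong driving) and "the integrals carry
no information" (driving so slow it is constant within a period).

Throughout, time is normalized so the unperturbed period is 1 and ω = 2π.
For the planar models this is implemented by multiplying the autonomous
vector field by the measured unperturbed period T0; the driver then acts
additively on the forced component in rescaled time, and all reported
quantities (τ, t_sim, Δ_ψ) are in rescaled units.

## The iterative fit

* **Linear system.** Integrating the phase equation over each inter-event
  interval with `Z` as an order-N Fourier series gives rows
  `[T_m, ∫p, ∫p cos nφ, ∫p sin nφ]` against the target 2π (or `n·2π` for
  the multi-period variant with intervals `t_{m+n} − t_m`). Quadrature is
  trapezoidal on the driver grid; the fractional sub-intervals at the event
  ends use the integrand linearly interpolated at `t_m`, where the phase is
  exactly 0 / 2π — the same linear-interpolation convention used to locate
  the events themselves. Intervals spanning fewer than
  `min_interval_samples = 5` driver samples are dropped (their quadrature is
  meaningless); a system with fewer rows than the 2N + 2 unknowns raises an
  error rather than silently regularizing.
* **Least squares.** Solved by SVD-based least squares; rank deficiency
  (the slow-driver failure mode, where the integral columns become nearly
  collinear) produces a conditioning warning and the minimum-norm solution.
  An optional ridge penalty on the Fourier coefficients exists but is off
  by default, which is the faithful form of the method.
* **Phase refinement.** The next phase iterate integrates
  `dφ/dt = ω + Z(φ_prev(t)) p(t)` per interval from φ(t_m) = 0, with `Z`
  evaluated on the *previous* iterate. That makes the right-hand side a
  known function of time, so the integration is cumulative trapezoidal
  quadrature (identical to RK4 once the integrand is piecewise-linear). A
  self-consistent variant (Z evaluated on the phase being integrated, RK4
  per interval) is exposed as `InferenceConfig(self_consistent=True)`; on
  test data it agrees with the default to a few per cent and is not the
  default.
* **Rescaling and the goodness trace.** Each interval's raw endpoint ψ_m is
  recorded, then the phase is rescaled to end at exactly 2π. If an isolated
  interval ends at ψ_m ≤ 0 (observed a couple of times per 500 intervals
  only at extreme driving, ε‖Z‖ ≈ 50) it cannot be rescaled; the previous
  iterate's phase is kept there, the raw ψ_m still enters Δ_ψ, and a
  warning is emitted. Only a widespread pathology (> 10% of intervals)
  aborts the fit. Iteration count is fixed (k = 10 by default, no early
  stopping); the per-iteration (ω, Z, Δ_ψ) trace is returned so callers can
  implement their own stopping or diagnostics.

## Simulators and the driver

* **OU driver.** Exact Gauss–Markov update
  `p_{i+1} = p_i e^{−dt/τ} + ε √(1 − e^{−2dt/τ}) N(0,1)` with a stationary
  initial condition `p_0 ~ N(0, ε²)`: exact marginals at any dt, no
  discretization bias, no transient. The white-noise variant draws i.i.d.
  `N(0, ε²/dt)` samples so window integrals have dt-independent variance.
  One seeded generator per signal; the seed is stored in the CSV metadata.
* **Integration.** All simulators use classical fixed-step RK4 on the
  driver grid with `p` held piecewise-linear between samples, keeping
  events, driver samples and quadrature aligned on one grid. Phase-model
  events are first passages of `m·2π`, located by linear interpolation
  between the bracketing samples.
* **Drive-strength convention.** Because equal ε perturbs different
  oscillators differently, driving strength is specified as ε‖Z‖ with ‖·‖
  the L2 norm over one period; ε = target / ‖Z_true‖ with ‖Z_true‖ taken
  from the measured ground-truth PRC (phase shift of the reconstructed
  curve leaves this norm unchanged, so the calibration does not depend on
  the section choice).
* **Planar models.** Morris–Lecar (driven through the voltage equation;
  unperturbed period T0 ≈ 64.01 in model units) and the van der Pol
  oscillator `ẍ − 2(1 − x²)ẋ + x = p(t)` (T0 ≈ 7.6299). Both start from a
  fixed state, relax for a configurable transient (default 10 unperturbed
  periods) without driving, and are then driven for the recorded span.

## Sections and events

Thresholds are parameterized relative to the observed extrema,
`s_thr = s_min + θ (s_max − s_min)`, so detection is affine-invariant.
Default crossing sense is downward (from above), configurable. A debounce
step enforces a minimum separation of 0.25 × median interval, suppressing
double crossings when strong driving wiggles the signal near the threshold.
Inclined sections use the five-point-difference derivative embedding
`(x, x̂)` and threshold `s_aux = −x sin α + x̂ cos α`; the angle convention
is anchored by α = −π/2 ⇒ s_aux = x (plain thresholding). The section
search runs the full fit per grid point (default θ ∈ {0.05..0.95} step
0.05, α ∈ (−π/2, π/2] step π/36) and returns the Δ_ψ surface with invalid
grid points (too few events) flagged.

## Ground truth and error measures

The reference PRC of a planar model is measured by the standard kick
protocol: land exactly on the zero-phase section using Hénon's
time-exchange step (the final integration step swaps time and the section
coordinate, giving crossing times to ~1e−12 relative), deliver an
instantaneous kick ε to the forced variable at a phase-proportional time,
and convert the deficit of the next n = 5 periods into a phase shift per
unit kick. Two accuracy safeguards were found necessary and are defaults:

* a half-period refractory guard on crossing acceptance — a kick delivered
  just after the zero-phase instant pushes the state back across the
  section and would otherwise register a spurious near-zero first period;
* Richardson extrapolation to the infinitesimal-kick limit
  (`2 Z_{ε/2} − Z_ε`, base kick 1% of the forced variable's cycle extent):
  the PRC is defined for infinitesimal perturbations, and at a finite 1%
  kick the Morris–Lecar curve still carries ~8% nonlinearity, which would
  put a floor of Δ_Z ≈ 0.16 under every reconstruction scored against it.
  The raw single-amplitude protocol remains available
  (`extrapolate=False`), and the n → n + 2 relaxation check warns if the
  relaxation span was too short.

For the pure phase model the kick transports the phase along
`dφ/ds = Z(φ)`, `s ∈ [0, ε]` (the exact effect of a delta pulse of area ε),
so the protocol converges to the generator PRC as ε → 0 — used as a
convergence test, not as a tautology: the measured curve differs from `Z`
at finite ε.

Δ_Z uses 2048-point trapezoidal quadrature; directly measured curves are
interpolated periodically from their 64-point phase grid.

## Problem sizes and numerical defaults

Benchmark experiments use the standard conditions dt = 0.001, t_sim = 500
(≈ 500 observed periods), N = 10, k = 10. Sweeps and the section scan
average over 20 noise realizations; the package supports 100 via
`prc-infer reproduce --scale full`, with 20 chosen as the default
reproduction scale. Period measurement uses RK4 at dt = 2e−4 with nine
Hénon-refined returns and demands relative spread < 1e−7.

## What the synthetic data does and does not show

The generators realize exactly the assumptions the method targets: an
oscillator with a true limit cycle, additive scalar forcing of known
waveform, stationary Gaussian driving, and noiseless observation of both
channels. Passing tests therefore demonstrate correctness of the algorithm
and its error diagnostics under those conditions — not robustness to
measurement noise on `x(t)` or `p(t)`, missing events, non-stationary
input, oscillator-intrinsic noise, or multi-dimensional coupling, none of
which are modeled here. The Δ_ψ/Δ_ψT diagnostic is expected to flag (not
fix) such violations. Known limitations inherited from the method: very
strong driving invalidates the linear initial phase (a Hilbert-transform
initialization could help; not implemented), very slow driving makes the
system rank-deficient, and thresholds far from an isochrone bias the
events — addressed only to linear order by the inclined-section search.
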