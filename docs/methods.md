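# Methods

## Models and assumptions

Both activation models treat PAS — the activated fraction of a platelet
population, or equivalently the activation probability of a single
platelet — as a state variable in [0, 1] driven by a *scalar* stress τ
sampled along a Lagrangian path. All anisotropy of the true stress state
is collapsed into that scalar; the models cannot distinguish a normal
from a shear loading of equal scalar magnitude, which is why the choice
of tensor contraction is itself part of the uncertainty budget.

**Power-law model.** dPAS/dt = c·a·τ^{b/a}·D^{a−1} with dD/dt = τ^{b/a}.
D is a stress-history variable; under constant stress the model is exactly
PAS = c·τ^b·t^a. PAS is not intrinsically bounded: the implementation
clamps at 1 and logs a warning, flagging that the power law has left its
admissible range.

**Additive-rate model.** dPAS/dt = (S + F + G)(1 − PAS). The (1 − PAS)
factor bounds PAS below 1. S = S_r·PAS·H carries the accumulated stress
H(t) = ∫₀ᵗ τ ds; F is the instantaneous-stress power law in "rate form";
G is the same construction applied to the stress rate SR. SR is the
*running cumulative mean* of |Δτ|/Δt from the path start — not the
instantaneous derivative — recomputed at every step; a windowed variant
was deliberately not added because the mean-from-start form is what the
model's rate constants were calibrated against.

## Units

All internal stresses are dyn/cm² and times are seconds, because the
calibrated parameter values are only consistent with that system: at
τ = 500 dyn/cm² (50 Pa) the closed form c·τ^b·t^a gives 4.9e-4 at 1 s,
matching the published benchmark, whereas feeding Pa would give a value
~70× smaller. Pa appears only at I/O boundaries (file headers, CLI
configs) and converts by the factor 10.

## Scalar contractions

The symmetric viscous stress tensor is contracted to a scalar by one of:

* `a`: √[(1/6)((τxx−τyy)² + (τyy−τzz)² + (τzz−τxx)²) + τxy² + τxz² + τyz²]
* `b`: √[(1/3)·Σ_{i≠j} τij·τji] (ordered pairs: each unordered shear pair
  counted twice)
* `c`: √[(1/3)·Σ τii²]

The printed forms of these contractions leave the summation ranges and
normalization placement ambiguous. The conventions above were fixed by a
physical anchoring condition: the calibration devices apply a single
shear component, so the default contraction (`a`) must return exactly the
applied shear for a single-shear-component tensor — which it does, while
also being invariant under rotation of the laboratory axes (it is a
J2-type invariant). `b` under this reading gives √(2/3)·τxy for the same
state; the literal single-count alternative is available as `b_single`.
`c` uses the plain RMS of the normal components. `b` and `c` are *not*
frame-invariant — along a rotating path a pure gap shear migrates between
their blocks — which is intentional: they exist to probe how much of the
scalar stress lives in shear vs. normal components of the chosen frame.

## Integration scheme

Explicit Heun (trapezoidal predictor–corrector) on the history's own
sampling grid, default dt = 1e-4 s. That step resolves the 50 Hz content
of the benchmark signals with 200 points per period; halving it changes
every benchmark PAS by less than 0.1% (asserted in the suite). For the
power-law model the D equation and the PAS rate are independent of PAS,
so the Heun march reduces to exact cumulative trapezoids.

**PAS = 0 bootstrap.** PAS = 0 is a degenerate state of the F and G
terms: for β > 1 it is an equilibrium that the generic stepper can never
leave (the physical solution branches off it non-uniquely), and for β < 1
the PAS^{(β−1)/β} factor is singular. Both cases are resolved the same
way: any step starting at PAS = 0 takes the exact constant-input
power-law increment PAS(Δt) = C·τ^α·Δt^β (+ C_r·SR^γ·Δt^δ when G is
active) instead of the Heun step. Because this is the exact short-time
solution, the result is insensitive to the bootstrap step size (< 0.5%
on halving, asserted). An arbitrary epsilon start was rejected: it makes
the β < 1 case step-size-dependent. The same idea handles the D^{a−1}
kink of the power-law model at D = 0 (first-interval exact increment
c·ΔD^a), and the ln D terms of the sensitivity system (first-interval
constant-stress closed forms).

## Sensitivity system

The linearized sensitivities are the ODEs obtained by differentiating the
power-law model with respect to a, b, c and a multiplicative rescaling
s of the whole stress history (evaluated at s = 1); they co-integrate
with the model and are validated two ways: against the closed-form
derivative set of PAS = c·τ^b·t^a under constant stress (within 0.5%)
and against a central finite-difference oracle on every scenario (within
1%; observed agreement is ~1e-9). Terms of the form x^p·ln x take their
continuous limit 0 at x = 0. The stress direction is reported both as the
dimensionless scale derivative and per unit stress (divided by the
time-mean of τ, so it equals c·b·τ^{b−1}·t^a under constant stress).
Per-instant stress sensitivities (a functional derivative) are out of
scope, as are analytic sensitivities of the seven-parameter family — for
those the finite-difference path is the supported route.

The inversion reported by `perturbation_for_relative_error` is the plain
first-order formula (target·PAS/|∂PAS/∂ζ|)/|ζ|. For c it is exactly the
target (PAS is linear in c); for b under constant stress it reduces to
1/(b·ln τ) ≈ 25.7% at 50 Pa for a 100% PAS error. The a-direction is
special: under constant stress ∂PAS/∂a = PAS·ln t vanishes at exactly
t = 1 s, so its inverted perturbation is effectively unbounded there —
a and b act in opposite directions at t < 1 s and admit an error-
cancellation direction (asserted in the suite).

## Monte-Carlo ensembles

Parameters are multiplied by (1 + amplitude·z), z ~ N(0, 1), drawn
independently per parameter (no correlation structure is imposed — none
is known). Draws making a positive quantity non-positive are rejected
and redrawn; clamping instead would bias the mean at 30% amplitude. The
default ensemble size is 250 samples, consistent with the N = O((σ/ε)²)
standard-error rule exposed as `required_sample_size`.

Two modes: `per_sample` (one static draw per ensemble member —
calibration uncertainty) and `per_timestep` (redraw at every step —
uncorrelated model error; the default). A caveat found and kept
documented here: per-timestep *relative* normal perturbation of exponent
parameters has catastrophic tails at large amplitudes. A single draw of
the time exponent near zero makes τ^{b/a} astronomically large, the
history variable D jumps irreversibly, and the sample saturates at
PAS = 1; at 30% amplitude with 1e3 steps essentially every sample is hit
and the ensemble variance collapses to zero from above. Diverging
increments are therefore mapped to saturation (PAS = 1), which is their
physical limit. Quantitative amplitude-sweep statements (variance
monotonicity, quantile containment of the unperturbed value) are made in
`per_sample` mode, where they hold robustly; per-timestep sweeps are
meaningful at small amplitudes, where the noise provably averages out
(ensemble SD ~30× smaller than static at 5% amplitude, asserted).

As amplitude → 0 the per-sample ensemble SD over amplitude converges to
the linearized prediction ‖(∂PAS/∂ζ·ζ)_ζ‖₂, cross-checking the MC and
sensitivity modules against each other (within 15% at amplitude 0.01,
n = 500). At 30% amplitude the ensemble mean shifts from the unperturbed
PAS by several standard errors and the distribution stretches upward —
the nonlinear behavior that motivates reporting medians and extremes
alongside mean/variance.

## Synthetic stress signals

The generators define the study conditions, emulating two regimes:

* **uniform**: τ(t) = τ0·(1 + 0.1·sin(2π·50·t)) across 5 Pa–15 kPa — a
  spatially uniform stress with mild 50 Hz modulation (one oscillation
  per impeller revolution at 3000 rpm). Benchmarks use 1 s exposures.
* **pump-like**: piecewise regions of prescribed mean stress in the
  10–1000 dyn/cm² range with an abrupt jump of about two orders of
  magnitude on region entry, modulated by seeded random-phase harmonics
  (8 components, 0.1–1× the stated bandwidth, RMS = the stated fraction
  of the region mean, clipped at zero). The default test schedule
  (0.2 s at 50 dyn/cm², then 0.3 s at 800 dyn/cm², 50% fluctuation,
  2 kHz bandwidth) yields SR/SA ≈ 6e3, the strongly unsteady regime in
  which the G-term dominates S and F by > 2 orders of magnitude.

What these signals do **not** emulate: turbulence spectra, coherent
vortex trapping, spatial correlation of the stress field, or any actual
pump geometry — device-trajectory results obtained with them are
qualitative. The analytic tracer fields add physically exact (laminar,
steady) tensor histories: plane Couette fixes the stress level exactly
(τxy = μ·γ̇), the Taylor–Couette annulus (uθ = A·r + B/r) stands in for
the rotating-gap region, and the Lamb–Oseen vortex provides a decaying,
SR-generating stress along spiral paths. Passive tracing is the default
(platelet Stokes number ~1e-4–1e-2); the inertial Stokes-drag mode exists
to verify that limit, not for production use.

## Degenerate inputs and numerical conventions

* τ = 0: τ^{b/a} = 0 and F = 0 by continuity; no NaN from 0^x.
* SR = 0 (constant stress): G ≡ 0; the 50 Hz benchmark series at
  dt = 1e-4 gives SR ≈ 4e5 dyn/(cm²·s), and the published uniform-stress
  benchmark values are reproduced with G *excluded* — they are
  numerically consistent only with a negligible G contribution, so the
  benchmark mode is include = (S, F).
* SR is discretization-dependent by construction (sampling a 50 Hz
  oscillation at exactly its period gives SR ≈ 0); histories therefore
  carry their own grids and SA/SR use per-interval Δt.
* Histories may be non-uniformly sampled; all integrators march on the
  given grid.
* A Soares-family step that would exceed PAS = 1 by more than a
  tolerance raises (divergent step — refine the grid); tiny overshoots
  are clamped.

## Known limitations

* No resolved device flow: all device-like inputs are synthetic or
  analytic, so only the uniform-stress benchmarks are quantitative.
* The scalar-stress reduction ignores stress anisotropy and
  mechano-sensing; no recalibration of parameters is attempted.
* Monotone stress accumulation (D, H) never "heals"; no time-weighted
  decay of old stress is modelled.
* Analytic sensitivities exist only for the three-parameter model.
* PAS is interpreted as an activation probability of a single platelet
  when applied per-trajectory; that reading strains the population-level
  calibration and is the reason population statistics report extremes,
  not just means.
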