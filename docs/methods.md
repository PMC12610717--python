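# Methods

This note records the model, the numerical choices, and the design
decisions behind `tgakinetics`, including what the synthetic validation
does and does not demonstrate.

## The kinetic model

Non-isothermal solid-state decomposition is described by the standard rate
law `dα/dt = A·exp(−E/RT)·f(α)` with R = 8.314 J·mol⁻¹·K⁻¹ and the
Šesták–Berggren autocatalytic conversion function `f(α) = α^M (1−α)^N`
(M ≥ 0, N > 0). M controls the initial product-driven acceleration, N the
late-stage deceleration; M = 0, N = 1 recovers simple first-order decay.

Multi-stage decomposition of organic solids is represented as a chain of
consecutive transitions A → B → C → D between normalized state masses
`m_A…m_D` (Σ = 1). Each transition carries its own Arrhenius pair (A_x,
E_x) and SB exponents (M_x, N_x), with the transition rate driven by the
*product* species of that transition (`m_B` for step 1, `m_C` for step 2,
`m_D` for step 3). The measured signal is assembled from the states via
step weights: `m_rel = w₁(1−m_A) + w₂(m_C+m_D) + (1−w₁−w₂)m_D` and
`m = m(t=0) + Δm·m_rel`, where w₁, w₂ are the fractional contributions of
the first two mass-loss steps and Δm (negative for loss) the total
relative mass change.

Two regularizations make this system well-posed numerically:

- **Seeding.** Product-driven rates vanish identically at the pure initial
  state, so integration starts from `m_A = 1 − 3ε`, `m_B = m_C = ε` (and
  hence `m_D = ε` through the algebraic closure), with ε = `seed_eps` =
  1e−8 by default. Note the closure forces a seed on m_D as well: with
  `m_D = 0` exactly, the third transition could never start for M₃ > 0.
  The test suite asserts that halving ε changes `m_rel` by < 1e−4 on a
  reference model; exponents M ≲ 0.6 keep this insensitivity (pure
  exponential autocatalysis, M = 1, would make onset positions depend
  logarithmically on ε).
- **Source gating.** As printed, each transition's rate does not stop when
  its *source* species is exhausted (e.g. step 1 keeps draining m_A while
  m_B is nonzero, driving m_A negative). Every rate is therefore
  multiplied by `clip(source/g, 0, 1)` with gate width g = 1e−6. The
  equations are untouched wherever all species are positive; the width is
  deliberately not sharper because a 1e−10 kink was observed to stall the
  stiff integrator, while results are identical for widths 1e−8…1e−4.

An alternative reading of SB kinetics in consecutive schemes — each step
driven by its own normalized conversion (α₁ = 1−m_A,
α₂ = (m_C+m_D)/(1−m_A), α₃ = m_D/(m_C+m_D)) — is available behind
`ConsecutiveModel(conversion_mode="step_conversion")`, default off; the
product-species form is the primary model.

Activation energies are either constants or temperature-dependent,
`E(T) = −R(b + 2c/T)`, the form produced by a quadratic Kissinger fit
(below). During integration E(T) is clamped at the edges of its validity
window (a logged warning, flagged on the trajectory); predictions that
relied on clamping report it, since extrapolated E(T) outside the measured
window has no empirical support.

### Integration

`m_A, m_B, m_C` are integrated with LSODA (via `scipy.integrate.odeint`,
chosen over `solve_ivp` for ~3× lower per-step overhead at identical
accuracy) at rtol = 1e−8, atol = 1e−10 by default; `m_D` is recovered
algebraically so the balance closes exactly. The defaults are validated
against (i) the closed-form first-order limit (max |Δα| < 1e−6 over five
half-lives), (ii) an independently written fixed-step RK4 integrator
(agreement < 1e−6 in `m_rel` on a smooth three-step toy), and (iii) a
conservation sweep over 100 random parameter draws (< 1e−8). Fitting uses
rtol = 1e−7, atol = 1e−10 (accuracy well below the noise floor, ~30 %
faster).

## Synthetic study generator

The generator emulates a realistic measurement campaign: linear heating
scans 30–550 °C at q⁺ ∈ {0.1, 0.2, 0.5, 1, 2, 3, 5, 7, 10, 20} °C·min⁻¹,
one fresh sample per scan, two atmospheres represented by two truth
parameter sets, sampling one point per second capped at 20 000 points per
curve. Noise matches quoted instrument reproducibility figures: a single
uniform ±2 °C temperature-axis offset per curve (run-to-run systematic
shift, not point noise), ±3 % relative scatter on w₁ and w₂, ±2 % relative
scatter on Δm, and 0.05 %-of-initial-mass Gaussian noise per point. All
randomness flows from one base seed through
`SeedSequence(entropy=seed, spawn_key=(curve_index,))`; the manifest
records each curve's derived seed and exact generating parameters, so any
curve regenerates bit-exactly and every downstream stage can be tested
closed-loop.

The two shipped truth models ("n2_like", "air_like") are synthetic
stand-ins with E between 135 and 205 kJ·mol⁻¹ and pre-exponentials
calibrated so the three DTG peaks at 10 °C·min⁻¹ fall near 268, 315 and
362 °C (inert) / 268, 314, 366 °C (oxidizing). The spacing is the
tightest that keeps exactly three ≥5 %-prominence DTG peaks at every
heating rate: with the product-driven consecutive equations, closer peaks
produce spurious local maxima (source-exhaustion kinks, and rate resurgence
when the next step drains a not-yet-saturated product).

What passing the closed loop does *not* show: the generator draws noise
from the same family the model assumes (no baseline drift, buoyancy,
oxygen-transport limitation, melting or sample-mass effects), and the
fitted model family equals the generating family. Recovery rates here are
therefore an upper bound on what real instrument data would give; they
validate the estimator machinery, not the model's adequacy for any
particular compound.

## Kissinger analysis

dm/dT is estimated by local linear regression of m on T over a fixed 2 °C
window centered on each grid point (exact for linear data, robust to
uneven sampling; the window widens to ~2 sampling intervals when the data
are too coarse to put two points in 2 °C). Per curve, the n most prominent
minima of dm/dT (default prominence threshold: 5 % of the maximum loss
rate, suppressing noise peaks) are the step peak temperatures, ordered by
temperature; step identity is never permuted afterwards.

For each (atmosphere, step), `ln(q⁺/Tp²)` is regressed on `1/Tp` (q⁺
converted to K·s⁻¹ internally; the unit choice shifts only the intercept)
and E = −R·slope. Curved sets are fit by `y = a + bx + cx²` *in the
Kissinger coordinates* (x = 1/Tp — the coordinate in which E is defined as
−R·dy/dx), giving `E(T) = −R(b + 2c/T)` valid on [min Tp, max Tp]. Mode
selection is automatic: quadratic iff the extra-sum-of-squares F-test for
the quadratic term has p ≤ 0.05 *and* E(T) stays positive over the window;
ties go to quadratic; numerically collinear points always select linear.

Hand-off to fitting: a linear-mode step contributes its constant E; a
temperature-dependent step contributes the per-curve constant `E(Tp)`
evaluated at that curve's own peak temperature.

Validation: on noiseless single-step simulations (Kissinger is an
approximation for autocatalytic f), recovered E is within 3 % of truth for
the reference model and in median over 20 random models; on the shipped
three-step studies all E recover within ~1 %.

## sc-MKA fitting

Per curve, the free parameters are `log₁₀A₁…₃ ∈ [2, 20]`,
`M₁…₃ ∈ [0, 3]`, `N₁…₃ ∈ [0.05, 12]`, and w₁, w₂ ≥ 0 with w₁ + w₂ ≤ 1
(enforced by the reparametrization w₂ = w₂ᶠ·(1−w₁), w₂ᶠ ∈ [0, 1]); E is
fixed. The objective is the unweighted RSS between observed and calculated
mass in percent units. Δm is fixed from the data plateau by default (mean
of the last 2 % of points; a plateau check — median |dm/dT| of the last
5 % of points below 2 % of the peak rate — rejects truncated curves), with
`fixed_value` and `free` modes available; m(t=0) defaults to 1 for
normalized data. Curves are subsampled evenly to ≤ 400 points for the
objective; the heating program is reconstructed from the recorded nominal
rate (exact for constant-rate runs even under a temperature-axis offset).

Initialization is a deterministic 9-point grid M ∈ {0.1, 0.5, 1.0} ×
N ∈ {0.5, 1.5, 4} applied to all steps, with each start's log₁₀A solved
from matching the observed peak loss rate
(`k(Tp)·f(0.5) ≈ dα/dt` at the detected peak) and w₁, w₂ read off the
mass levels at mid-valley temperatures. The initial RSS of all nine starts
is evaluated; the three best are polished with Levenberg–Marquardt (lmfit
`leastsq`, bounds via the MINPACK parameter transformation, xtol = ftol =
1e−10, ≤ 2000 function evaluations per start) and the lowest final RSS
wins. The optimizer-sanity invariant (final RSS ≤ every start's RSS) is
asserted against all nine. Everything is deterministic; repeated fits are
bit-identical.

Fit quality is reported as the squared Pearson correlation between the
observed and calculated curves. The cross-rate trend table carries one
row per curve with `log₁₀A_x, M_x, N_x, E_x`, the step contributions
I₁ = 100·w₁, I₂ = 100·w₂, I₃ = 100·(1−w₁−w₂) (interpreting the step
"proportional representations" as weight percentages — the state variables
themselves vanish at completion), Δm in %, and r².

Closed-loop performance on the default 20-curve noisy study: all 20 fits
recover log₁₀A within ±0.3 (typically ±0.05 plus the jitter-induced
compensation shift), M and N within max(±0.15, 25 %), w₁/w₂ within ±0.03.
Fixing E 10 % high shifts fitted log₁₀A up by the compensation-effect
amount ΔE/(ln10·R·T_step) while barely degrading the fit — the reason E
must come from an independent method.

## Predictions

Protocols are an isothermal hold with an optional preceding linear ramp
(the zero-length ramp collapses to a pure hold, so both variants share one
representation; queries beyond the program end raise rather than clamp).
Conversion is reported total-mass-loss-normalized (α ≡ m_rel), with
"% mass loss" = |Δm|·α·100 alongside. The reporting clock starts at hold
onset; conversion accumulated during the ramp appears as a separate
`pre_conversion`, so the effect of the preceding heating step is
quantifiable (on the shipped fixtures it is small but strictly positive,
and ramp+hold conversion dominates the direct hold at every hold-clock
time — a property asserted numerically). Threshold times use linear
interpolation between bracketing grid points; thresholds not reached
within the hold report a `None` sentinel. Basis-comparison tables report
conversion at 30 s, 60 s, 5 min, 15 min and 60 min plus time-to-1 %, with
ratio columns against a declared reference basis.

## Problem sizes in the shipped validation

The acceptance script and test suite run: conservation over 100 random
models on a 250-point grid; Kissinger recovery over 6 heating rates ×
(1 + 20) truth models at 2 500 output points; the full 20-curve noisy
study (up to 20 000 points per curve, fit on 400) for sc-MKA recovery;
and a reduced 3-curve pipeline executed twice for byte-identical
reproducibility. These sizes keep the complete validation within a few
minutes on one CPU while leaving every statistical conclusion
(recovery fractions, median errors) unchanged from larger runs.

## Known limitations

- Single-ramp heating only; cooling, modulated programs and
  sample-controlled heating are out of scope, as are heat-flow (DSC/DTA)
  signals, diffusion/oxygen-transport terms and melting.
- Mass gain is rejected, not modeled.
- The trend analysis fits each curve independently (that is the point of
  sc-MKA); no joint multi-curve estimator is provided.
- Kissinger E for strongly autocatalytic steps carries an intrinsic ~1–3 %
  approximation error that propagates into fixed-E fits as a small
  compensation shift in log₁₀A.
- Adjacent-heating-rate peak spacing in the shipped fixtures (~5 °C) is
  comparable to the ±2 °C run-to-run temperature jitter, so strict
  Tp-vs-q⁺ monotonicity on *noisy* data can flip a marginal pair at
  unlucky seeds; the kinetic property itself is asserted on noiseless
  studies.
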