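# tgakinetics

Solid-state decomposition kinetics from thermogravimetric (TGA) mass-loss
curves, built for thermal-stability assessment of drug substances under
processing conditions such as hot-melt extrusion (HME, minutes at
80–170 °C) and fused-deposition-modelling 3D printing (FDM, tens of
seconds at 150–230 °C).

Many organic compounds decompose through several consecutive stages, each
with autocatalytic character: the rate first accelerates as product
accumulates, then decelerates as reactant is exhausted. `tgakinetics`
implements the full analysis chain for such systems:

1. **Forward model.** A three-step consecutive scheme A → B → C → D in
   normalized state masses `m_A…m_D` (summing to 1). Each transition has an
   Arrhenius rate constant `k_x(T) = A_x·exp(−E_x/RT)` and a two-exponent
   Šesták–Berggren (autocatalytic) conversion function
   `f(α) = α^M (1−α)^N` evaluated on the product species of that
   transition:

   ```
   dm_A/dt = −k₁(T)·m_B^M₁ (1−m_B)^N₁
   dm_B/dt = +k₁(T)·m_B^M₁ (1−m_B)^N₁ − k₂(T)·m_C^M₂ (1−m_C)^N₂
   dm_C/dt = +k₂(T)·m_C^M₂ (1−m_C)^N₂ − k₃(T)·m_D^M₃ (1−m_D)^N₃
   m_D     = 1 − m_A − m_B − m_C
   ```

   The observable mass signal is reconstructed through the step weights
   w₁, w₂ and the total relative mass change Δm:
   `m_rel = w₁(1−m_A) + w₂(m_C+m_D) + (1−w₁−w₂)m_D`,
   `m = m(t=0) + Δm·m_rel`.

2. **Kissinger analysis.** Peak temperatures Tp of the mass-loss-rate
   (DTG) maxima are located per step across a series of heating rates q⁺,
   and the activation energy follows from
   `ln(q⁺/Tp²) = −E/(R·Tp) + const`. Curved Kissinger plots are fit by a
   second-order polynomial in 1/Tp whose derivative gives a
   temperature-dependent `E(T) = −R(b + 2c/T)`; an F-test decides between
   the two forms.

3. **sc-MKA fitting.** Single-curve multivariate kinetic analysis: each
   curve is fit separately by bounded Levenberg–Marquardt least squares
   with the activation energies *fixed* at the Kissinger values, which
   removes the E/ln A compensation degeneracy and makes
   `log₁₀A, M, N, w₁, w₂` identifiable per curve — exposing their
   heating-rate dependence across the measurement series.

4. **Predictions.** The fitted model is extrapolated to isothermal
   annealing protocols (optionally preceded by a heating ramp), reporting
   conversion trajectories, % mass loss and time-to-threshold summaries,
   plus comparison tables between parameter bases fitted at different
   heating rates or atmospheres.

A first-class synthetic-data module generates noisy study sets with the
structure of a real measurement campaign (three consecutive steps, ten
heating rates 0.1–20 °C·min⁻¹, scans 30–550 °C, two atmospheres as two
parameter sets, ±2 °C temperature-axis reproducibility, ±3 % step-magnitude
and ±2 % total-mass-loss scatter), so the whole pipeline is testable
closed-loop without any instrument data.

## Worked example

```python
from tgakinetics import celsius_to_kelvin
from tgakinetics.synthetic import StudyDesign, NoiseSpec, n2_like_model, generate_study
from tgakinetics.kissinger import KissingerAnalysis
from tgakinetics.scmka import FitSpec, fit_curve
from tgakinetics.prediction import PredictionProtocol, predict

design = StudyDesign(q_list=(0.5, 1, 2, 5, 10, 20),
                     atmosphere_models={"n2": n2_like_model()},
                     sampling_interval=2.0)
curves = generate_study(design, NoiseSpec(seed=7))

kiss = KissingerAnalysis(curves).fit()
print(kiss.summary().to_string(index=False))

c10 = next(c for c in curves if c.q_plus == 10)
res = fit_curve(c10, FitSpec(fixed_E=tuple(kiss.fixed_E_for_curve(c10))))
print(res.summary().to_string(index=False))
print(f"RSS = {res.rss:.3g} %^2, r^2 = {res.fit_quality:.6f}")

proto = PredictionProtocol(hold_temperature=celsius_to_kelvin(230.0),
                           hold_duration=3600.0, resolution=2.0)
pred = predict(res.consecutive_model, proto, thresholds=(0.01,))
print(f"time to 1% conversion at 230 C: {pred.time_to_thresholds[0.01]:.0f} s")
```

Output:

```
atmosphere  step_index   mode   E_kJ_mol  r_squared    b    c       T_window_C
        n2           1 linear 141.330630   0.996157 None None (223.19, 277.94)
        n2           2 linear 164.999792   0.996071 None None (268.98, 324.61)
        n2           3 linear 195.120229   0.998392 None None (315.86, 371.94)

 step  E_kJ_mol (fixed)  log10_A_per_s        M        N     I_pct
    1        141.330630      12.014277 0.543854 1.207047 12.786434
    2        164.999792      13.073321 0.600993 1.296420 46.380113
    3        195.120229      14.462418 0.595369 1.598685 40.833453
RSS = 0.973 %^2, r^2 = 0.999999
time to 1% conversion at 230 C: 322 s
```

Reading it: the Kissinger fits recover the generating activation energies
(140/165/195 kJ·mol⁻¹) to ~1 %; the fixed-E per-curve fit then recovers
the remaining kinetics of the noisy 10 °C·min⁻¹ curve — pre-exponentials
within ~0.15 decades of the generating values (the small offsets absorb
this curve's ±2 °C temperature jitter via the compensation effect),
exponents M/N and the step contributions I₁/I₂/I₃ (≈13/46/41 %) close to
the generating 13/47/40 %. Extrapolating that description to an isothermal
230 °C hold puts 1 % conversion at ≈5 minutes — a direct, quantitative
statement about how long such a material survives at an FDM-grade nozzle
temperature.

## Command line

The same pipeline is scriptable via the `tgakin` entry point:

```bash
tgakin simulate --config examples/demo.yaml --seed 42 --out curves/
tgakin kissinger --curves curves/ --out kiss/
tgakin fit --curves curves/ --kissinger kiss/kissinger.json --out fits/
tgakin predict --params fits/model_n2_q0.1.json --hold-c 230 --hold-min 60 --out pred/
tgakin report --basis slow=fits/model_n2_q0.1.json --basis fast=fits/model_n2_q20.json \
              --reference slow --out comparison.csv
```

Curve files are plain CSV (`time_s,temperature_C,mass_pct`) with a JSON
metadata sidecar; model parameters travel as JSON documents with a
bit-exact read/write round trip.

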