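# Methods

## Scope

`aortasv` has two halves: an *estimator* that turns noninvasively measurable
quantities (pulse wave velocity, mid-aortic cross section, effective aortic
length, cuff pressures, pulse-contour timing) into stroke volume and cardiac
output, and a *mock circulation* — a deterministic lumped-parameter model of
the human systemic circulation — that generates ground-truth data to
validate the estimator. The simulator doubles as the package's fixture
generator: all test data are synthesized at run time; nothing is recorded
from patients.

## The mock circulation

Twelve compartments in a closed hydraulic loop:

- a **pump** (left ventricle) of compliance `C_p` = 12 ml/mmHg, squeezed by
  an external half-sinusoidal pressure `P_ext(t) = P_max·max(0, sin ωt)`;
  its pressure obeys `dP = dV/C_p + P'_ext(t)·dt`, with `P'_ext` clamped to
  zero during the off half-cycle. One-way inflow/outflow valves are modelled
  as `i = max(0, ΔP/R)` with `R_i = R_o` = 0.01 mmHg/(ml/s).
- **ten aortic segments** a0–a9 (root, brachiocephalic branch, arch,
  descending/abdominal aorta, iliacs), each 5 cm long, initial radius
  1.5 cm, reference compliance 0.13 ml/mmHg (total 1.3). Nine junctions
  carry inline flow with resistance and blood-column inertance
  `L = ρ·s/A/1333.22` (mmHg/(ml/s²)), the instantaneous area `A` being the
  upstream segment's volume over its length. Flow path:
  pump → a0 → a2; a2 feeds the brachiocephalic dead-end a1 and the chain
  a3 → … → a9. The two junctions feeding the narrow brachiocephalic and
  iliac trees have R = 0.1 mmHg/(ml/s); the other seven have 0.005, chosen
  (as in the reference parameterisation) to give realistic waveform damping.
- **systemic runoff**: segments a1–a9 each drain through 10.3 mmHg/(ml/s)
  (nine in parallel ≈ 1.14 total = 95 mmHg / 83.3 ml/s, the normal mean
  pressure over cardiac output) into a **venous reservoir** of compliance
  10 ml/mmHg and initial volume 2000 ml, which refills the pump. Venous
  inertance is neglected (large venous cross sections, slow velocities).

### Integration

Explicit Euler with `dt` = 1e-5 s over 0–3 s (300,000 steps). The inertial
junction flows use the one implicit ingredient: substituting the backward
difference `di/dt ≈ (i_new − i_old)/dt` into `ΔP = R·i + L·di/dt` and
solving for the current flow,

    i_new = (ΔP·dt + L·i_old) / (R·dt + L),

which is unconditionally stable and reduces to Ohm's law as `L → 0`. All
pressure updates are `ΔP = ΔV/C` with the compliance of the active mode:
constant `C_ref` (linear) or the Fung dynamic compliance
`C(P) = 2·C_ref·P_ref/(P + P_ref)` evaluated explicitly at the segment's
current pressure (`P_ref` = 80 mmHg, so `C(P_ref) = C_ref`, doubling at zero
distending pressure and halving at 3·P_ref). Nonlinearity is applied to the
ten aortic segments only; pump and veins stay linear.

The run cold-starts with every compartment at the 10 mmHg mean circulatory
pressure and nominal volumes; the drive switches on at t = 0 and periodic
steady state is reached by the second beat. Samples are saved every 100
steps (1 kHz) within the 1.5–3.0 s recording window — two beats at 80/min,
three at 120/min; segment radii are reported as `sqrt(V/(π·length))`, the
ultrasound surrogate. True stroke volume is the integral of aortic-valve
flow over the window divided by the number of beats, available both as a
trapezoidal sum over the 1 kHz samples and as the exact per-step accumulator
(they agree to <0.1 %); halving `dt` changes it by <0.5 %.

The marching loop is compiled with numba; a 3-s run takes well under a
second after JIT warm-up, and a pure-Python reference stepper (`step`) is
cross-checked against the kernel in the tests.

Two deliberate model properties worth knowing:

- **Volume is conserved exactly** (closed circuit); the kernel tracks the
  maximum relative drift (≈1e-14) as a diagnostic.
- **The pump volume may transiently go negative** during the cold-start
  first beat at high aortic compliance (the initially depressurised aorta
  swallows ~200 ml): the pump has no volume constraint, only an elastic
  pressure. The system recovers within the first beat, long before the
  recording window; only non-finite states or a collapsed aortic segment
  abort a run.

## Feature extraction

- **Beats** are delimited by diastolic minima (peak search on the negated
  signal with ≈0.7·T minimum separation); only complete beats (two bounding
  onsets) are used, and per-beat features are averaged arithmetically.
- **Foot of the upstroke**: first upward crossing of DBP + 2 %·PP, linearly
  interpolated between samples (ties resolve to the earlier sample). This
  marks the very beginning of the upstroke and is insensitive to
  reflected-wave augmentation.
- **PWV**: 30 cm center-to-center distance between segments 2 and 8 divided
  by the difference of their foot times, averaged over beats.
- **Halftime `t_h`**: scanning *backwards* from just before the next onset
  for the last downward crossing of the (SBP+DBP)/2 level — robust against
  early post-peak oscillations that cross the half level several times.
- **Mid-aortic area**: mean diastolic (beat-onset) radius of segments a4–a6
  (the symmetric middle of the ten-segment aorta; configurable), squared
  times π.

In simulator-driven estimation the timing features come from the a5 *radius*
contour (what ultrasound can see) and the pressure levels from the a5
pressure channel; for external CSV input any channel can be used. In linear
mode radius- and pressure-derived halftimes agree to a few ms (the square
root linking radius to volume is mildly concave, so the radius half level
sits slightly off the pressure half level); in Fung mode they legitimately
differ, which is part of what the nonlinear correction absorbs.

## Estimator conventions

- Effective length for simulator-driven estimation is the actual 50 cm of
  the ten segments. For clinical input, `L` is the external-landmark
  estimate and an optional tapering multiplier
  `1 + (1/3)·(ϵL/2r₀)²` (≈1.04 for the anatomic taper ϵL/r₀ ≈ 0.75) may be
  applied; the model aorta is untapered, so the factor defaults to 1.
- λ is computed per run from the measured `t_p`, `t_h`, `T` and pressures:
  `λ = [1 + β(1 − t_p/t_h)] / [1 − β(T + t_p − 2t_h)/T]` with
  `β = PP/(4·(PH − CVP))`, `PH = (SBP+DBP)/2`. CVP defaults to 0
  (negligible, or estimated from jugular examination when elevated).
- The halftime stroke volume is `C·PP/(2(1 − λ·t_h/T))` — the volume
  balance at `t_h`, where the stored excess above diastole is `C·PP/2`
  because the pressure has fallen to the half level. (The companion
  ejection-time form `C·PP/(1 − t_e/T)`, valid when the pulse traverses the
  aorta within the ejection time as in small animals, stores the full
  `C·PP` at the systolic peak; that form also underlies the 1.3 ml/mmHg
  normal-compliance derivation 2.08·(1 − 0.28/0.75).)
- The Fung correction uses the exact logarithmic ratio with
  `P_ref` = 80 mmHg; the two-term series `1 − PP/(4(DBP+P_ref))` is provided
  for small pulse pressures but the exact form is preferred throughout
  (0.942 vs 0.938 at 120/80; they diverge strongly by 180/40, where the
  series gives 0.708).

## Validation experiments

- **Compliance sweep** (linear mode, Pmax 120, HR 80): segment compliances
  scaled by {1/3, 1/2, 1, 3/2} — severe atherosclerosis to a compliant
  young aorta. Measured PWV ≈ 1003, 837, 642, 563 cm/s; Bramwell–Hill
  recovers the known total compliance within 10 % at every scale, and
  estimated SV stays within 10 % of truth (identity-line slope ≈ 1.07).
- **Contractility sweeps** (Fung mode, Pmax 25–175 mmHg step 25): at HR 80
  the corrected estimates correlate with truth at r² ≈ 0.9997, at HR 120 at
  r² ≈ 0.9994; uncorrected estimates systematically overestimate at high
  pulse pressure and the correction reduces the signed error at every grid
  point. The grid step is a package choice (only the 25–175 range is fixed
  by the experiment's design); r² is the squared Pearson correlation.
- **Error budget**: CO = A·L·PP/(ρ·v²·(T − λt_h)) is a product of five
  measured factors; with independent errors the log-variances add and the
  squared-PWV term counts four-fold:
  `cv(CO) = sqrt(cv_A² + cv_L² + cv_PP² + cv_timing² + 4·cv_v²)`.
  Five 5 % errors give 14 % (28 % at 95 % confidence, inside the 30 %
  clinical acceptability bound). A lognormal Monte-Carlo sampler (seeded,
  lognormality keeps all factors positive and matches the logarithmic
  treatment) confirms the analytic value within 5 %.

## What the synthetic data do and do not show

The mock circulation reproduces the features the estimator depends on —
finite pulse transit, waveform damping, pulse reflections from discrete
impedance steps, pressure-dependent compliance, runoff — with realistic
normal-adult magnitudes. It does *not* include distributed (1-D wave) or 3-D
flow, pulmonary circulation, baroreflex control, respiratory variation,
arrhythmia, measurement noise, or operator variability in ultrasound and
cuff readings. Passing validation here therefore demonstrates the method's
*accuracy in principle* (absence of structural bias) and its error *budget*,
not its field precision; the method is explicitly not applicable in severe
arrhythmia.

## Numerical choices and degenerate inputs

- Single unit system mmHg/ml/s with one CGS conversion constant 1333.22
  (dyn/cm²)/mmHg, used in the inertance and Bramwell–Hill conversions.
- Threshold crossings are always linearly interpolated; exact hits resolve
  to the earlier sample.
- Degenerate inputs raise `ValueError` with stage identification: constant
  (pulseless) signals, beats that never cross the half level, non-positive
  transit times, λ·t_h ≥ T, CVP above DBP, taper exceeding the diameter.
- A non-integer number of beats in the recording window warns at parameter
  construction and errors in `true_stroke_volume`.
- The divergence guard checks every 1000 steps (and at the final step) for
  non-finite pressures or a collapsed aortic segment and reports the
  offending compartment.

## Known limitations

- The estimator's residual +10 % bias in the linear normal case traces to
  the piecewise-linear waveform model behind λ and to reflections making
  the mid-aortic pulse pressure slightly unrepresentative of the whole
  aorta; it is a constant bias of the kind clinicians can calibrate away,
  not random error.
- Foot-to-foot PWV lands ~3 % below the Bramwell–Hill closed-form value for
  the model's diastolic volume — transit-time measurement on a discretely
  lumped aorta is only an approximation to the continuum wave speed.
- Explicit Euler needs the small 1e-5 s step; the `dt` is configurable but
  accuracy claims hold at the default.
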