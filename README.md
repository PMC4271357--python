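# aortasv

Noninvasive estimation of cardiac stroke volume from pulse wave velocity,
pulse contour and aortic dimensions — together with the lumped-parameter
mock circulation used to validate the method.

Continuous knowledge of stroke volume (SV) and cardiac output (CO) guides the
care of critically ill patients, but the standard thermodilution measurement
needs a pulmonary-artery catheter. This package implements a fully
noninvasive alternative built from three bedside measurements: carotid-femoral
pulse wave velocity *v*, an ultrasound estimate of the mid-aortic cross
section *A*<sub>mid</sub> and effective aortic length *L*, and cuff systolic/diastolic
pressures, plus the pulse contour from an external pulse pickup.

## The method

1. **Compliance from PWV** (Bramwell–Hill): total aortic compliance
   `C = V/(ρ·v²)` with aortic volume `V = A_mid·L`; in clinical units
   `C [ml/mmHg] = 1333.22·A_mid·L/(ρ·v²)`.
2. **Halftime method.** Let `t_h` be the time from pulse onset until the
   contour has fallen midway between systolic and diastolic levels, and `T`
   the cycle length. At `t_h` the aorta still stores `C·PP/2` of the ejected
   beat while `λ·CO·t_h` has already run off to the periphery, so

   `SV = C·PP / (2·(1 − λ·t_h/T))`,

   where `λ ≈ 1.1` weights early-cycle runoff and is computed from a
   piecewise-linear pulse model using `t_p`, `t_h`, `T`, SBP, DBP and CVP.
3. **Nonlinear-compliance correction.** A real aortic wall behaves as a Fung
   exponential material: dynamic compliance `C(P) = 2·C_ref·P_ref/(P + P_ref)`
   falls as pressure rises, so the PWV-derived *diastolic* compliance
   overestimates the effective compliance at large pulse pressures. The exact
   correction ratio
   `SV′/SV = (2(DBP+P_ref)/PP)·ln(1 + PP/(2(DBP+P_ref)))` (0.942 at 120/80
   with `P_ref` = 80 mmHg) restores accuracy.

The validation testbed is a 12-compartment closed circulation: a compliant
pump squeezed by a half-sinusoidal external pressure, ten aortic segments
with inline resistances and blood-column inertances, nine systemic runoff
branches and a venous reservoir, marched by explicit Euler at 10 µs steps
with either linear or Fung segment compliance. Estimated SV is compared with
the integral of aortic-valve flow — the model's ground truth.

## Worked example

Simulate a normal adult (heart rate 80/min, peak pump pressure 120 mmHg,
total aortic compliance 1.3 ml/mmHg) and estimate SV from its waveforms:

```console
$ aortasv simulate --out wave.csv
wrote wave.csv: 1501 samples, true SV 61.5 ml
$ aortasv estimate --in wave.csv
{
  "pwv_cm_s": 642.49,
  "a_mid_cm2": 8.922,
  "c_total_ml_mmhg": 1.3988,
  "sbp": 122.99,
  "dbp": 81.29,
  "pp": 41.70,
  "t_p_s": 0.128,
  "t_h_s": 0.3930,
  "period_s": 0.75,
  "lambda": 1.0824,
  "sv_uncorrected_ml": 67.38,
  "correction_ratio": 1.0,
  "sv_ml": 67.38,
  "co_ml_s": 89.84,
  "co_l_min": 5.39
}
```

Reading: the foot-to-foot transit between aortic segments 2 and 8 gives a
pulse wave velocity of 642 cm/s, which with the 8.9 cm² diastolic mid-aortic
section and 50 cm length yields 1.40 ml/mmHg of compliance (model truth:
1.3). The halftime method then returns 67.4 ml against the true 61.5 ml —
a 10 % overestimate, within the method's expected accuracy band — and a
cardiac output of 5.4 l/min.

The clinical entry point takes the measurements directly (here a stiff,
low-output example; the Fung correction is applied by default):

```console
$ aortasv estimate-clinical --pwv 900 --area 7.1 --length 55 \
    --sbp 130 --dbp 85 --tp 0.13 --th 0.34 --period 0.8
{
  "c_total_ml_mmhg": 0.624,
  "lambda": 1.1006,
  "sv_uncorrected_ml": 26.38,
  "correction_ratio": 0.9374,
  "sv_ml": 24.73,
  "co_l_min": 1.85
}
```

Other subcommands: `features` (per-beat SBP/DBP/t_p/t_h table), `pwv`,
`sweep-compliance`, `sweep-pmax`, `error-budget` (delta-method propagation:
five 5 % measurement errors compound to a 14 % CV in CO, 28 % at 95 %
confidence), and `reproduce`.

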