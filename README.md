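# memri

Quantification of membrane-potential-linked MR parameters: two-pool
magnetization-transfer modelling of selective inversion-recovery signals,
T2 relaxometry (mono-exponential and EPG-dictionary with stimulated-echo
and slice-profile correction), Cramér–Rao inversion-time design, and the
mixed-effects / Dunnett inference layer that relates the MR parameters to
membrane-potential change.

## The problem

Raising or lowering extracellular K⁺ (or blocking K⁺ channels with Ba²⁺)
shifts the membrane potential V_m of cells, and this shift is accompanied
by measurable changes in the water T2 relaxation time and in the
macromolecular pool size ratio (PSR) of the tissue. The analysis chain
that turns raw spin-echo signals into these conclusions has several
non-trivial steps, and this package implements all of them as a tested,
reusable pipeline for anyone working on MR-based detection of
membrane-potential change:

1. **Forward physics.** A 1 ms hard inversion pulse selectively inverts
   free-water protons while only saturating the short-T2 macromolecular
   pool; the post-pulse state is found by numerically integrating the
   Bloch equations per pool. The coupled longitudinal recovery of the
   two-pool system (free pool *f*, macromolecular pool *m*, transfer
   rates k_fm = PSR·k_mf and k_mf) is bi-exponential:

       M_z,f(t)/M_∞,f = b_f⁺ exp(−R1⁺ t) + b_f⁻ exp(−R1⁻ t) + 1

   with R1± the eigenvalues of the coupled relaxation matrix and b_f±
   the projections of the initial state (δ_f, δ_m) onto its
   eigenvectors.

2. **Relaxometry.** Least-squares mono-exponential T2 fits for
   single-echo spin-echo (SESE) decays; EPG-simulated dictionaries with
   stimulated-echo and slice-profile correction for multi-echo (MESE)
   trains; echo-train averaging and bi-exponential fitting for
   inversion-recovery MESE, followed by the closed-form inversion (under
   R1,f = R1,m)

       PSR  = b_f⁺ / (b_f⁻ − δ_m + 1),     k_mf = (R1⁺ − R1⁻) / (1 + PSR).

3. **Protocol design.** Fisher-information / CRLB analysis of the
   bi-exponential model and multi-start optimization of the
   inversion-time schedule, minimizing the summed relative CRLB standard
   deviations of PSR and k_mf.

4. **Synthetic studies.** A generator that emulates the in vitro
   cell-pellet experiment (seven ionic conditions, batch random effects,
   fractional-linear dependence of T2, PSR and k_mf on ΔV_m) and the
   four-epoch in vivo perfused-cortex time series, down to the raw
   signals, so the whole chain runs end to end with no external data.

5. **Inference.** Random-intercept mixed models (REML) reporting
   fractional slopes in the `a·(1 + s·ΔV_m)` parameterization,
   a potassium-vs-barium interaction test, Dunnett many-to-one
   comparisons against the control condition (one-factor multivariate-t
   quadrature), and the per-epoch in vivo arm contrast model.

## Worked example

```python
import numpy as np
from memri import (TwoPoolParams, InversionState, rates_from_twopool,
                   simulate_inversion_pulse, mt_from_biexp,
                   StudyDesign, generate_parameter_dataset,
                   fit_fractional_slope, dunnett_vs_control)

# forward physics at the baseline operating point
pools = TwoPoolParams(r1f=0.5, r1m=0.5, kmf=14.8, psr=0.0377)
inv = simulate_inversion_pulse(pools, pulse_duration=1e-3, flip=180.0)
comp = rates_from_twopool(pools, InversionState(-1.0, inv.delta_m))
mt = mt_from_biexp(comp, inv.delta_m)

# one synthetic in vitro study and its inference
dataset = generate_parameter_dataset(StudyDesign(seed=20250703))
fit = fit_fractional_slope(dataset, "t2_ms")
```

This prints (via the obvious format calls):

```
delta_f = -0.9917, delta_m = 0.9068
R1+ = 15.858 Hz, R1- = 0.500 Hz, bf+ = -0.06928, bf- = -1.93072
PSR = 0.0377, k_mf = 14.80 Hz
t2_ms: intercept 49.62, fractional slope +0.00650/mV, p = 1.91e-268
psr:   intercept 0.03737, fractional slope -0.00556/mV, p = 8.37e-278
kmf_hz: intercept 14.91, fractional slope +0.00036/mV, p = 0.724
```

The hard pulse leaves the macromolecular pool at 91% of equilibrium
while fully inverting free water; the round trip through the recovery
algebra returns the generating PSR and k_mf exactly; and on one noisy
synthetic study the mixed model recovers fractional slopes close to the
generating relations (0.00687 and −0.00542 per mV), with the
exchange-rate slope correctly indistinguishable from zero. The Dunnett
table for T2 flags the depolarizing conditions (20–80 mM K⁺ and 10 mM
Ba²⁺) against the 4.2 mM control:

```
label    diff       t  p_adj tier
 K0.2 -1.5540 -2.5851 0.0535   ns
   K1 -0.0433 -0.0720 1.0000   ns
  K20  6.0913 10.1329 0.0000  ***
  K40  7.0036 11.6505 0.0000  ***
  K80  9.6016 15.9724 0.0000  ***
 Ba10  4.4996  7.4851 0.0000  ***
```

A command-line interface wraps the same pipeline:

```
memri simulate  --arm invitro --out runs/sim
memri fit-t2    --signals runs/sim/sese_signals.csv --out runs/t2.csv
memri fit-mt    --signals runs/sim/ir_mese_signals.csv --out runs/mt.csv
memri design-ti --n-ti 25 --out runs/design
memri analyze   --arm invitro --seed 1 --out runs/invitro
```

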