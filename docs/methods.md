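# Methods

## Two-pool model and its assumptions

Tissue water is modelled as a free pool *f* exchanging longitudinal
magnetization with a macromolecular pool *m*. The state is
(R1,f, R1,m, k_mf, PSR, T2,f, T2,m) with k_fm ≡ PSR·k_mf derived and
never stored (detailed balance, PSR = M_∞,m / M_∞,f). After a selective
inversion of the free pool the coupled longitudinal system relaxes
bi-exponentially; `rates_from_twopool` evaluates the eigenvalue /
eigenvector closed forms for the apparent rates R1± and amplitudes b_f±
given the post-pulse state (δ_f, δ_m), and `biexp_recovery_signal`
evaluates the recovery. The closed form is verified in the test suite
against a brute-force integration of the coupled ODEs to 1e-8.

Assumptions, and where they matter:

* **R1,f = R1,m** — required by the explicit inversion
  PSR = b_f⁺/(b_f⁻ − δ_m + 1), k_mf = (R1⁺ − R1⁻)/(1 + PSR). The
  assumed common value (default 0.5 Hz, `TwoPoolConfig.r1_hz`) only
  enters the forward simulation; the inversion uses fitted rates.
* **Lorentzian (Bloch) macromolecular dynamics.** The inversion factor
  δ_m = M_z,m(0)/M_∞,m is computed by numerically integrating the Bloch
  equations for a hard on-resonance pulse with the pool's own T2;
  super-Lorentzian lineshapes are deliberately not implemented. For the
  default 1 ms, 180° pulse and T2,m = 10 µs this gives δ_m ≈ 0.907,
  within 0.1% of the analytic saturation limit exp(−ω₁²·T2,m·τ).
* **T2,m default 10 µs** — a typical semisolid value; it is not
  measurable from the data handled here, so it is exposed in
  configuration (`t2m_us`) and every derived quantity records the δ_m
  actually used.
* **δ_f fixed at −1.** The Bloch simulation for free water
  (T2,f ≈ 60 ms) gives −0.992; the pipeline treats free water as fully
  inverted and exposes the value in configuration rather than fitting
  it.

Units: seconds and Hz internally; milliseconds (and mV, degrees) in all
file formats, configuration fields and reports.

## Inversion-recovery fitting

`fit_biexp_ir` fits scale·(b_f⁺ e^{−R1⁺t} + b_f⁻ e^{−R1⁻t} + 1) to the
per-TI averages of an IR-MESE acquisition (16 echoes per TI averaged to
one point, noise SD scaled by 1/√16). The optimizer parameterization is
(scale, b_f⁺, δ₀, log R1⁻, log ΔR1) where δ₀ = 1 + b_f⁺ + b_f⁻ is the
fitted initial state bounded to [−1, 1] and ΔR1 = R1⁺ − R1⁻ ≥ 0, so
rate ordering and the physical range of the initial state are enforced
structurally rather than repaired after the fact. Eight multi-start
initializations over log-spaced rate guesses (seed 20250703) make the
fit deterministic; noise-free forward signals are recovered to better
than 1e-4 in all four components across the physiological range
(PSR 0.01–0.15, k_mf 5–30 Hz, R1 0.3–1.5 Hz).

Magnitude data are sign-ambiguous near the recovery null. The fit first
tries the candidate polarity restorations around the magnitude minimum,
then polishes the winner against the folded model |model(t)| − y, which
is the correct high-SNR objective for magnitude data. The polish step
matters: without it the small fast-component amplitude picks up a
systematic ≈ 4% PSR bias at 1% noise from misassigned near-null points;
with it the median PSR over Monte-Carlo replicates stays within ~1% of
truth (asserted at 3% in the suite).

## T2 estimation

SESE decays are fitted mono-exponentially, initialized from a
log-linear regression (deterministic). MESE trains are matched against
an EPG-simulated dictionary: the configuration-state recursion
(F_k, F*_{−k}, Z_k) over excitation, refocusing pulses, gradient
dephasing and relaxation, evaluated at every slice-profile position
(relative flip scaling) and integrated across the slice, curves
normalized to unit first echo. At exactly 180° refocusing with a
uniform profile the recursion reproduces exp(−t/T2) to 1e-10; at
sub-180° angles it is verified to 1e-6 against an explicit 2048-
isochromat rotation-matrix simulation, and the stimulated-echo excess
of later echoes over the pure exponential is asserted. Matching
maximizes the normalized inner product; ties break toward smaller T2;
`residual_norm` = √(1 − score²) flags structureless inputs.

Defaults: dictionary grid 5–300 ms in 0.5 ms steps; T1 fixed at a
nominal 1.8 s (MESE echo amplitudes are weakly T1-sensitive); slice
profile from the small-tip Fourier transform of a 3-lobe Hann-windowed
sinc, discretized at 64 positions and truncated at 1% of peak — all
config-replaceable, since actual pulse shapes vary by implementation.

## Inversion-time design

For the five-parameter recovery model under independent Gaussian noise
the Fisher information is J^T J/σ² with the analytic Jacobian J; CRLB
variances are propagated to PSR and k_mf through the Jacobian of the
closed-form conversion. The design criterion is the summed relative
CRLB standard deviation of PSR and k_mf — these are the quantities of
interest, and the criterion is invariant to joint rescaling of signal
and noise. Optimization runs multi-start (16 starts, seed 20250703)
bounded L-BFGS-B in log-TI coordinates over the default span
4–10 079.4 ms; the log-uniform schedule is always included as a start,
so the optimum never falls behind it. A singular information matrix
raises an error naming the unidentifiable direction. Default schedule
length is 25 TIs.

## Synthetic study generator

The generator is the study definition, not a tuning knob.

**In vitro.** Seven ionic conditions: K⁺ at 0.2, 1, 4.2 (control), 20,
40, 80 mM and Ba²⁺ at 10 mM. Measured membrane-potential changes anchor
three potassium conditions (−5.33 mV at 0.2 mM, 0 at control, +30.0 mV
at 80 mM) and the barium condition (+13.3 mV); the unanchored potassium
conditions are interpolated with a least-squares line in log₁₀[K⁺]
through the three anchors, reflecting the near-log-linear dependence of
V_m on extracellular potassium. Each of 15 batches × 7 conditions draws

    value = intercept · (1 + slope·ΔV_m) · (1 + u_b) · (1 + ε)

with generating relations T2 = 49.7·(1 + 0.00687·ΔV_m) ms,
PSR = 0.0377·(1 − 0.00542·ΔV_m), k_mf = 14.8·(1 + 0.000648·ΔV_m) Hz;
u_b ~ N(0, 0.03) shared within a batch (multiplicative, matching the
fractional-slope parameterization) and ε ~ N(0, 0.02) per cell for T2
and PSR. The exchange-rate residual uses its own fraction, 0.14: k_mf
estimates are far noisier in practice than T2 or PSR, and the
condition contrasts for k_mf in the emulated study are uniformly
non-significant — back-calculating from its barium contrast
(−0.832 Hz, p = 0.263, 15 paired batches) gives a per-observation SD near 2 Hz ≈ 14% of the
intercept. With a single 2% fraction the near-null k_mf slope would be
detected almost always, inverting the qualitative significance pattern
the generator is meant to emulate. Raw-signal bundles (SESE decay from
the row's T2; IR-MESE recovery from the row's PSR and k_mf with 16-echo
trains decaying at the row's T2) carry additive Gaussian magnitude
noise, default 0.5% of equilibrium — the high-SNR limit of Rician noise
appropriate for ROI-averaged pellet signals.

**In vivo.** Two arms: modulation (7 rats, epochs at [K⁺] = 3, 40, 80,
3 mM) and control (5 rats, 3 mM throughout), four 12-minute epochs, the
recovery epoch observed for 2 of the 7 modulation rats. Epoch means for
ΔT2 anchor the emulated study's values (modulation 0.684 and 1.10 ms
at epochs 2 and 3; control 0.104 and 0.181 ms); the recovery-epoch
means (0.30 / 0.25 ms) are generator choices. Per-rat random
intercepts (SD 0.3 ms) and residual noise (SD 0.2 ms) are set so the
epoch-2 contrast is borderline and the epoch-3 contrast reliably
detected, mirroring that study's significance ordering qualitatively.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: Rician noise at low SNR, B0/B1
inhomogeneity, partial-volume and perfusion physics, cell-type
differences (the step-like lymphocyte response), any departure of the
true ΔV_m–[K⁺] relation from log-linearity, and drift between epochs.
Closed-loop recovery demonstrates the estimators are consistent with
their own forward models, not that the biological relations are true.

## Statistical layer

Responses are regressed on ΔV_m with a per-batch random intercept,
fitted by REML (statsmodels MixedLM); the reported fractional slope is
b/a, matching the a·(1 + s·ΔV_m) form, with a large-sample Wald test
for the slope. The estimator choice is cross-checked in the suite
against a direct profiled restricted-likelihood search. When the
residual variation is numerically zero (noise-free synthetic data) the
mixed fit is ill-posed and the implementation falls back to ordinary
least squares, which is then exact — this is what makes the noise-free
closed-loop identities hold to 1e-8. Degrees of freedom for Wald tests
are asymptotic (normal reference); with 15 batches this is mildly
liberal compared to small-sample corrections, and p-values should be
read accordingly.

The potassium-vs-barium comparison adds a barium-specific slope
deviation (ΔV_m × group interaction) to the same mixed model; the
control condition sits on the potassium branch.

Dunnett's many-to-one test uses the exact one-factor structure of the
contrast family: comparisons against a shared control have correlation
λ_i λ_j with λ_i = √(n_i/(n_i+n₀)), so the familywise tail probability
is a double integral over the shared normal factor and the pooled-
variance scale, evaluated by 96-point Gauss–Hermite × 64-point
Gauss–Legendre quadrature. This covers unbalanced designs without Monte
Carlo; a single comparison reduces to the two-sided t-test, and the
suite checks the k = 6 family against a 10⁶-draw max-|t| simulation
(2e-3) and against an independent multivariate-t implementation.
Significance tiers follow the conventional 0.05 / 0.01 / 0.001
asterisks.

The in vivo model regresses ΔT2 on epoch, arm and their interaction
with a per-rat random intercept; the reported epoch-e contrast
β_arm + β_arm:epoch_e is the modulation-minus-control difference at
that epoch, skipped for epochs observed in only one arm.

## Numerical choices and degenerate inputs

* ODE integrations (inversion pulse, test oracles): LSODA with
  rtol 1e-9 / atol 1e-12 — the 10 µs macromolecular T2 makes the
  pulse-period system stiff.
* Nonlinear fits: `scipy.optimize.least_squares` (trust-region
  reflective) with tolerances at 1e-15; fixed multi-start seeds.
* Degenerate inputs raise typed errors: constant or non-decaying T2
  series, ragged echo trains, schedules that cannot identify the model
  (with the offending direction), negative derived PSR (with the raw
  values attached); a PSR of exactly zero is returned flagged
  nonphysical rather than raised, since it is the valid no-
  macromolecular-pool limit.
* Dictionary ties break toward smaller T2; dictionary fits report the
  grid member, never an interpolated value.

## Problem sizes

The default test suite and the acceptance script use the full emulated
protocol sizes (50 echo times, 25 inversion times × 16 echoes, 15
batches × 7 conditions, 200 study replicates); Monte-Carlo power and
bias checks use 100–200 replicates, chosen as the sizes at which the
asserted medians and rates are stable across seeds.

## Known limitations

* No voxelwise map fitting, registration, k-space or image simulation;
  the unit of analysis is the ROI-averaged signal.
* No super-Lorentzian lineshape, off-resonance MT saturation, B1
  correction or transverse-pool exchange.
* The mixed-model Wald tests use the normal reference; no
  Satterthwaite/Kenward–Roger correction.
* The fractional slope is reported as b/a of a linear fit, not a
  directly fitted fractional model; for the small relative effects here
  the difference is negligible.
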