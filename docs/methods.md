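# Methods

This note records the models implemented in `reservoirbp`, the numerical
choices behind them, what the synthetic data does and does not emulate, and
the limitations a user should know about.

## 1. The reservoir model

The arterial tree is idealised as `N` compliant segments with one root
(the ascending aorta) receiving the ventricular inflow `Q_in(t)` and `K`
terminal segments discharging through constant resistances `R_k` into the
microcirculation once pressure exceeds the zero-flow pressure `P_zf`
(assumed common to all termini).  Segment compliance follows from geometry
and wave speed, `C_n = L_n·A_n/(ρ v_n²)`, and the wave transit time from the
root to segment `n` is `τ(n) = Σ L/v` along the path.  Mass conservation
with the defining ansatz — the reservoir pressure has the same shape
everywhere, delayed by `τ(n)` — gives a scalar delay-differential equation
for the root history:

    Q_in(t) = Σ_n C_n P'_res(t−τ(n)) + Σ_k (P_res(t−τ(k)) − P_zf)/R_k .

Because arterial transit times are short compared with the cardiac cycle
(aorto-iliac transit < 80 ms in humans, enforced as the default budget in
`ReservoirNetwork`), a zeroth-order Taylor expansion in `τ` collapses this
to the lumped ODE

    C dP_res/dt = Q_in − (P_res − P_zf)/R ,    C = ΣC_n,  1/R = Σ1/R_k ,

formally identical to a two-element Windkessel but without assuming a
spatially uniform pressure.  The excess pressure is the pointwise remainder
`P_xs = P − P_res`; in the proximal aorta it is empirically proportional to
inflow, `Q_in = ζ·P_xs`, which under a three-element-Windkessel reading
makes `ζ` the characteristic admittance `1/Z_c`.

### Estimation routes

**Pressure + flow.**  With measured `Q_in`, the ODE is integrated directly.
Its parameters come from diastole, where `Q_in = 0` and the solution is the
mono-exponential `P_res − P_zf = (P_es − P_zf) e^{−t/RC}`:

1. `fit_diastolic_decay` fits `P(t) = P_∞ + (P_es − P_∞) e^{−k_d (t−t_es)}`
   over a diastolic window by unweighted nonlinear least squares, giving
   `k_d = 1/RC` and the asymptote `P_∞`.
2. `estimate_rc` sets `R = (mean P − P_∞)/mean Q` over the beat and
   `C = 1/(k_d R)`.  Both means are plain sample means; the resistance
   identity is exact only in periodic steady state, and with a three-element
   generator it absorbs `Z_c` into `R` (a ~4 % bias at physiological
   `Z_c/R`); the rate constants are unaffected.
3. `compute_pres_pq` integrates the ODE and returns `P_res`, `P_xs`, and
   summary indices.

**Pressure only.**  Substituting `Q_in = ζ·P_xs` turns the same ODE into
one driven by measured pressure, with rates `k_s = ζ/C` and `k_d = 1/RC`.
`k_d` and `P_∞` come from the diastolic fit as above; `k_s` is chosen so the
computed `P_res` matches measured `P` over diastole, where the model demands
`P_xs = 0`.

**The spurious large-`k_s` minimum.**  The diastolic-mismatch objective is
not globally identifying: as `k_s → ∞` the solution `P_res → P` tracks the
measured pressure exactly — zero excess pressure everywhere — so the
objective always re-descends to ~0 at the top of any search range.  On model
data the floor can even undercut the true-`k_s` residual.  `fit_ks`
therefore scans the objective on a coarse log grid over [1e-3, 1e3] 1/s and
polishes the *first* (smallest-`k_s`) local minimum — the physiologic root
with finite characteristic impedance.  A scan that is monotone over the
bracket returns the best bound with a `k_s at bound` warning.

### P_zf vs P_∞

The diastolic asymptote `P_∞` is *assumed* equal to `P_zf` by the default
mode, but directly measured zero-flow pressures are substantially lower
than mono-exponential asymptotes from normal beats, so the identification
is a modelling choice, not a fact.  All fitting entry points expose
`pzf_mode`:

* `fit` (default) — `P_zf := P_∞` from the diastolic fit;
* `fixed` — user-supplied value (e.g. 0, or venous pressure);
* `measured` — a stopped-flow measurement.

The mode is recorded in every result.  A fitted `P_∞` at or above the
minimum pressure in the window is flagged `implausible` but not clipped;
negative asymptotes likewise survive with a flag, since silently
constraining them would bias `k_d`.

## 2. Numerics

* **Integration.**  Every scalar linear ODE in the package (Windkessel
  state, both reservoir routes) is advanced by the exponential-integrator
  step `y(t+dt) = E·y(t) + b0·f(t) + b1·f(t+dt)`, `E = e^{−a·dt}`, which is
  the exact solution when the forcing is piecewise linear.  Against smooth
  signals the global error is O(dt²) — the same order as trapezoidal
  quadrature of the integrating-factor form — but the step is also immune
  to overflow for stiff rates (the `k_s → ∞` limit is handled exactly) and
  reproduces the diastolic closed form to round-off.  Halving `dt` cuts the
  error ≈ 4×, verified against closed-form oracles.
* **Delay network.**  Method of steps on the sampling grid: terms at zero
  delay form a scalar linear ODE advanced with the same exponential step;
  positively delayed pressures are read from the stored history by linear
  interpolation and delayed derivatives by central differences on the
  stored grid (both O(dt²)).  The history is constant `P_init` for `t ≤ 0`.
  The grid must satisfy `dt ≤ min positive τ / 4` so delayed terms lie
  strictly in the past ("refine dt" otherwise).  The gap to the lumped ODE
  shrinks linearly with the delay scale (~2× per halving), as the
  first-order Taylor remainder predicts.
* **Fiducials.**  Derivatives for fiducial detection are central
  differences after Savitzky–Golay smoothing (default window 20 ms, cubic),
  since max −dP/dt is noise-sensitive and no smoothing rule is standard.
  End-systole is the global minimum of smoothed dP/dt after the foot, ties
  broken to the earliest sample; on simulated three-element beats at
  dt = 1 ms it lands within 10 ms of the true inflow-cessation time, and
  the bias vanishes when the smoothing window is scaled down with dt.  Beat
  feet are the maxima of the second derivative in a short window before
  each systolic upstroke; feet closer than `min_period` are merged.
* **Diastolic window.**  Defaults to [t_es + 30 ms, t_end − 30 ms]: the
  leading guard skips the end-systolic transition, the trailing guard the
  pre-systolic perturbation from the next beat's isovolumic contraction.
  Both guards are configurable; the window end-points used in published
  analyses are not standardised.
* **Decay fit starts.**  Levenberg–Marquardt from several deterministic
  starting points (`k_d ∈ {0.3, 1, 3}` 1/s, `P_∞ ∈ {0, 0.7, 0.95}× min
  window pressure`), best SSE kept — no randomness, so results are
  bit-reproducible.
* **Units.**  mmHg / mL / s at every interface; vessel geometry is SI
  internally with the conversion pinned at 133.322 Pa/mmHg.  Velocity
  input (m/s) is accepted everywhere; `R` and `C` are then per-area
  (resistance × area, compliance / area, flagged `per_area`), their product
  `RC = 1/k_d` invariant to any rescaling of the flow trace.

## 3. Synthetic data

The generator defaults define the benchmark conditions used throughout the
tests: half-sine systolic inflow (`T_sys = 0.3 s`, `T_beat = 1.0 s`,
`SV = 70 mL`, so `Q_pk = π·SV/2T_sys ≈ 366.5 mL/s`), `dt = 1 ms`, 10 beats,
and Windkessel parameters around `R = 1.2 mmHg·s/mL`, `C = 1.4 mL/mmHg`,
`Z_c = 0.05 mmHg·s/mL`, `P_zf = 20 mmHg` — typical adult-human systemic
values.  The half-sine is not a measured flow profile; it was chosen
because it is smooth, exactly integrable, standard in Windkessel
benchmarking, and its cessation time defines the true end-systole for
fiducial validation.  Additive Gaussian pressure noise with a caller-owned
seed is the single source of randomness.

What the synthetic data does **not** emulate: reflected-wave fine
structure, the dicrotic notch, respiratory and beat-to-beat variability,
measurement drift, cuff-calibration error, and nonlinear (pressure-
dependent) compliance or resistance.  Passing the recovery suites therefore
shows the estimators are correct *for the model class they assume*; it does
not certify accuracy on clinical waveforms, where the mono-exponential
diastole itself is an approximation.

## 4. Meta-analysis

Study-level records (mean, SE, n; SD converted at ingest as `se = sd/√n`)
are pooled with the DerSimonian–Laird moment estimator:
`Q = Σw_i (y_i − ȳ_w)²` with fixed weights `w_i = 1/se_i²`,
`τ² = max(0, (Q − df)/(Σw − Σw²/Σw))`, random weights `1/(se_i² + τ²)`,
and a normal-approximation 95 % CI.  This matches the historical default of
the standard commercial package for the field.  Known property: with
substantial heterogeneity the z-based CI undercovers by roughly two points
(~93 % at k = 20, τ = 6 mmHg, SE ∈ [1, 4] mmHg — the package's own
calibration simulation); Knapp–Hartung adjustment would repair this but is
deliberately not the default, to stay comparable with the literature the
toolkit is meant to audit.  The prediction interval is the
Higgins–Thompson–Spiegelhalter form `pooled ± t_{0.975,k−2}·√(τ² + SE²)`
(k ≥ 3).  Paired differences (e.g. P_zf − MCFP from the same animals)
assume within-study independence of the two arms — conservative for the
usual positive correlation, and flagged with a warning, since within-study
correlations are essentially never reported.  The Egger test is OLS of the
standardized effect on precision (intercept = asymmetry, t with k−2 df);
meta-regression uses the method-of-moments residual `τ²` with weighted
least squares; subgroup heterogeneity compares subgroup pooled means by a
between-group Q against χ² with (groups − 1) df, excluding subgroups with
fewer than two studies.

## 5. Known limitations

* The lumped reservoir is an O(τ) approximation; with transit times pushed
  to the 80 ms budget the network/lumped discrepancy reaches a few mmHg at
  the root.  Full 1-D wave propagation (branching impedances, re-reflection,
  visco-elastic walls) is out of scope.
* The diastolic mono-exponential is a single-time-constant idealisation;
  multi-exponential decays are deliberately not fitted, and the weak
  identification of `P_∞` over short diastoles (< half a time constant)
  produces ±3–4 mmHg scatter at 0.5 mmHg noise — quantified in the test
  suite's Monte Carlo.
* `estimate_rc` folds `Z_c` into `R` when the generator is three-element
  (see §1); the pressure-only rates do not share this bias.
* The excess-pressure–inflow proportionality is an empirical proximal-aorta
  observation; at distal sites, and in aortic valve disease, it degrades.
* Alternative definitions of excess pressure (local-flow-proportional), the
  `P_res = 2·P_b` wave-separation relation, ECG-gated beat detection, and
  ensemble averaging are not implemented.
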