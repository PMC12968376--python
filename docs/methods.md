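# Methods

## Models

Two deterministic descriptions of power decline during a maximal cycling
sprint are implemented on a shared substrate, the fatigue-free linear
force-velocity profile `F(PR) = a·PR + F_max` (cadence `PR` in rpm at
interfaces, rev/s internally; conversion 1/60). Power is force times
tangential pedal speed, `P = F·2πr·PR` with `PR` in rev/s.

**Time-based decay (PASA).** Only the intercept decays,
`F_max(t) = (F_max − C_F)·exp(min(0,−(t−TD)/τ_F)) + C_F`; the slope is
untouched (parallel shift). Assumptions: the fatigue-free relation is linear
(empirically reliable for multi-joint cycling), fatigue expresses itself as a
loss of force-generating capacity uniform across cadence, and a residual
force `C_F` remains indefinitely sustainable (the critical-power rationale).
`A_F = F_max − C_F` is the decay amplitude; the identity `F_max = A_F + C_F`
is enforced structurally (the amplitude is never stored separately).

**Stroke-based decay (PESA).** Peak power at the evaluation cadence decays
geometrically per completed pedal stroke,
`P(n) = P_peak·(1−Δ)^max(0, n−ND)`. Assumptions: fatigue is driven by the
count of maximal contractions, not elapsed time, and the relative per-stroke
loss `Δ` is cadence-invariant. The legacy linear form
`P_peak·(1 − Δ·max(0, n−ND))` is retained solely to exhibit its
non-physiological zero crossing near `n = ND + 1/Δ`. The exponent is allowed
to be real-valued when the model is evaluated in time through the stroke
clock `n(t) = ∫PR dt` (trapezoidal integration of the cadence series, exact
for piecewise-linear cadence); integer stroke indices are used when scoring
per-revolution data.

**Duality and congruence.** At constant cadence the time form is exactly a
geometric per-stroke decay with `ΔF_max = 1 − exp(−1/(PR·τ_F))`; the
stroke-form uses the integer completed-stroke delay `ND = floor(PR·TD)` and
coincides with the time form at every stroke boundary (machine precision; a
grid test holds it to 1e-9). Inverting the decrement gives the congruence
condition `τ = 1/(PR·ln(1/(1−Δ)))`: one cadence per `(Δ, τ_F)` pair at which
the two *decay laws* coincide. The full power surfaces still differ there,
because the time-based model shifts the line (the `a·PR` term does not
scale) while the stroke-based model scales its whole profile; the congruence
statement is therefore about normalized fatigue trajectories, and the
divergence map shows the power-level disagreement growing with cadence and
time regardless.

## Calibration

1. **Fatigue-free profile.** Up to 4 acceleration revolutions (end time
   < 3 s, below target cadence) plus up to 3 highest-power revolutions at
   ≥ 160 rpm from the low-resistance motoric sprints; ordinary least squares
   of force on cadence. With no motoric points the fit degrades to an
   extrapolation and a warning is emitted.
2. **Time-based fit.** Constrained nonlinear least squares on per-revolution
   power (trust-region reflective) under `A_F > C_F > 0`, `0 < τ_F < 100 s`,
   `TD ≥ 0`. Default parameterisation fixes `F_max` to the measured
   fatigue-free intercept, so the free parameters are `(C_F, τ_F, TD)` and
   the ordering constraint reduces to the box `C_F < F_max/2`; a boundary
   solution is flagged. `fix_fmax=False` frees the amplitude via
   `(C_F, gap, τ, TD)`. Initialisation: `τ₀ = 30 s`, `C_F₀ = 0.4·F_max`,
   `TD₀` at the observed power peak; up to 5 multiplicatively jittered
   restarts from a fixed restart seed. The fit window is the isokinetic
   regime (from target-cadence attainment): the acceleration revolutions
   follow a prescribed ramp whose analytical role is to supply F-v points,
   so including them would let the ramp idealisation bias `TD`. With `F_max`
   fixed, `TD` remains identified from post-onset data alone.
3. **Stroke-based parameters.** `ND` by the decline rule — the stroke at
   which the first run of ≥ 5 consecutive strictly decreasing per-stroke
   powers begins (ties break a run; tolerance configurable, default 0 W),
   scanning from target-cadence attainment. Under uncorrelated multiplicative
   noise adjacent per-stroke losses are anti-correlated and strict runs
   become rare, so the full pipeline cross-checks the rule against the
   stroke/time conversion `ND = n(TD̂)` from the fitted delay and falls back
   to the conversion when the rule lands more than 5 strokes later (or not
   at all); the report records which source was used. `Δ` is the arithmetic
   mean of relative per-stroke losses `1 − P(i+1)/P(i)` for strokes after
   `ND` within the window (15 s and full-sprint variants), with the loss SD
   reported alongside. `Δ_opt` minimises the RMSE of the exponential stroke
   model over the post-onset revolutions with `ND` held fixed — a
   deterministic 1-D bounded search over `Δ ∈ (0, 0.2]` in which the peak
   power is concentrated out analytically (for each `Δ` the optimal
   `P_peak` is the closed-form least-squares scale of the decay shape).
   This quantifies the stroke model under ideal calibration; the
   single-revolution maximum is upward-biased by roughly two noise SDs over
   ~95 revolutions, which would penalise the optimized variant for a reason
   unrelated to its decay structure (`fit_peak=False` restores the
   fixed-empirical-peak behaviour, which the `Δ₁₅`/`Δ₄₅` variants always
   use). All model variants are scored on the same post-onset revolution
   set, so their RMSEs are comparable.

## Convergence analysis

Default grids: cadence 60–180 rpm in 5 rpm steps, time 0–60 s in 0.5 s steps.
Relative error is normalised by the time-based prediction (the reference
model); cells where that prediction is non-positive fall outside every
corridor (except the trivial ε = ∞ corridor, which admits everything). Each
model keeps its own delay convention (TD in seconds, ND in strokes). For
cadence-resolved comparison the stroke model's fatigue-free peak is read off
the same linear profile that underlies the time-based model, so map
differences isolate the decay laws; a cubic power-velocity profile carried
by the stroke parameters is used instead when present. Per-cadence OLS of
stroke-based on time-based predictions summarises agreement (slope ≈ 1 at
moderate cadence, falling with cadence as stroke accumulation outpaces the
exponential time decay).

## Synthetic data

The generator emulates the identification protocol: a stationary start, four
acceleration revolutions at 35/65/85/96% of the 135 rpm target (span
≈ 2.9 s) with forces on the fatigue-free line, then isokinetic revolutions at
the target until 45 s; two 6 s motoric sprints ramp toward ~94% of `PR_max`
and provide ≥ 160 rpm fatigue-free points. Isokinetic revolutions follow the
chosen truth model (time-based at end-of-revolution time stamps, or
stroke-based at integer stroke counts). Noise is multiplicative lognormal
per revolution (mean 1, default CV 3%, independent across revolutions; an
optional linear CV growth emulates the larger late-sprint stroke-to-stroke
variability of real sprints), applied identically to force and power so
`P = F·2πr·PR` is preserved; power is clamped at zero, though lognormal
noise on a positive truth never reaches it.

Athletes are drawn from truncated normal marginals matching the published
elite cohort (overall: `F_max` 1207±245 N, `a` −4.53±0.76 N/rpm, `τ_F`
38±12 s, `C_F` 483±129 N, `TD` 2.55±0.53 s; sex-specific baselines for
force/slope where a sex is requested), independently — marginal SDs are
published without correlations, a flagged simplification. Joint screening
enforces `A_F > C_F > 0`, `PR_opt ∈ [100, 160]` rpm, and a sustained-effort
condition: the end-of-sprint force at the target cadence must stay at or
above 5% of the fatigue-free force (~70 W at 135 rpm for the cohort mean),
since isokinetic sprints end by time with physiologically meaningful power,
not by collapse. Because rejecting whole draws would skew the `τ_F`
marginal upward (fast decayers need high asymptotes to finish), `τ_F` is
drawn first and only the partner parameters are redrawn against the
constraints; `τ_F` itself is redrawn only when no compatible partners exist
(the rare fast-decay tail). The realised `τ_F` marginal is 38.3±11.4 s over
1000 draws. The stroke-based truth is derived from the time-based one —
`Δ` from the per-stroke decrement of `τ_F` at the protocol cadence, `ND`
from `TD`, `P_peak` from the fatigue-free line — keeping the truth families
comparable. All randomness flows from one seed through `SeedSequence`
spawning; traces record their provenance in metadata.

**What passing tests do and do not show.** The generator reproduces the
study's protocol structure, parameter scales and noise level, so recovery
and hierarchy results demonstrate the pipeline's correctness under those
conditions. It does not reproduce physiological autocorrelation of
stroke-to-stroke variability (white noise makes the strict decline rule
fire late — real per-stroke power is smoother around its trend), crank-angle
dynamics within revolutions, cadence drift around the isokinetic target, or
parameter correlations across athletes; conclusions about real data
transfer only to the extent those features are second-order.

## Statistics

Implemented from sums of squares and closed-form statistics; scipy supplies
only distribution tail probabilities. Two-sided p-values throughout,
α = 0.05. The repeated-measures ANOVA computes the Greenhouse-Geisser
epsilon from the double-centred condition covariance matrix
(`ε = tr(S̃)²/((k−1)·ΣS̃²)`, clipped to `[1/(k−1), 1]`; `ε = 1` exactly for
two conditions) and reports partial eta squared. The Pitman-Morgan test for
correlated variances uses
`t = (s₁²−s₂²)·√(n−2)/(2·s₁·s₂·√(1−r²))` on `n−2` degrees of freedom (sign
convention `s₁²−s₂²`). Hedges' g applies the small-sample correction
`J = 1 − 3/(4·df−1)` to the pooled-SD standardised difference. The
two-factor (model × sex) mixed design is deliberately reduced to the one-way
repeated-measures ANOVA across models plus independent-sample sex
contrasts; the interaction term is out of scope. Shapiro-Wilk/Levene
pre-checks are not re-implemented (standard library territory); the CLI
report exposes the raw per-athlete table so they can be run externally.

## Numerical choices and degenerate inputs

- R² about the observed mean; for constant observations it is 1 for a
  perfect fit and −∞ otherwise (undefined variance explained).
- `goodness`, `estimate_delta` and the ND rule operate on observed (not
  model-smoothed) power; smoothing would couple the empirical stroke
  parameters to a model choice.
- The ND rule requires *strict* decreases; equal consecutive powers break a
  run (measurement-scale ties are handled by the configurable tolerance).
- Empirical `Δ` estimates from noisy windows may be slightly negative; they
  are reported raw and clipped to `[0, 1)` only when a stroke-model variant
  is scored with them (flagged).
- Forces above `PR_max` are returned negative, never clamped, keeping the
  convergence algebra exact; clamping exists only in the generator's
  power output.
- Degenerate fits raise (`< 2` distinct cadences, `< 10` revolutions in the
  fit window, no decline run, empty Δ window, perfectly correlated samples
  in the variance test).

## Known limitations

- A scalar `P_peak` is only meaningful at its calibration cadence; the
  cadence-resolved cubic profile is optional and unused by the isokinetic
  pipeline.
- When the truth stroke delay falls inside the acceleration phase, `(P_peak,
  ND)` is identified only up to the exact equivalence
  `(P_peak·(1−Δ)^k, ND+k)`; fitted parameters may differ from generating
  ones while predictions coincide.
- With `F_max` freed and no plateau revolutions in the fit window, `(A_F,
  TD)` are identified only jointly.
- `Δ`'s cadence-invariance is a model assumption, not a finding; the
  convergence module is the tool that exposes its consequences.

## Problem sizes

Defaults used by the test suite and the acceptance script: single traces of
~98 revolutions; 12-athlete cohorts for hierarchy and reporting; 100 seeded
athletes for recovery medians; 2000 replicates at n = 12 for the variance
test's type-I rate; duality and congruence grids of a few thousand points.
These sizes give CLT-stable summaries while keeping any single check in
seconds.
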