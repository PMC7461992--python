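# Methods

## Model

The dose of hyperbaric oxygen accumulated over a continuous exposure of
`t` minutes at oxygen partial pressure `PO2` (bar) is summarised by the
CNS-OT index `K = t²·PO2^c`. Symptom onset is modelled as lognormal in
the index: `½·ln K` at onset is Normal(μ, σ), so

    risk(K) = Φ((½·ln K − μ) / σ)

and the 50%-risk critical index is `Kc = exp(2μ)`. Equivalently, onset
time at fixed PO2 is lognormal with location `μ − (c/2)·ln PO2` and
scale σ — a lognormal accelerated-failure-time (AFT) model in which
PO2 acts as a time-acceleration covariate with coefficient −c/2. The
two views are the same object; the test suite asserts their identity
exactly.

Assumptions worth stating plainly: risk depends on the exposure history
only through K (a single-compartment dose); the quadratic time term and
the power-law PO2 term are separable; individual susceptibility enters
only through the population scale σ; σ is constant across PO2. The
model is calibrated for resting metabolic rate (1 MET), separately for
thermoneutral immersion and dry chamber exposure.

Sources of the printed notation: some texts print the transform as
`ln(K^0.5)` and others as `ln(K)^0.5`; this package reads both as
`½·ln K`, the only reading under which `Kc = exp(2μ)` reproduces the
published critical indices (the internal-consistency test enforces
agreement within 1%).

## Parameter registry

| name            | condition | MET | c     | μ     | σ    | Kc        |
|-----------------|-----------|-----|-------|-------|------|-----------|
| `immersed_rest` | immersed  | 1   | 10.93 | 8.99  | 0.81 | 6.42×10⁷  |
| `dry_rest`      | dry       | 1   | 12.99 | 11.34 | 0.65 | 7.10×10⁹  |
| `active_4_4`    | active    | 4.4 | 6.8   | 9.63  | 2.02 | exp(18.02)|

For the two at-rest sets `|ln Kc − 2μ| < 0.02` (printed rounding). The
active-diving set stores Kc as exp(18.02) as published even though that
is not exp(2·9.63); both values are kept as printed rather than
reconciled, and the Kc≈exp(2μ) invariant is asserted only for the
at-rest sets. Units: t in minutes, PO2 in bar throughout; K in
min²·bar^c. Converters from ATA and kPa are provided but never applied
implicitly.

### MET interpolation

Between the fitted submerged endpoints (c = 10.93 at 1 MET, ≈6.8 at
4.4 MET) the exponent falls linearly, `c = 12.14 − 1.21·MET`, with a
constant critical index 6.57×10⁷. Evaluating the printed formula at
4.4 MET gives 6.816 (the published endpoint is rounded to 6.80); the
formula is authoritative for the operation. No σ is available between
the endpoints, so `interpolate_met` returns a deliberately risk-incapable
type: any attempt to compute a probability from it raises
`UnsupportedOperationError` rather than silently substituting a scale.
MET outside [1, 4.4] requires an explicit `extrapolate=True` and
attaches a warning.

## Profile accumulation

A profile is an ordered list of oxygen and air segments. The running
index starts at 0 and advances as:

- oxygen segment (PO2 p, duration d):
  `K ← (t_eq + d)²·p^c` with `t_eq = √(K/p^c)` — the oxygen time at p
  that would have produced the carried-over K. This also handles PO2
  changes without a break. Equivalently, K follows the ODE
  `dK/dt = 2·√K·p^(c/2)`; the test suite checks agreement with a
  0.001-min-step brute-force integrator to within 0.1% relative K.
- air segment (duration d): `K ← K·exp(−0.079·d)`; the recovery rate
  0.079/min is a model constant. Air breaks are *pure recovery*: the
  ~0.6 bar oxygen in chamber air at treatment depth contributes no
  accrual. Only this treatment reproduces the worked treatment-table
  predictions (1.16% and 12.7%).

Unlabelled segments are classified by a configurable PO2 threshold
(default 1.0 bar — conservative, since the toxicity data envelope
starts above 2 bar). The "1 h at 2.5 bar with a 10 min air break"
treatment is encoded as two 30-min oxygen segments (the break does not
count toward the hour); this is the only reading that reproduces the
1.16% prediction. Risk is reported at segment boundaries by default,
with an optional fixed-step densification. All index arithmetic is
carried in the log domain: with c up to ~13, naive powers overflow.
K = 0 maps to risk 0 (the continuous limit) so zero-length profiles
evaluate cleanly.

## Survival fitting

`PowerEquationAFT` maximises the right-censored lognormal AFT
likelihood: events contribute the log density of onset time at location
`μ − (c/2)·ln PO2`, censored records the log survival at exposure end.
Event records are treated as exact onset times and symptom-free
exposures as right-censored — the standard AFT reading of data whose
historical sources mix conventions. A single σ is fitted per condition
by pooled MLE.

Numerics: quasi-Newton (L-BFGS-B) on (c, μ, ln σ) with an analytic
gradient; five deterministic starts on an exponent grid
{4, 8, 11, 14, 18} with moment-matched (μ, σ) initialisation, keeping
the best optimum; convergence tolerance 1e−8 on relative objective
change. A fit is flagged converged when the optimiser succeeds and the
projected gradient is small, judged either by norm or by the Newton
decrement `½·gᵀH⁻¹g` — the decrement is the curvature-aware criterion
that behaves correctly in the near-degenerate small-σ limit where the
information grows like 1/σ². Standard errors come from the inverse
observed information (central differences of the analytic gradient in
optimisation coordinates, delta-method-mapped to (c, μ, σ)); 95% CIs
are normal-approximation for c, μ, σ and lognormal for Kc via
`exp(2μ ± 1.96·2·SE_μ)`. Identifiability is enforced up front: at least
one event and at least two distinct PO2 levels (c is confounded with μ
at a single level). The fit was cross-validated in the test suite
against an independent AFT implementation (lifelines) to 4+ decimals.

Model comparison: the joint Wald statistic on the (c, μ, σ) difference
vector with summed covariances, and the likelihood ratio
`2·(ll_immersed + ll_dry − ll_pooled)`, both chi-square with 3 df.

## Synthetic data

`simulate_records` draws onset times from the exact generating process
the fit assumes and censors at the scheduled exposure end — so
parameter-recovery and calibration tests measure estimator quality, not
model misspecification. Default envelopes mirror the published study
conditions: immersed PO2 2.26–3.24 bar with censoring at 120 min, dry
2.55–3.67 bar with censoring at 180 min. σ = 0 is allowed as a
degenerate deterministic limit for testing.

The embedded group table ships the compiled human at-rest exposures as
printed (three immersed groups totalling 219 exposures/105 events;
seven dry groups totalling 507/136), keyed by (condition, PO2, n) since
PO2 values repeat. The zero-event outlier group (PO2 2.54 bar, 120 min,
n = 14) that was dropped from the published analysis after a
goodness-of-fit assessment is shipped with an explicit `excluded` flag
and filtered by default — a documented filter, not a hidden one; its
condition label (dry) is inferred from its PO2 and the dry totals. Two
printed immersed PO2 values (4.08, 3.44 bar) lie outside the stated
immersion range; the table is stored as printed, discrepancy noted, not
resolved.

`expand_groups` reconstructs individual records from group summaries by
lognormal moment matching (lognormal, not normal, because times are
positive and the model is lognormal). The output preserves group sizes,
event counts and first two moments, but **not** the real joint
time/outcome structure — event times and censoring times are drawn from
the same marginal — so it is flagged `reconstructed` and is
demonstration data only. Individual-level source data were never
published, which is also why the fitted registry constants are not
re-derivable here: they serve as constants and as simulation truths,
and the estimator is validated by parameter recovery instead.

## What passing tests do and do not show

Simulation-based tests (parameter recovery within sampling error, 95%
CI coverage over replicates, Wald/LR size ≈ 5% under equality and
decisive rejection at the published parameter sets and sample sizes)
validate the estimator under the model's own assumptions. They do not
validate the model against real physiology: no inter-subject frailty,
no time-varying susceptibility, no interval censoring of grouped
historical data. Problem sizes used by the default suite — a 20,000
record fit, 200-replicate coverage and calibration runs at n = 2,000
and n = 600 — were chosen to make Monte-Carlo error small relative to
the tolerances being asserted.

## Known limitations

- Valid for rest (1 MET) and the fitted 4.4 MET set; interpolated
  workloads give dose only.
- No pulmonary oxygen-toxicity (UPTD/OTU) modelling, no water
  temperature corrections, no compression/decompression schedule
  modelling or gas mixing.
- The recovery constant 0.079/min is shared across conditions and
  assumed independent of PO2 history.
- Fits assume a shared σ per condition; heterogeneous historical
  sources may violate this (a per-source σ diagnostic can be obtained
  by fitting sources separately).
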