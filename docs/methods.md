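# Methods

## Model overview

The package evaluates two-arm vitamin D3 supplementation trial designs
for cancer incidence on the expected-value scale. Three components are
composed:

1. a **dose-response curve** mapping serum 25(OH)D concentration
   (ng/mL) to a disease odds ratio,
2. a **status-response model** mapping (baseline concentration, daily
   dose) to the achieved concentration after sustained supplementation,
3. an **expected-case model** distributing person-years over deciles of
   the baseline-status distribution and converting odds ratios into
   expected case counts per arm.

The expected counts then feed ordinary 2×2 statistics (Woolf interval),
a required-sample-size scan, and a Monte Carlo simulator that replaces
the expected counts with binomial draws.

### Assumptions

- The association between 25(OH)D and cancer incidence is causal,
  multiplicative on the odds scale, and common to all deciles; the
  breast-cancer-derived power law stands in for all-cancer incidence.
- Hazards are constant per person-year; person-years are exchangeable
  within a decile (one participant followed three years contributes the
  same as three followed one year).
- Treatment acts only by moving a participant's concentration from
  baseline to achieved; no lag between status change and risk change,
  no dropout, non-compliance, seasonality or control-arm contamination.
- Effects are evaluated on expected counts: the "required N" criterion
  (upper confidence bound below 1.0 at the expected counts) corresponds
  to roughly 50% power at the boundary, not 80/90% power in the formal
  sense. The simulator quantifies the actual power.

## Components and parameters

### Dose-response (`dose_response`)

OR(c) = coefficient · c^exponent, defaults 18.3 and −0.833 (ng/mL
scale), stored at the published precision and not re-derived because
the underlying study-level points are not tabulated. OR = 1 falls near
33 ng/mL; OR(11) ≈ 2.48. The curve has an evaluation floor
(`min_concentration`, default 1 ng/mL): the power law diverges at zero,
and concentrations below ~4 ng/mL are not physiological, so requests
below the floor raise an error rather than clamp — bad inputs should
surface. `fit_power_law` is ordinary least squares of log OR on log
concentration, provided for users substituting their own
outcome-specific association. Units are ng/mL throughout; ×2.5
converts to nmol/L, and the conversion is never applied implicitly.

### Status response (`status_response`)

Two backends, because the published calibration grid cannot be
recovered from the three published increment anchors by simple
integration; fidelity and smoothness are separate goals.

- **`calibration_table`** (canonical for reproducing published
  designs): achieved concentrations for ten baseline deciles
  (11–40 ng/mL, Canadian adults 50–79 y) × doses 400/1000/2000/4000
  IU/d, stored verbatim. A zero-dose column equal to the baseline
  anchors interpolation at the identity. Queries between grid nodes use
  bilinear interpolation (linear in dose and in baseline); queries
  outside the grid are clamped flat to the nearest edge rather than
  extrapolated — the data say nothing beyond 4000 IU/d. Two grid cells
  (baseline 11 ng/mL at 400 and 1000 IU/d) exceed the neighbouring
  decile's values; they are stored as published and flagged with a
  `CalibrationWarning` at construction, never silently corrected.
- **`parametric`** (for novel doses/baselines): the rise per 1000 IU/d
  is g(c) = A·exp(−c/τ) + B, with (A, τ, B) solved exactly from the
  anchors (0, 13), (28, 4), (140, 2) ng/mL — A ≈ 11.002, τ ≈ 16.433,
  B ≈ 1.998. The form is the simplest smooth, positive, strictly
  decreasing three-parameter family through three anchors, and the
  decay mirrors the physiology (CYP24A1 catabolism rises with status).
  Achieved concentration integrates dc/dD = g(c)/1000 by fixed-step
  Euler with a 100 IU/d step; the fixed step makes sequential dosing
  exactly additive (2000 IU/d in one pass equals two 1000 IU/d passes)
  and the truncation error is far below the grid's ±1 ng/mL rounding.

### Scenario (`scenario`)

Flat-key YAML configs with documented defaults, logged at load time so
any rendered result is auditable. Defaults: the ten-decile Canadian
50–79 y population, incidence rate 0.0176 cases/person-year (1760 per
100,000/yr, US all-cancer incidence at ages 65–69), dose 2000 IU/d,
α = 0.05, equal allocation across selected deciles. Person-years are
the primitive; a `years` multiplier covers the "N participants × Y
years" bookkeeping, and `treatment_person_years_per_arm` covers unequal
arms. `achieved_override` pins the treatment-arm concentration
directly, for single-cohort designs specified as "baseline b achieving
a". A zero incidence rate is tolerated (for null simulations) although
the analytic 2×2 statistics then have empty cells and refuse to run.

### Expected cases (`expected_cases`)

control_i = r·N_i·OR(b_i)/mean(OR); treatment_i uses OR(a_i) with the
same normalization. Two normalization choices are deliberate:

- **Mean, not sum.** Dividing by the arithmetic mean of the baseline
  ORs over the ten reference deciles makes the untreated full
  population reproduce r·N_total exactly (conservation); with equal
  allocation this is algebraically the same as r·N_total·OR_i/ΣOR.
- **Baseline mean, full population, always.** The treatment arm and
  any sub-population (a decile subset or a single cohort) are
  normalized by the same full-population baseline mean OR. The
  normalization is a property of the reference population, not of the
  enrolled sample; this is what makes single-cohort required-N answers
  consistent with the decile-table answers.

Counts remain fractional expected values internally; one-decimal
rounding happens only in report rendering.

### 2×2 statistics (`trial_stats`)

OR = (a/b)/(c/d) on cells a, b = treatment cases/non-cases, c, d =
control cases/non-cases, with non-cases = person-years − cases. Woolf
interval exp(ln OR ± z·SE), SE = √(1/a+1/b+1/c+1/d); two-sided normal
p on ln OR/SE, so p < α exactly when 1.0 is outside the interval.
Fractional cells are evaluated as-is: the model feeds expected counts
into the same asymptotic formulas as observed integers. z is the exact
normal quantile (1.959964 at α = 0.05). No continuity correction and
no exact test — with expected-count inputs cells are never zero unless
the rate is, and a zero cell raises an explicit error. Both OR and RR
are returned: trial reports in this literature often label odds ratios
"RR", and returning both avoids inheriting that ambiguity.

### Required N (`power_solver`)

The expected-count OR is independent of N while its log-scale standard
error shrinks as 1/√N, so the upper bound is monotone decreasing in N
for a protective effect and the crossing of 1.0 is unique. The solver
therefore evaluates the bound directly on multiples of the step
(default 100 person-years) and returns the first below 1.0 — no curve
is fitted through CI points, because the bound is computable exactly at
any N and a smooth fit would only add method error. A scenario with
OR ≥ 1 raises immediately (no finite answer exists); exhausting
`n_max` (default 10^6) returns a "not reached" sentinel (`None`).

### Simulator (`simulate`)

Person-years are allocated deterministically across deciles (equal
blocks by default); each control person-year becomes a case with
probability r·OR(b_i)/mean(OR) and each treatment person-year with
r·OR(a_i)/mean(OR) — Bernoulli per person-year rather than per-person
multi-year survival, which keeps the hazard scale identical to the
analytic model so the simulated means converge to the analytic expected
counts. Only case events are random, drawn from a single
`numpy.random.default_rng(seed)` stream; results are bit-identical for
a given seed. A replicate is significant when its observed-count Woolf
upper bound is below 1.0; replicates with a zero cell are counted
non-significant rather than dropped (material only at tiny N). Note
the criterion is effectively one-sided at α/2, so the null rejection
rate calibrates near 0.025.

## What the defaults emulate — and what they do not

The default inputs are the study conditions of the published design
analysis: the Canadian 50–79 y decile distribution, the 18.3·c^−0.833
curve, rate 0.0176, and the published achieved-concentration grid.
Passing tests show the arithmetic and its composition are right under
those conditions; they do not show that the power law is the true
all-cancer dose-response, that the calibration grid transfers to other
populations (body weight, genetics and season all shift it), or that
real trials are free of dropout and contamination — none of which the
model represents. The simulator shares every structural assumption of
the analytic model and therefore validates its variance treatment, not
its biology.

## Preset problem sizes

Shipped presets run at the published design sizes (400 person-years
per decile per arm; sum rows at 1000–10,000 person-years per arm), and
every preset renders in well under a second. Simulator checks in the
test suite use 400–2000 replicates, which bounds Monte Carlo standard
errors at a few percent — adequate for the ±3·SE and ±0.15 tolerances
they assert.

## Known limitations

- Expected-count significance is not formal power; use the simulator
  for power at a stated alternative.
- The calibration grid is rounded to whole ng/mL; recomputed per-decile
  treatment cells can differ from published tables by ±0.1 cases, and
  published sum rows built from pre-rounded cells can differ from
  full-precision recomputation in the second decimal of a bound.
- The grid covers 400–4000 IU/d and baselines 11–40 ng/mL; outside
  that range the calibration backend clamps and the parametric backend
  extrapolates its exponential form.
- Two-arm designs only; no stratified (Mantel–Haenszel) estimation, no
  time-to-event modelling, no cost or recruitment constraints.
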