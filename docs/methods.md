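# Methods

## The screening experiment model

A component-screening experiment crosses `k` two-level intervention
components into a full `2^k` factorial. Levels are effect coded −1
(off/basic) and +1 (on/enhanced). The analysis model is ordinary least
squares on the post-intervention score:

```
y_i = b0 + Σ_T b_T · Π_{c∈T} x_ic + b_base · baseline_i + b_age · age_i + e_i
```

where `T` ranges over factorial terms (all 2^k − 1 of them in the full
model; only the "important" ones in the parsimonious refit) and `x_ic` is
participant *i*'s ±1 code on component *c*. With ±1 coding, `b_T` is half
the difference between the outcome means at the term's +1 and −1 levels in
a balanced design, and the coefficients are mutually orthogonal there
(X'X = n·I), so dropping terms leaves the kept coefficients unchanged up
to imbalance. The package reports coefficients in this half-difference
convention throughout, because the screening decision rules consume them
directly.

Standardization is post hoc: `beta = b · sd(x) / sd(y)` with sample
standard deviations from the analyzed data (for a balanced ±1 column
`sd(x) ≈ 1`, so beta is b in outcome-SD units). Inference is the usual
t-based inference at the residual degrees of freedom; confidence intervals
default to 90%, matching the decision-priority convention of weighing
type I and type II errors equally (α = 0.1 two-sided).

Model fitting delegates to `statsmodels.OLS`; the package adds the rank
diagnostics (SVD, rank-deficient when the smallest singular value is below
1e−10 of the largest, offending columns named), the standardization layer,
and the factorial bookkeeping. The test suite checks the fit against an
independent normal-equations solve and against the balanced group-means
identity.

## Sample size

The per-level requirement uses the normal-approximation two-group formula
applied to any single effect-coded contrast, which splits the total sample
into halves: `n/2 = ceil(2 (z_{1−α/2} + z_{1−β})² / d²)`, total
`n = 2 · n/2`. For d = 0.15, power 0.9, α = 0.1 this gives 1,524.
Recruitment inflation divides by (1 − attrition) and rounds to the nearest
integer: 1,524 / 0.95 → 1,604 at 5% anticipated unusable responses.
(Ceiling instead of nearest-integer rounding would give 1,605; the
nearest-integer rule is adopted as this package's convention.)

## Decision engine

Screening follows the all-active-components criterion (best expected
outcome, cost ignored) in three deterministic stages:

1. **Main effects.** Components with an important main effect — two-sided
   p strictly below the importance threshold, default 0.1 — are screened
   in if the coefficient is positive, out if negative.
2. **Interactions**, in effect-hierarchy order: first those sharing a
   component with an important main effect (ascending interaction order),
   then the rest (ascending order), ties broken by canonical factor order.
   Each interaction fixes its still-undecided components at the level
   combination that maximizes the parsimonious-model prediction,
   *restricted to the effects whose components are all in play* (already
   decided, or part of the interaction being examined). Components outside
   this set therefore sit at a neutral reference: effects involving them
   contribute nothing to the comparison. Already-decided components are
   never flipped; an interaction whose components are all decided is
   logged as confirmatory. Ties go to the first candidate in
   all-high-first order — the all-active-components preference for
   switching components on.
3. **Defaults.** Components untouched by any important effect stay at the
   low level (resource management: don't pay for a component with no
   evidence).

The restriction in stage 2 is a deliberate design choice. Scoring
candidates with the *full* parsimonious predictor while parking undecided
outside components at −1 lets a later-stage interaction (for example a
synergistic two-way with a not-yet-examined component) leak into an
earlier, lower-order decision and reverse it — which both violates the
effect-hierarchy principle the stepped procedure is built on and, on the
worked example, contradicts the stepwise narrative the procedure is meant
to formalize. Restricting each comparison to the effects actually in play
makes every step depend only on decisions already taken.

Every step appends a machine-checkable log entry (effect examined,
candidate predictions compared, levels chosen), so a screening result can
be audited end to end.

### Predictions

`predict_condition` evaluates the parsimonious linear predictor at a ±1
configuration in two modes. `table5_compatible` uses the standardized
coefficients with the raw intercept — the convention used in published
prediction tables for this kind of screening report, and what numerically
reproduces the worked example's printed `Ŷ` values. `unstandardized` (the
default for new analyses) uses raw b-weights and accepts covariate values;
it equals the model-matrix inner product exactly. Prediction-table argmax
ties break to the lowest condition id.

## Synthetic cohort generator

The generator emulates the data-generating process the analysis assumes:

- **Baseline.** The necessity−concerns differential is drawn
  `Normal(1.52, 5.36)` (the worked example's baseline descriptives),
  rounded to an integer and clipped to [−20, 20], then split into
  necessity and concerns totals near a configurable subscale sum
  (default 34) so the differential is realized exactly.
- **Assignment.** Simple randomization, uniform over the 2^k conditions —
  per-condition counts are binomial, as in the real design.
- **Outcome.** The truth model above, with defaults taken from the worked
  example's parsimonious fit (patient input 0.361; diagrams×benefits
  0.266; diagrams×side effects −0.163; diagrams×concerns×patient input
  0.160; four-way −0.224; baseline 0.785; age 0.005; intercept 2.319).
  Residual SD defaults to 3.85, chosen once so the follow-up differential
  SD lands near the example's 5.72 given the baseline carry-over
  (√(5.72² − (0.785·5.36)²) ≈ 3.9). The continuous outcome is rounded to
  the nearest integer differential and clipped to [−20, 20]; this
  discretization adds variance ≈ 1/12 and up to 0.5 of per-observation
  error, which parameter-recovery tolerances account for.
- **Items.** A subscale total is split deterministically over its five
  items (floor(total/5) each, remainder to the first items). Post items
  hold the concerns total at baseline and move necessity, spilling across
  the 5–25 bounds when needed, so the post differential is always realized
  exactly.
- **Timing and contamination.** Completion times are log-normal with
  median 9.45 min (positive, right-skewed). `inject_speed_responders`
  contaminates a seeded random subset: completion time below a third of
  the median, or all ten pre (or post) items straight-lined; truth flags
  are returned so filter recovery is testable.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: item-level response processes (items are
a deterministic function of the subscale total, so item covariance
structure is degenerate), demographic joint distributions, informative
missingness (none: the real instrument was mandatory-response), or
response styles beyond straight-lining. Age is truncated-normal
(default mean 46, SD 15, range 18–90) and enters the truth model linearly.

All randomness flows from one `numpy.random.Generator` per operation,
seeded explicitly; identical configurations produce byte-identical tables.

## Simulation studies and problem sizes

- **Power / type-I** (`simulate_power`): each replicate randomizes n
  participants, draws `y = (d/2)·x_T + Normal(0, 1)`, fits the saturated
  factorial model, and tests the focal term two-sided. Defaults: 1,000
  replicates at n = 1,524 — at d = 0.15, α = 0.1 the analytic power is
  ≈ 0.90, and the simulation lands within Monte-Carlo error of it
  (binomial SE ≈ 0.0095 at 1,000 replicates). With d = 0 the same path
  estimates the type-I rate; the mean per-term rejection rate across all
  31 terms is reported alongside the focal term's.
- **Screening accuracy** (`simulate_screening_accuracy`): full
  generate→score→fit→screen replicates; a hit is a screened configuration
  whose *true* expected outcome attains the truth model's maximum.
  Components with zero true effect are free, deliberately: at the lenient
  α = 0.1 importance threshold the expected number of false-positive null
  terms in a 31-term scan is about three per replicate, so demanding the
  exact level set would measure the multiplicity of the threshold, not the
  engine's ability to find the optimum. Default 50 replicates; the test
  suite uses 12–40 at n between 400 and 1,524.

## Numerical and edge-case conventions

- Importance threshold comparisons are strict (`p = 0.1` exactly is not
  important). p-values entered from printed tables as "<.001" are stored
  as 0.0005.
- Condition ids: condition 1 is all components high; the last factor
  varies fastest, high before low. Ids are stable under subsetting: a
  prediction-table row maps its levels back to the full design's id.
- Exclusion median time uses the full pre-exclusion sample, strict
  inequality; straight-lining is judged within the pre and the post
  administration separately. The primary analysis excludes only under-18s;
  speed and breast-cancer-diagnosis exclusions are sensitivity
  configurations.
- Integer rounding is round-half-to-even via numpy where it touches data
  (score discretization) and round-half-up for the attrition inflation.
- Degenerate inputs: zero noise SD, empty term sets, empty exclusion
  results, and all-tied prediction tables are all defined (documented in
  the respective docstrings) rather than errors.

## Known limitations

- The restricted-prediction interaction rule is one formalization of a
  narrative procedure; alternative orderings are supported via
  `order_interactions` but other resolution semantics are not.
- The generator's item-level structure is too regular for psychometric
  work (no IRT, no item covariance); it is built for validating the
  pipeline's arithmetic, not for simulating instruments.
- Covariate offsets in prediction tables are a constant shift supplied by
  the caller; the package does not estimate a canonical "with covariates"
  offset.
- Only complete two-level full factorials are supported — no fractional
  designs, blocking, or stratified randomization.
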