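# mostscreen

Tools for the optimization phase of the multiphase optimization strategy
(MOST): design, simulate, analyze, and make screening decisions for
`2^k` factorial experiments that test which components of a behavioural
intervention are worth keeping.

The package grew out of a concrete use case — optimizing an information
leaflet about adjuvant endocrine therapy (AET) for breast cancer, with five
candidate components (mechanism *diagrams*, *benefits* infographics,
*side-effects* information, answers to common *concerns*, and breast-cancer
survivor *patient input*) and the 10-item Beliefs about Medicines
Questionnaire (BMQ-AET) necessity−concerns differential as outcome — and
that experiment ships as the built-in worked example. Every piece is
generic over any set of two-level components and any bounded Likert
instrument.

## What it does

- **Design** (`mostscreen.design`): enumerate the `2^k` condition table
  with citable condition ids, effect-code levels as −1/+1, build orthogonal
  model matrices for all main effects and interactions, compute the
  screening sample size from the normal-approximation two-group formula

  `n/2 = ⌈2 (z₁₋α/₂ + z₁₋β)² / d²⌉`,

  and assign participants by simple (unconstrained) randomization.
- **Synthetic cohorts** (`mostscreen.cohort`): participant-level tables
  with a configurable truth model — post score = intercept + Σ effect·code
  product + baseline + age + noise, discretized onto the instrument scale —
  plus completion times and injectable "speed responder" contamination, so
  the whole pipeline is testable without any raw data.
- **Measurement** (`mostscreen.measurement`): BMQ scoring (two 5-item
  subscales, differential in [−20, 20]), speed-responder flags (time below
  a third of the median; straight-lined pre or post items), and logged,
  idempotent exclusion rules.
- **Analysis** (`mostscreen.model`): effect-coded multiple linear
  regression (full 31-term model or a parsimonious subset, plus baseline
  and age covariates). Because of ±1 coding each coefficient is *half* the
  difference between level means. Standardized coefficients, 90% CIs,
  t and p per term.
- **Decisions** (`mostscreen.screening`): the stepped screening algorithm —
  important main effects first (p < .1), then interactions in
  effect-hierarchy order, each fixing its undecided components at the
  levels that maximize the parsimonious-model prediction; then predicted
  outcomes `Ŷ` for every candidate condition and the argmax configuration.
- **Pipeline & simulations** (`mostscreen.pipeline`, CLI `mostscreen`):
  end-to-end runs with deterministic artifacts, Monte-Carlo power / type-I
  error at the design stage, and end-to-end screening accuracy under a
  known truth.

## Worked example

The built-in example reproduces the leaflet experiment's published analysis
from its coefficient tables (`mostscreen.published`), no raw data needed:

```sh
$ mostscreen samplesize
n_analysis: 1524
n_recruit:  1604

$ mostscreen screen
screened in:  diagrams, benefits, concerns, patient_input
screened out: side_effects
best condition: 5
```

With d = 0.15, power 0.9 and α = 0.1 the experiment needs 1,524 analyzable
participants, 1,604 after 5% attrition. Screening keeps four of the five
components and drops the enhanced side-effects information (it interacts
antagonistically with the others); condition 5 — everything on except
enhanced side effects — has the highest predicted belief score
(Ŷ = 2.524 on the −20…+20 differential scale). The same thing in Python:

```python
import mostscreen as ms
from mostscreen import published as pub

design = pub.leaflet_design()
res = ms.run_screening_from_tables(
    pub.full_model_table(design), pub.parsimonious_table(design), design
)
print(res["screening"].screened_out)      # ('side_effects',)
print(res["predictions"].argmax_id)       # 5
```

For a fully synthetic run (generate → score → exclude → fit → screen →
predict, artifacts written as CSV/JSON):

```sh
mostscreen analyze --seed 21 -n 1604 --outdir out/
```

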