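# htncea

A Markov microsimulation cost-effectiveness model of antihypertensive drug
treatment versus non-drug management for **stage 1 hypertensive patients
(130–139/80–89 mm Hg) younger than 60 years with high cardiovascular risk**,
from a societal perspective in 2020 US dollars.

The package is aimed at health-economic modellers who want a fully scripted,
testable reimplementation of this kind of decision model: every input is a
published point estimate with its uncertainty interval, every result is
recomputable from a single parameter file, and a deterministic cohort solver
serves as an exact oracle for the individual-level simulation.

## The model

Seven health states: stage 1 hypertension, stage 2 hypertension, acute
stroke, post-stroke, acute MI, post-MI, and death (absorbing). Acute stroke
and MI are one-cycle tunnel states. Cycle length is 1 year with a half-cycle
correction; costs and QALYs are discounted at 5%/year.

- Event rates *r* (per 1000 person-years, stratified by hypertension stage)
  convert to annual probabilities by the constant-hazard form
  *p* = 1 − exp(−*r*/1000).
- Stage-1 → stage-2 progression is an annual probability (24.08%/year).
- Drug treatment applies published relative risk reductions *x* as hazard
  multipliers (1 − *x*) to stage-1 first events, mortality, progression, and
  recurrent events; progressed patients receive usual care in both arms.
- QALYs weight state occupancy by EQ-5D utilities (hypertension 0.90, acute
  stroke 0.63, post-stroke 0.65, acute MI 0.76, post-MI 0.88, death 0).
- Costs accrue by category — stage-1 management (+ drug in the treatment
  arm), stage-2 management + drug, stroke (first-year/subsequent-year), MI,
  and productivity loss (first 10 years, 4.8% lower under treatment).
- Strategies are compared by the ICER ΔC/ΔE against willingness-to-pay
  thresholds of 1–3× per-capita GDP ($10,438.66–$31,315.98/QALY), with
  dominance (ΔC < 0, ΔE > 0) reported as cost-saving.
- Uncertainty: one-way (tornado) analyses over every printed interval, and a
  probabilistic sensitivity analysis sampling beta (rates, probabilities,
  utilities), gamma (costs, CV 25%), and lognormal (treatment effects)
  distributions, summarised as a cost-effectiveness acceptability curve.

See `docs/methods.md` for conventions, assumptions, and limitations.

## Worked example

```sh
htncea base-case
```

```
8-year horizon: drug 5.92 QALYs / $2,605.60; non-drug 5.80 QALYs / $2,584.86; ICER $184.78/QALY
15-year horizon: drug 9.36 QALYs / $3,747.33; non-drug 9.08 QALYs / $3,920.58; dominant (cost-saving)
```

Over 15 years, drug treatment yields 0.29 more QALYs per patient *and* costs
$173 less: the extra stage-1 medication spending ($709.74 vs $85.87) is more
than offset by lower stage-2, stroke, MI, and productivity-loss costs, so
treatment dominates. Over the shorter 8-year horizon the savings have not yet
caught up and treatment costs $184.78 per QALY gained — far below the
$10,438.66 (1× GDP per capita) threshold. Full per-category tables, cohort
traces, and a run manifest are written to `results/`.

The same computations are available as a library:

```python
from htncea import Arm, RunConfig, compare, load_default_parameters, solve_cohort

params = load_default_parameters()
cfg = RunConfig(horizon_years=15)
drug = solve_cohort(params, Arm.DRUG, cfg)
non_drug = solve_cohort(params, Arm.NON_DRUG, cfg)
print(compare(drug, non_drug, wtp=params.wtp_per_gdp).verdict)  # "dominant"
```

Other subcommands: `htncea psa` (10,000-draw probabilistic sensitivity
analysis with CEAC and Welch tests), `htncea tornado`, `htncea scenarios`
(8/15/55-year horizons and productivity exclusion), and `htncea synth`
(synthetic person-time cohort with rate re-estimation).

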