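# Methods

## Model structure

The model follows a closed cohort of stage 1 hypertensive patients
(130–139/80–89 mm Hg, aged < 60, ≥ 3 cardiovascular risk factors) under two
strategies: antihypertensive drug treatment and non-drug management. Seven
clinical states are modelled — stage 1 hypertension, stage 2 hypertension,
acute stroke, post-stroke, acute myocardial infarction (MI), post-MI, and
death — with annual cycles. Acute stroke/MI are tunnel states occupied for
exactly one cycle before the chronic post state, unless a recurrence, a
cross event (MI after stroke, stroke after MI), or death intervenes; a
recurrence re-enters the acute state and re-incurs the first-year event
cost. Death is absorbing. Everyone starts in stage 1 hypertension.

Second-event rates are published in two columns, by hypertension stage. The
model therefore tracks a persistent *stage attribute*: patients who suffer a
first event while in stage 1 keep using the stage-1 second-event column
afterwards; patients who progressed to stage 2 first use the stage-2 column.
There is no progression after a first event (the state diagram has no
stroke → stage-2 arrow). Internally this expands the seven clinical states
to eleven (clinical state × stage attribute, death unstratified); the
expansion is exact and invisible at the API surface.

Two evaluators share one transition model and one accrual convention:

* **Microsimulation** (`run_microsimulation`): one multinomial draw per
  patient-cycle; means carry Monte-Carlo standard errors. Sample-size
  default 100,000, which puts the SE of the 15-year QALY mean near 0.004.
* **Cohort solver** (`solve_cohort`): deterministic propagation of the
  occupancy vector — the exact n → ∞ limit of the microsimulation, used as
  the internal oracle in tests and as the inner evaluator for sensitivity
  analyses. State occupancy is conserved to 1e−12 per cycle and asserted.

## Transition probabilities

Event rates r per 1000 person-years convert to annual probabilities by the
constant-hazard form p = 1 − exp(−r/1000). Each cause converts
independently and the residual 1 − Σp remains in (or, from an acute tunnel,
moves to) the source state. At the published rate magnitudes every cause
probability is below 6% and row sums stay well under 1; this is asserted at
model build. The stage-1 → stage-2 progression input (24.08%/year,
21.72–25.52) is already an annual probability and enters directly.

**Treatment effects.** The published effect values for drug treatment
(stroke 0.85, recurrent stroke 0.68, MI 0.98, recurrent MI 0.73, all-cause
mortality 0.98, hypertension progression 0.61; each with a 95% CI) are
applied as relative risk **reductions**: the drug arm multiplies the
corresponding hazard (or, for progression, the annual probability) by
1 − value. This is the convention under which the source analysis's
published per-arm results are reproduced essentially exactly (see the
acceptance checks), and it matches that analysis's own description of
deriving "RR reductions" from the treatment literature. It is, however, a
strong reading: taken as risk *ratios* the same numbers would imply far
smaller effects (e.g. a 2% rather than 98% mortality reduction), and the
reduction reading implies effect sizes well beyond what blood-pressure
trials typically show for events. The implication is discussed under
Limitations; the convention is a single, documented code path
(`engine._drug_multiplier`), so the ratio reading can be obtained by
supplying complementary effect values.

Effects apply to patients with stage attribute 1. Progressed (stage-2)
patients receive usual care in both arms in the base case — consistent with
stage-2 management costs appearing in both arms of the published breakdown —
and the stage-2 effect column can be switched on via
`RunConfig(apply_stage2_rrs=True)` for scenario use. Cross events and
post-event mortality carry no treatment effect.

## Costs, utilities, discounting

Annual costs (2020 US$, each ±25%): hypertension screening/management 28.71;
one standard-dose drug 88.92; productivity loss 275.38 (non-drug arm) with a
4.8% reduction under drug treatment; stroke 3249.55 first year / 1525.64
subsequent; MI 4710.83 / 428.26. Category attribution: stage-1 occupancy
accrues screening (+ drug in the drug arm); stage-2 occupancy accrues
screening + drug in both arms (stage 2 includes receiving antihypertensive
medication); acute/post event states accrue the first-year/subsequent-year
event cost; productivity loss accrues to all living patients during the
first 10 years of simulation (the cohort's mean early-retirement horizon),
regardless of clinical state. Utilities: hypertension (both stages) 0.90,
acute stroke 0.63, post-stroke 0.65, acute MI 0.76, post-MI 0.88, death 0.

Accrual attaches to state occupancy at cycle boundaries t = 0..H,
discounted by (1 + d)^−t with d = 5%/year (range 0–8% in sensitivity
analyses); boundary 0 is undiscounted. The half-cycle correction is the
trapezoid: weights ½, 1, …, 1, ½ over the boundaries, so a living cohort
accrues exactly H undiscounted years over an H-year horizon. The
productivity window masks the same trapezoid to boundaries t ≤ 10 (no extra
half-weight appears at the window edge; if the horizon ends inside the
window, the terminal half-weight applies). In the zero-event limit the
discounted QALY has the closed annuity form
u·(Σ_{t<H} v^t − ½(1 − v^H)), which the tests check exactly.

Total discounted cost is the sum of the five category totals by
construction, asserted to 1e−6.

## Cost-effectiveness comparison

`compare` classifies the incremental result by quadrant: dominant
(ΔC < 0, ΔE > 0), dominated (ΔC > 0, ΔE < 0), otherwise ICER = ΔC/ΔE; a
zero ΔE is flagged with no ICER. Cost-effectiveness at a willingness-to-pay
threshold λ uses the incremental net monetary benefit λ·ΔE − ΔC, which is
well defined in every quadrant. The threshold anchor is 1× per-capita GDP
($10,438.66 in 2020), with 3× GDP as the upper acceptability bound.

## Sensitivity analyses

**One-way (tornado).** Every printed interval is varied to its bounds — 18
rate CIs, the progression CI, 6 stage-1 effect CIs, 7 cost ranges (±25%), 5
utility ranges, and the discount rate (0–8%) — with the cohort solver.
Entries are ranked by the swing in incremental NMB at 1× GDP (the ICER is
recorded per entry but is unstable for ranking because ΔE can cross zero,
and under dominance the ICER is undefined). Ties break alphabetically so
the ordering is invariant to the input listing.

**Probabilistic (PSA).** Each of 10,000 draws samples every uncertain
input: beta distributions for event rates (fitted on the per-person-year
proportion scale), the progression probability, and utilities; gamma
(shape 16, from CV 25%) for costs; lognormal for treatment-effect values,
with the median at the point estimate and σ from the CI width. Beta fitting
matches the mean exactly (β = α(1−m)/m) and picks α by a bounded
one-dimensional least-squares match of the 2.5%/97.5% quantiles to the
printed interval; a degenerate interval collapses to a point mass. Sampled
effect values map to multipliers clip(1 − x, 0, 1): draws beyond the null
(x > 1) become null effects rather than harms — a conservative truncation
affecting only the extreme tail of the stroke/MI/mortality CIs. The inner
evaluator is the cohort solver, so draw spread reflects parameter
(second-order) uncertainty only; `inner="microsim"` nests first-order noise
if wanted. Outputs: per-draw (ΔE, ΔC) scatter, the CEAC by the NMB rule,
per-arm means/SDs, and Welch two-sample t-tests of per-draw costs and QALYs
across arms.

**Scenarios.** 8-, 15-, and 55-year horizons (55 years ≈ remaining lifetime
for a cohort with mean age 45.9) and exclusion of productivity losses.

## Synthetic cohort generator

`synthetic_cohort` emulates the upstream epidemiology that the rate inputs
summarise: n persons with follow-up drawn Uniform(1.90, 14.56) years — mean
8.23 within the observed range — and independent exponential event times per
endpoint, censored at follow-up; rates are re-estimated as 1000·events/
person-years with exact Poisson (Garwood) 95% CIs, and early-retirement
records (statutory ages 60/55 for men/women, mean early retirement 9.5
years) feed the productivity-loss formula (years early × wage). The wage
default is a synthetic placeholder; the decision model itself uses the
aggregated annual productivity cost input.

What the generator does *not* emulate: competing-risk correlation between
endpoints, longitudinal blood-pressure trajectories behind progression,
cohort demographics, or record-linkage noise. Passing recovery tests
therefore show that the estimators are consistent for the data-generating
process the model assumes — not that the published rates are themselves
unbiased for any real population.

## Numerical choices

* Probabilities are computed with `expm1`/`log1p` to avoid cancellation at
  small hazards.
* The microsimulation draws one uniform per patient-cycle against row-wise
  cumulative probabilities (final column pinned to 1 against round-off);
  identical (seed, config, parameters) runs are bit-reproducible, and the
  two arms use independent streams keyed on (seed, arm).
* Monetary outputs are rounded to cents only at CSV serialisation; all
  internal arithmetic and the ICER use full precision.
* Degenerate inputs: zero rates, zero discount, horizon 1, and empty effect
  maps are all well defined; `compare` flags ΔE = 0 instead of dividing.

## Limitations

* The treatment-effect convention (risk reductions, above) implies event
  and mortality reductions far beyond meta-analytic estimates for
  antihypertensive therapy at this blood-pressure range; results inherit
  that optimism wholesale. The dominance verdict at 15 years is driven by
  the progression and event reductions jointly.
* Published post-event mortality rates (0.2–1.4 per 1000 person-years) are
  implausibly below general mortality (4.1–8.9); the model uses the printed
  values verbatim and does not repair them.
* No age- or sex-specific background mortality, no time-varying hazards, no
  medication adherence, and no covariates beyond the stage attribute.
* The PSA samples all parameters independently; correlations between rates
  (e.g. both stage columns derived from one cohort) are ignored.
* The 55-year horizon extrapolates constant annual rates estimated from a
  mean 8.23-year follow-up far beyond the observation window.
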