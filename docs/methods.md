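# Methods

## Study design

`nestcc` implements a nested case-control study with incidence-density
(risk-set) sampling inside a cohort of antipsychotic initiators.  The
matched odds ratio from conditional logistic regression then estimates the
rate ratio of the underlying hazard — which is why the synthetic generator
simulates a hazard process and why recovery of its exponentiated effects is
the package's central correctness check.

### Cohort entry and screening

Entry is the first antipsychotic prescription inside the enrolment window
(2001-01-01 .. 2022-08-31); earlier clinical information is taken to be
unobservable, so this first observed prescription defines the exposure
clock.  Four exclusions apply, in order: (1) structurally missing
demographics (sex or birth date); (2) death recorded before the first
prescription; (3) lung cancer diagnosed on or before the first
prescription; (4) lung cancer diagnosed before the outcome window opens
(2003-01-01) — 2001–2002 act as a screening period against prevalent
cancer.  An *empty* death date means alive at database end; treating all
living patients as "missing date of death" would empty the cohort, so
exclusion 1 is read strictly as a data-quality rule.  Membership in the
final set is order-invariant; the order matters only for attrition
reporting, where each patient is counted at the first rule that removes it.

### Matching

Cases are first lung-cancer diagnoses (ICD-9-CM 162.x) in the outcome
window at completed age >= 18.  For each case, up to 10 controls are drawn
uniformly without replacement from screened patients who, on the case's
index date, share its sex and completed age in years, had their first
antipsychotic prescription strictly before the index date, have no
lung-cancer diagnosis on or before it, and are alive on it.  Future cases
are eligible — the defining property of risk-set sampling.  A patient may
serve as a control for at most 4 distinct cases (configurable; `None`
removes the cap for the corresponding sensitivity analysis).

Design choices made where the source design is silent:

* **Processing order**: cases are matched in ascending index-date order
  (ties by patient id).  Under a reuse cap the result depends on order, so
  a fixed order is required for reproducibility.
* **Alive at index**: required for controls, because membership in the risk
  set at the index date presupposes being at risk then.
* **Sampling primitive**: a partial Fisher–Yates shuffle of the candidate
  list sorted by patient id, under one seeded generator — platform-stable
  and a deterministic function of (inputs, seed).
* **Singleton sets**: cases with zero eligible controls are dropped and
  logged; the conditional likelihood is undefined for a set of one.
* **Exact age**: "matched by age in years" is implemented as equality of
  completed years, not age bands.

### Exposure

Cumulative exposure before the index date is the number of distinct
calendar days covered by at least one qualifying prescription, truncated at
index − 1 day (exposure must precede the outcome).  Intervals are closed
and a same-day prescription counts as one day, consistent with the
"at least one day of exposure" inclusion rule.  Overlapping prescriptions
are counted once *across* drugs, and — by the package's default — also
*within* a drug group, since raw summing can exceed calendar time; a
`raw_sum` mode is available behind `StudyConfig.flupentixol_sum_mode` for a
literal sum-of-periods reading.

Durations resolve through three levels: (1) both dates present — use
as-is; (2) one date missing but dosage, frequency and quantity present —
duration = ceil(quantity / (dosage x frequency)) anchored at the known
date; (3) otherwise the median duration of the drug's complete records
(global median fallback).  Records with neither date have no anchor and are
dropped with a logged count rather than imputed to an arbitrary position.

Categories: any-antipsychotic 1–365 (reference) / 366–1825 / 1826+ days;
flupentixol and other-antipsychotic groups use a 0–365 reference because
not every cohort member received them.

### Confounders

21 binary flags (NSAIDs, statins, aspirin, metformin; 17 diagnoses) are set
when any matching record falls in [2001-01-01, index date], both ends
inclusive ("between X and the index date" plainly includes the index date;
a strict mode is a one-flag switch).  Drug flags match prescription codes
exactly; diagnosis flags match normalized ICD-9 codes by prefix with the
decimal retained.  The shipped codelists are editable placeholders aligned
with the synthetic generator's vocabulary — they are deliberately not
presented as an authoritative clinical codelist.

### Conditional logistic regression

With exactly one case per set the likelihood is the per-set softmax; no
tie-handling variants arise.  The log-likelihood, analytic gradient
(x_case − softmax-weighted mean) and Hessian (− softmax-weighted
covariance) are evaluated with per-set max-subtraction.  Newton–Raphson
starts at beta = 0 with step-halving (<= 10 halvings per step) and stops
when the gradient max-norm falls below 1e-8 or after 50 iterations.
Standard errors come from the inverse observed information; CIs use the
fixed quantile 1.959964 for bit-stable output.  Any |beta| > 15 at
termination flags `suspect_separation`; no penalization is applied.
Regressors with no within-set variation contribute nothing to this
likelihood, so they are removed before fitting and reported as
inestimable — every other estimate is unchanged by construction.  A
genuinely singular information matrix raises an error naming the collinear
columns.

## The synthetic generator

The generator emulates the *statistical structure* the analysis assumes:
antipsychotic initiators 2001–2022 with overlapping/gapped prescription
episodes, ~2% missing end dates (completely at random; half of those retain
dispensing fields so imputation level 2 is exercised), a flupentixol-user
subset, binary comorbidity/co-medication events, competing death, and a
lung-cancer hazard that depends on the current cumulative exposure
category.

The outcome is a discrete-time logistic hazard on a 30-day grid from the
first prescription: at each step the interval-union exposure is computed,
categorized at 365/1825 days, and an event occurs with probability
expit(baseline + b2·I[366–1825] + b3·I[1826+] + gamma'z); death competes
with constant per-step hazard (cancer is evaluated before death within a
step).  Because every random array's size is independent of (b2, b3), runs
differing only in effect size share their uniform draws — common random
numbers — making the case count monotone in the effect, a property the
tests assert.

Default parameters, chosen once:

| parameter | default | rationale |
|---|---|---|
| episodes per patient | negative binomial, mean 24, dispersion 1 | chronic-user cohort whose cumulative exposure straddles both cut-points |
| episode length | lognormal, median 28 d, sigma 0.9 | typical dispensing cycle |
| gap between episodes | exponential, mean 30 d | interrupted but persistent therapy |
| overlap probability | 0.15 | overlapping prescriptions must exist for union counting to be testable |
| flupentixol | 12% of patients, 80% of their episodes | keeps the flupentixol-category cells populated enough for analysis one |
| baseline hazard logit | −8.8 per 30-day step | yields ≈1.5% incident cases, the case fraction of the emulated cohort (6435 / 445,015) |
| true ORs | 0.5 (366–1825 d), 0.6 (1826+ d) | effect sizes of the magnitude the design is meant to detect |
| death hazard | 0.003 per step | elderly cohort attrition |
| covariate prevalences | per-flag values near a real elderly antipsychotic cohort's | descriptive realism |
| covariate log-ORs | COPD/pneumonia +0.7, tobacco +0.4, schizophrenia −0.6, dementia −0.5, others 0 | a mix of risk and protective confounding signals |

What the generator does **not** emulate: dose–response pharmacology,
smoking behaviour (absent from the emulated source too), private-sector
care fragmentation, informative missingness, or prescriptions stopping at
death (post-death episodes can only inflate exposure after a control's
index date, which is never counted).  Covariates are drawn independently
of exposure, so they add noise but no true confounding; passing recovery
tests therefore demonstrates correctness of the estimator under the
design's assumptions, not robustness to confounding structures the
generator does not contain.

## Problem sizes and numerical choices

Replicate batteries (CI coverage over 100 replicates; null calibration over
200) run the complete pipeline at 20,000 patients per replicate, roughly
250–350 cases each; the single-run point-estimate check and the acceptance
script use 50,000 patients.  These sizes give each replicate enough cases
(~12 per fitted parameter) for Wald asymptotics while keeping the whole
battery inexpensive.

Ties in case identification (two lung-cancer codes on the same first date)
resolve to the lowest code.  Date arithmetic is integer epoch-day based;
completed age compares (month, day) pairs, so a Feb-29 birthday is reached
on Mar-1 of non-leap years.  The union counter is a sort-and-sweep over
interval endpoints verified exactly against day-set enumeration.

## Known limitations

* The default codelists are placeholders; real analyses must supply their
  own (`StudyConfig.covariate_codelists`, editable YAML via `to_yaml`).
* The conditional likelihood assumes covariates are never missing —
  binary flags defined by record presence cannot be.
* Flupentixol's 1826+ category can be nearly empty at small cohort sizes,
  in which case analysis one is reported with a separation flag or the
  affected indicator marked inestimable; this mirrors the low statistical
  power the emulated study itself reports for flupentixol.
* No exact conditional inference, random effects, or dose standardization.
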