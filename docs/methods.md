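# Methods

`claimsignal` implements a directed signal-detection workflow for possible
adverse drug reactions (ADRs) in administrative claims, demonstrated on the
canonical setting of cholinesterase-inhibitor (AChEI) treatment in an older
dementia-diagnosed population. This note documents the models, the protocol
constants and their defaults, the synthetic-data generator, and the numerical
and design choices a maintainer would want to know.

## Study designs

Two complementary designs are built from the same claims bundle.

**Propensity-matched new-user cohort.** Exposure eras are reconstructed from
dispensing dates and days-supply (stockpiling rule: a fill begins the day the
previous supply runs out if dispensed early); a supply gap of
`course_gap_days` (60) or more ends a course, which persists
`course_tail_days` (60) past its last supplied day. The incident course is
the first one preceded by a `washout_days` (180) window that is fully inside
the study period, fully enrolled, free of any anti-dementia dispensing
(`excluded_classes`), and contains at least one medical claim. Follow-up for
treated subjects starts at the incident first dispensing; untreated subjects
(dementia-diagnosed, never dispensed an anti-dementia drug) are indexed at
their first outpatient dementia visit allowing the same fully observed
baseline, which defines an indicated population engaging care. Prevalent
users fall in neither arm.

Outcomes are episodes of care: medical claims whose *primary* diagnosis is
in an outcome group, clustered so that a new episode requires a
`episode_gap_days` (28-day) claim-free gap, measured in days between
consecutive claims. Person-time is discretized to 1-week bins from the index
day; weeks inside temporary enrollment gaps carry no person-time, and only
death, terminal disenrollment, study end, or (in the default `as_treated`
mode) course end censors.

For each outcome a logistic propensity model (all baseline covariates in
`covariates[outcome]`) is fitted, and 1:1 greedy nearest-neighbour matching
without replacement is performed within a caliper of `caliper_sd` (0.2)
standard deviations of the logit score: the distance is Mahalanobis over the
logit score plus the key prognostic covariates (default age, comorbidity
count, clinic-visit count), with exact constraints (the outcome's own
baseline-episode flag; hospice for death) and banded age (+-5 years) for the
death analysis. Balance is reported as Welch t / uncorrected Pearson
chi-square p-values plus standardized mean differences; these are
diagnostics, so no multiplicity adjustment is applied.

Hazard ratios come from a Cox model on the weekly counting-process table
with episode starts as recurrent events, Breslow tie handling (person-time
is genuinely discrete here), each matched pair a stratum, and a robust
sandwich variance clustered on the pair (on the subject for the single-
stratum crude fit). Pair-level clustering matters: the two members of a pair
contribute dependent score terms, and subject-level clustering was measured
to understate the SE by ~25% in simulation. The solver collapses the table
to risk sets at event times and runs Newton iterations on the collapsed
arrays; it reproduces `survival::coxph(..., ties="breslow")` in R to 1e-6 on
the coefficient. A monotone likelihood (all events on one arm in every
informative risk set) is flagged and reported with an infinite CI bound
rather than a spurious estimate. Optional within-stratum covariate
adjustment is available (`adjust_covariates`), off by default.

Incidence densities are episodes per 100 person-years (365.25 days/year,
weeks x 7 days), with a normal-approximation CI and the exact Poisson upper
bound 3.69/PT at zero events.

**Case-crossover.** For incident users three 6-week windows are formed: the
first treatment window starting at the first-dispensing week, the second
immediately after, and a pre-treatment referent window starting the week
after the latest baseline clinic visit whose window still ends before week
0 (this anchor rule keeps exposed time out of the referent). A window
counts at most one event and is eligible only when fully observed — inside
the study, fully enrolled, and the subject alive through its last week
(consistent with eligible-subject counts shrinking across windows). Among
subjects eligible for both windows of a contrast, the conditional-likelihood
odds ratio is the discordant ratio n10/n01 with a Wald CI; an empty
discordant cell is reported as degenerate with a one-sided exact
(Clopper-Pearson) bound and a warning. The closed form is verified against
`statsmodels` ConditionalLogit to 1e-6.

## Synthetic claims generator

The generator emulates a three-year state Medicaid fee-for-service extract
for subjects aged 50-92 with dementia: monthly enrollment with i.i.d. gap
months (p = 0.01/month), weekly outpatient/ED/inpatient/hospice/nursing-home
claims coded with a toy diagnosis grouper (licensed groupers are replaced by
a configurable code-group map), maintenance pharmacy fills for nine drug
classes plus statins, 30-day AChEI refills with a 12% per-refill stop
probability (median course ~35 weeks), and death days from vital records
regardless of enrollment.

Confounding by indication is generated by a latent gamma frailty (shape 2,
mean 1). Frailty raises the number of chronic conditions, hospice and
nursing-home use, clinic-visit and drug-use rates, and the death hazard
(frailty^power), and lowers statin use and the probability of starting
treatment. Deliberately, the frailty->treatment link flows almost entirely
through these *measured* manifestations, with only a small direct latent
coefficient: this is what makes the confounding reversible by covariate
methods, mirroring the observation that matching on recorded frailty markers
moved the death hazard ratio from crudely protective to null. A strong
latent-only link would be unremovable by any matching method and would test
nothing but an impossibility. Two scales were likewise chosen to limit
*differential survivor selection* (treated are indexed at treatment start,
later than the untreated index; with frailty-driven mortality the longer
pre-index survival otherwise depletes frail treated subjects in a way no
baseline covariate can record): treated start days are drawn from 190-420
(190-330 in the death scenario) and the death-scenario baseline weekly death
hazard is 0.0035 (~20-30 deaths per 100 person-years, the realistic range
for this population).

Weekly outcome hazards are Bernoulli on the 1-week grid:
`h = h0 * exp(b_age*(age-77)/10 + b_com*(conditions-1)) * frailty^power`,
multiplied by the exposure hazard ratio from the first dispensing through
course end (supply + 60-day tail — the same era definition the cohort
analysis uses, so "true HR" is well defined), and by an acute multiplier
during the first 6 exposed weeks in the acute scenario. Baseline weekly
hazards (gastrointestinal 0.005, psychological 0.009, respiratory 0.0055,
hematological 0.004, hepatic 0.0008, death 0.0045) put the untreated
incidence densities in the tens per 100 person-years, the scale reported
for this population. Latent events emit an index claim plus a truncated-
geometric burst of 0-3 follow-up claims at 7-21-day offsets, exercising the
episode-clustering rule; claims are emitted only while alive and enrolled,
so enrollment churn produces realistic under-ascertainment.

Presets: `null_all` (all exposure HRs 1), `gi_effect` (gastrointestinal HR
2), `frailty_death` (death HR 1 with strengthened frailty links and
measured-channel treatment selection; crude death HR ~0.65-0.70),
`acute_transient` (all HRs 1, outcome hazards tripled during the first 6
exposed weeks).

**What passing tests do and do not show.** The generator's treatment
assignment is logit-linear in recorded covariates with near-complete
baseline ascertainment of chronic conditions; real claims have coarser,
differentially recorded covariates, true unmeasured confounding, dose and
product switching, and coding drift. Recovery of the simulated hazard
ratios therefore validates the machinery (era construction, episode logic,
matching, estimators, their calibration) — not the claim that matching
removes confounding in any particular real data set.

## Numerical choices and edge cases

- Dates are integer day offsets from study day 0; weeks are floor-division
  7-day bins anchored per use; enrollment months are fixed 30-day bins
  unless explicit month indices are supplied.
- The propensity MLE falls back to a weak L2-penalized fit (C = 10) when
  separation is detected (e.g., zero treated hospice users, which occurs in
  a sizeable fraction of replicates at realistic prevalences); set
  `ridge_fallback = False` to make separation a hard error.
- Greedy matching processes treated subjects in descending logit score
  (hardest first) and breaks distance ties by the smaller untreated id, so
  results are bit-for-bit reproducible. The full pooled-covariance
  Mahalanobis metric should be used with small key sets; a `diagonal`
  metric option exists for larger key sets, where the inverse covariance
  otherwise concentrates weight on near-collinear contrasts.
- Newton iterations on the collapsed partial likelihood stop at 1e-10; a
  non-converged or |beta| > 8 fit is reported as monotone.
- Zero-variance covariates get balance p = 1 and SMD 0; zero-event
  incidence uses the exact Poisson bound; degenerate crossover cells use
  one-sided exact bounds.
- Replicate studies in the test suite use n = 4000 subjects (2000 for the
  null calibration, 3000 for the acute scenario) with 100-400 replicates,
  matching the populations the scenarios describe while keeping each
  replicate ~1 s.

## Known limitations

- 1:1 greedy matching only; optimal matching and IPW re-weighting are out
  of scope.
- Only primary diagnoses drive outcome and comorbidity detection (a config
  flag exists for all-position data, but the bundled schema carries a single
  code per claim).
- The RxRisk-style score is a distinct-drug-class count proxy, clearly
  labelled as such.
- The per-replicate max |SMD| over ~19 covariates at ~350 pairs is noise-
  dominated (sampling SD of one SMD ~ 0.05-0.08), so balance is summarized
  by the mean |SMD|; single-covariate excursions to ~0.1 are expected even
  under perfect matching.
- Episode clustering slightly attenuates strong effects (more events means
  more within-gap merging in the exposed arm); at HR 2 the attenuation is
  ~2-3% on the log scale.
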