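# Methods

This note documents the modelling choices behind `asthma-qa`: what each
stage computes, the assumptions it makes, how the synthetic claims world is
constructed, and where the design was genuinely open.

## Observation design

Claim years run July 1–June 30 and all windows are half-open
`[start, end)`.  For assessment period *t*, covariates are measured in the
premeasurement year A(t) and the binary exacerbation outcome in the
measurement year B(t) = A(t+1).  With `n_periods` assessment periods the
pipeline therefore consumes `n_periods + 1` years of claims.  The analysis
unit is the patient-period; the patient is the repeated-measures cluster,
with at most one observation per period.

## Cohort rules

"More than two outpatient clinic visits while using asthma medication" is
read strictly as ≥ 3 outpatient visit-days with a same-day prescription of
any catalog asthma drug, which matches the ongoing-visit indicator
("at least three"); the threshold is the `min_outpatient_visits` parameter
for sensitivity analyses.  Visit-days are counted per calendar day per
institution, so two same-day claims at one clinic count once.  The
alternative inclusion route is ≥ 1 hospitalization with same-day systemic
corticosteroids plus ≥ 1 medicated outpatient visit-day.  Age is computed
in whole years as `A_start.year − birth_year`.  Insurance eligibility is an
`uninsured_periods` column appended to the patients table (the claims
schema has no eligibility file; the synthetic generator emits it).  A
patient whose asthma diagnoses touch both a single primary clinic and a
single tertiary hospital in one period is assigned to the primary stream,
whose grades are the disclosed ones; diagnoses at two or more primary
clinics exclude the period entirely.

## Severity

Each prescription contributes its class rank to every covered day
(`[date, date + days_supplied)`), overlaps adding; relievers (SABA,
nebulizer) and systemic-steroid bursts carry rank 0.  Oral prednisolone is
a rank-4 controller only when `days_supplied ≥ 28` (the "long-term"
threshold is otherwise undefined in claims); shorter courses are treated as
exacerbation bursts.  Dose tier (low- vs high-dose ICS) is a property of
the catalog entry, not dose arithmetic.

Monthly trajectory values average the daily rank-sum over *all* days of the
calendar month, so unmedicated months score 0 — this is what makes the
mildest cluster sit near zero year-round.  February 29 is included; the
"365 daily ranks" of the total medication rank means all days of the
window.  By construction the total rank equals the days-in-month-weighted
sum of the monthly means exactly (the conservation identity tested at
1e-9).

K-means uses Euclidean distance on the raw 12 monthly features (shared
units, no standardization), k-means++ with 20 restarts and a fixed seed.
k = 4 is the default to mirror the published choice; because the overall
R² (between/total sum of squares) is non-decreasing in k, the optional
`"elbow"` mode selects the k whose marginal R² gain most dominates the next
gain.  Clusters are relabelled I–IV by ascending centroid annual mean.
Inputs are sorted by observation key before fitting so assignments are
order-invariant.

## Adherence, comorbidity, outcome

MPR = 100 × (distinct days covered by maintenance medication) / (follow-up
days), where the follow-up runs from the first maintenance prescription to
the last one plus its supplied days, clipped to window A (a config flag
ends it at the last start date instead).  Maintenance medication is
anything with a positive severity rank.  The ratio is capped at 100.
Levels honour the published bands literally: level 1 on [0, 20), level 2 on
[20, 80], level 3 on (80, 100]; level 0 means no maintenance prescription
at all (MPR undefined).

Comorbidity is a prefix match of the 3-character ICD-10 categories L20,
K21, J31, J30, J32, F32, F33, F40, F41, E66 on any primary or secondary
diagnosis in window A.

An exacerbation day carries a J45/J46 diagnosis at an outpatient visit or
at a primary clinic (emergency/inpatient events outside primary clinics are
excluded, since assessment results are disclosed only for primary clinics),
together with either a same-day systemic corticosteroid dispensing whose
daily dose exceeds 80 mg hydrocortisone-equivalent, or a same-day SABA
nebulizer treatment.  The threshold phrase "more than 80 mg of
hydrocortisone or any other corticosteroid of any potency" is ambiguous
between an equivalence reading and an any-dose reading; the
hydrocortisone-equivalent reading is the default and `mode="any_dose"`
exposes the literal alternative.  Equivalence factors (prednisolone 4,
methylprednisolone/triamcinolone 5, dexamethasone/betamethasone 25) are
editable catalog data.  Dose aggregation is per calendar day; multi-day
accumulation is not attempted.

## Grading

The surveyed population of a clinic is every patient aged ≥ 15 with an
asthma code there during window A — deliberately wider than the association
cohort, because conditioning the survey on the ≥ 3-visit inclusion rule
would make the ongoing-visit indicator degenerate at 100%.  Satisfactory
requires a rate strictly above the per-period median on all four mandatory
indicators and not falling in the worst decile on any penalty indicator.
"Lowest 10%" is interpreted as worst performance, i.e. the *highest* rates
of LABA/SABA/oral-steroid use without ICS; the cut is the empirical 90th
percentile with strict `>` (ties at the cutoff are not penalized, which
keeps the rule usable when many clinics tie at 0).  The strict-median rule
bounds the satisfactory fraction at 50% of graded clinics.

## GEE estimation

The estimating equations are solved by iteratively reweighted least
squares with the working correlation re-estimated by moment methods from
Pearson residuals at each step (lag-1 adjacent products for AR(1), all
within-cluster pairs for exchangeable), robust sandwich covariance, Wald
95% CIs at z = 1.959964, and QICu = −2·QL + 2p with the independence
binomial quasi-likelihood at unit scale.  The solver groups clusters by
their observed time pattern and runs each update as one einsum across all
clusters sharing a pattern, which makes fits over tens of thousands of
3-observation clusters take milliseconds; tests cross-check coefficients,
robust standard errors and QICu against `statsmodels.GEE`, and the
independence/one-observation-per-cluster case reproduces the logistic MLE
to 1e-6.  The AR(1) distance is the assessment-period index (annual,
consecutive).  The published model equations include an additive normal
error inside the logit, which has no standard GEE interpretation; it is
treated as notational, and the fitted model is ordinary marginal GEE.

Reference levels: Tertiary for grade, last period for period, severity I,
MPR level 3, comorbidity "yes", female sex, age 65+.  Age enters as the
five bands of the baseline table (a configurable choice; the source does
not state bands-vs-linear).  No multiplicity adjustment is applied.

The subgroup specification fits one model per severity group without the
severity covariate but with the total medication rank, and sums the
per-stratum QICu; the lower of (whole-group QICu, summed subgroup QICu)
selects the specification.  Strata with a single outcome level are skipped
with a warning.

## Synthetic claims world

The generator produces the four claims tables plus ground-truth frames.
Defaults are chosen to match the published study margins: archetype
weights (0.730, 0.098, 0.146, 0.026); tertiary-care shares by archetype
(0.074, 0.482, 0.357, 0.738); sex ratio 0.53 male; age-band weights from
the baseline table; comorbidity prevalence 0.67; intercept −2.05, which
puts the overall measurement-year exacerbation rate near the published
21.6%; severity log-odds (0, 0.68, 1.11, 1.70) matching the published
severity-specific exacerbation rates; period effects (0.34, 0.12, 0);
planted grade log-odds log 1.10 (Unsatisfactory) and log 1.25
(Satisfactory) against Tertiary, optionally severity-specific to create
effect heterogeneity.

Archetype trajectory curves reproduce the four published shapes: I flat
near 0.1; II winter-peaking at 2.1 in January; III flat near 2.4; IV high
with a January peak of 5.9, a February dip and a March rebound.  Monthly
targets are realized as same-month prescriptions whose rank and coverage
fraction multiply to the target; archetype-I targets are capped at 0.42 and
contained within the month, so a pure-archetype-I population provably keeps
every monthly mean below 0.5.  Emission for archetype I is thinned by a
clinic visit propensity and a patient engagement factor, which is what
creates ongoing-visit heterogeneity across clinics.

Clinics carry a latent quality class (good, 45% of clinics) that separates
their indicator propensities (PFT rates, visit intensity, ICS preference,
short-steroid habits).  The planted outcome model uses this latent class;
the pipeline's assigned grades track it closely but not perfectly, so
end-to-end grade effects are mildly attenuated relative to the planted
values — a realistic misclassification feature, not a bug.  The
Monte-Carlo recovery study therefore uses `simulate_analysis_rows`, the
generator's model-level view, which draws covariates from the configured
margins and outcomes from the identical planted model, isolating the
estimation stage.

Outcomes are drawn with exact marginal probabilities through a Gaussian
copula: a latent AR(1) standard-normal series (ρ = 0.4 by default) is
thresholded at the marginal probability, so planted log-odds are exactly
the population-averaged effects a GEE estimates.  An additive latent term
inside the logit would instead attenuate the marginal effects and make the
planted values unrecoverable by any marginal method.  Positive cases are
realized as an asthma-coded outpatient visit with a same-day >80 mg
hydrocortisone-equivalent dispensing (or a nebulizer treatment, 25%);
about 5% of non-cases receive deliberately non-qualifying decoys
(emergency-only bursts at tertiary hospitals, exactly-80 mg dispensings).

What the generator does **not** emulate: seasonal/air-pollution outcome
drivers, realistic national drug codes and formulary breadth, coding error
and claim-reversal noise, migration in and out of the insured population,
within-year adherence dynamics (the realized MPR distribution skews lower
than the published margins), and care-seeking feedback from disclosed
grades.  Passing tests therefore demonstrate correctness of the pipeline's
logic and estimators under the assumed data-generating structure, not
fidelity of any real-world effect size.

## Problem sizes used in tests

Unit and integration tests run on a shared 1,500-patient world (40 primary
clinics); the Monte-Carlo recovery study uses 200 replicates of 20,000
patients × 3 periods, fit with the full whole-group covariate set; the
acceptance script additionally runs one full claims pipeline at 20,000
patients.  These sizes give Monte-Carlo standard errors of roughly 0.002
on the recovered log-odds means while keeping the whole suite to a few
minutes on one CPU.

## Known limitations

* The grading stage assumes at least two graded primary clinics per period;
  medians are otherwise undefined (error).
* The AR(1) moment estimator uses adjacent-period products only; with long
  gaps between observations it falls back to the independence update for
  those clusters' missing lags.
* QICu comparisons assume the same observations enter both specifications;
  strata skipped for single-outcome degeneracy make the summed subgroup
  QICu incomparable (the skip is warned and recorded).
* `simulate_claims` memory grows linearly in patients × years; 100k+
  patients are feasible but the default sizes are chosen for test budgets.
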