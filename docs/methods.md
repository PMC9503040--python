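# Methods

`mwasplus` implements a three-stage screen for repurposing candidates
against an incident, syndromically coded outcome (the worked example
throughout is Alzheimer's disease and related dementias, ADRD) on
longitudinal EHR-style data, together with a synthetic-data generator that
makes every estimator testable by parameter recovery. This note records
the models, the parameters that matter, and the design choices made where
the design was genuinely open.

## Stage 1 — medication-wide association scan

For each subject in a matched case-control cohort and each drug, cumulative
exposure is the sum of dose-days (`days_supply x daily_dose`, dose
defaulting to 1 when unrecorded) over the fill days overlapping the closed
window `[index − 10 x 365 d, index]`; fills straddling either window edge
contribute only their in-window days. One year is 365 days everywhere, so
all windows are deterministic.

Users (cumulative dose > 0) are cut into deciles of the user-only dose
distribution pooled over cases and controls; a dose tied with a cut point
falls into the lower decile, and a drug whose users collapse into a single
decile is flagged degenerate. Each decile is contrasted with non-users in
an unadjusted 2x2 odds ratio. The scan is deliberately crude — it is a
hypothesis-generating sweep, not an adjusted analysis — so the odds ratios
are pooled over matching sets rather than conditioned on them. Confidence
intervals are Woolf (normal on the log odds ratio); when any cell of a 2x2
table is zero the Haldane–Anscombe +0.5 is added to all four cells of that
table and flagged. A drug is a candidate when the two-sided p-value of its
pooled treated-vs-non-treated odds ratio falls below the Bonferroni
per-drug alpha `family alpha / number of drugs` (0.05/10 = 0.005 for a
ten-drug family). Per-decile p-values are reported but not used for
selection. Drugs with fewer than 10 users, or with an empty non-user
reference cell, are skipped with a logged reason; the scan never aborts on
a single drug.

## Stage 2 — candidate dossier

Mechanistic review is a human step. The tool emits a structured dossier
template per drug, pre-filled with the scan numbers, with free-text fields
for mechanism, prior observational evidence and prior trial evidence. A
decision of `advance` or `reject` is refused while any expert field is
empty; the tool never advances a candidate on its own.

## Stage 3 — target-trial emulation

The trial stage emulates a randomized trial of drug-class initiation among
carriers of the indication (statins among hyperlipidemia carriers in the
worked example):

* **Sequential enrollment.** For each annual trial, initiators are
  carriers whose first-ever class fill falls in that year (strict new-user
  washout: no class fill at any earlier observed time) and who are
  outcome-free at that fill; time zero is the fill date. Non-initiator
  candidates are carriers with no class fill through year end and at least
  one non-class prescription that year; their time zero is a seeded-random
  choice among those fills, which mimics the arbitrary "visit" a control
  would have been randomized at. Each patient enrolls once, in the first
  eligible trial, and keeps that arm for good (intention-to-treat): a
  non-initiator who later starts the drug is not re-classified.
* **Covariates at baseline.** Demographics, indication year and disease
  duration, comorbidity flags (any matching code on/before index), and
  labs/vitals carried forward from the most recent measurement on/before
  index. Missing continuous covariates are imputed with the pre-match
  pooled median plus a missingness indicator. Covariate columns that are
  exact duplicates (the missingness flags of jointly sampled lab panels)
  are collapsed to one before model fitting, since they would make the
  design singular.
* **Propensity and matching.** Initiation propensity is a
  maximum-likelihood logistic regression; scores are clipped away from 0/1
  before taking logits. Matching is greedy 1:1 nearest-neighbor on the
  logit propensity without replacement, initiators visited in seeded
  random order, with a caliper of 0.2 pooled-SD of the logit score —
  standard practice where no algorithm is otherwise dictated. Unmatched
  initiators are counted, never silently dropped.
* **Balance.** Standardized differences in percent:
  `100·|m_a−m_b|/sqrt((s_a²+s_b²)/2)` for continuous covariates and the
  analogous `p(1−p)` form for binary ones, reported exactly and rounded to
  integer percent for table parity; two-sample p-values use Welch's t-test
  (continuous) and the chi-square test without continuity correction
  (binary). A zero pooled variance with unequal means reports infinity.
* **Hazard estimation.** Cox proportional hazards on the arm indicator
  (Efron ties), optionally with the propensity score as a covariate;
  exposure is fixed at baseline. Plain (non-pair-robust) variance is the
  primary report. Subgroup contrasts compare one member drug's initiators
  against all matched non-initiators with the propensity score as a
  covariate and no re-matching, matching how small subgroups are usually
  handled when re-matching would be underpowered. Kaplan–Meier curves and
  events per 1000 person-years round out the report.

## Cohort assembly (case-control stage)

Incident cases are indexed at their first outcome-coded diagnosis;
carriers of any exclusion code (dementias of known cause, schizophrenia,
bipolar disorder) on or before index are removed, not re-indexed. Controls
are outcome-free patients indexed at their last encounter. Both must be
≥65 at index, satisfy regular use (≥1 hospitalization or ≥2 outpatient
visits in the 365 days before index, index day excluded) and carry ≥10
years of observed history. Matching is greedy 1:5 on exact sex, race and
ethnicity with |age difference| ≤ 2 years (the tolerance is configurable;
the source design says "by age" without one), nearest age first, ties
broken by patient id, cases visited in seeded random order. Optimal
matching is out of scope. Code sets are configuration — named lists of
(code system, prefix) pairs matched by leading string within a system —
because curated ICD lists are site-specific.

## The synthetic cohort generator

Discrete-time simulation in calendar years (1999–2016 by default),
matching the yearly granularity of fills and visits and making the ground
truth computable in closed form. Each patient carries one latent
standard-normal confounder `c` standing in for unmeasured frailty and
clinical severity; observed covariates are generated with fixed links to
it so that propensity models have something to adjust on: `c` is partly
derived from age (weight 0.3), and sex, race, marital status, income,
rurality, four comorbidities and seven lab/vital kinds all shift with `c`.
Indication onset, drug prescribing (`logit⁻¹(logit(base) +
confounder_link·c)` per eligible year) and the outcome hazard
(`logit⁻¹(logit(h₀) + γ·c + Σ_d f_d(D_d))`) share the same `c`, producing
confounding by indication. Drug effects `f_d` are zero (`none`),
proportional to cumulative dose-days (`linear`), or a single log-hazard
step once cumulative dose passes a threshold (`threshold`); hazard in year
`t` uses the dose accrued before `t`. Because the yearly hazards are ~1%,
the logit and log scales agree to well under 0.1% and `exp(β)` is the
hazard ratio a Cox analysis should recover. Fills carry `days_supply ∈
{30, 90}` (3–4 fills per prescribed year), `daily_dose = 1`, so cumulative
dose equals days supplied. Death is an age-increasing yearly risk;
follow-up ends at the first of outcome, death, and administrative
censoring, and a fraction of outcome events (5%) is coded as
other-cause dementia to exercise the exclusion pathway, as is a small
prevalence (1%) of severe psychiatric codes. All randomness flows from one
seeded generator in fixed order, so outputs are bitwise reproducible.

Prescribing can optionally carry a per-patient log-odds intercept
(`prescribing_heterogeneity_sd`), making drug use persistent at the
patient level the way chronic therapies are — without it, yearly
independent prescribing makes every non-user a future user, which washes
out intention-to-treat contrasts under long follow-up; the demo scenario
uses this for its chronic drugs.

What the generator does *not* emulate: real coding practice (granular ICD
usage, rule-out codes), within-year timing effects, dose titration,
site effects, or informative visit processes.
Passing recovery tests therefore demonstrates estimator correctness under
the stated generating model, not robustness to every bias in real claims
data.

## Validation scenarios and problem sizes

* **Null scan calibration** — 20 null drugs, 200 replicates of 5,000
  patients; the family-wise candidate rate must stay within Monte-Carlo
  slack of the family alpha.
* **Class-effect recovery** — one protective class drug (`threshold` step,
  true HR 0.90) prescribed to indication carriers during a single
  enrollment year (2002). One year, with prescribing confined to it, makes
  the intention-to-treat contrast exactly the generating hazard step: with
  several trial years, earlier-enrolled non-initiators can initiate later,
  and that crossover dilutes the ITT estimate away from the configured
  truth by design rather than by estimator error. 115,000 patients yield
  roughly 50,000 enrollees; 20 replicates check both the point estimate
  and Wald-interval coverage. Confounding in this scenario is moderate and
  flows through covariates the propensity model observes — the regime in
  which matching can be expected to recover the truth; the latent part of
  `c` left after conditioning on the battery contributes residual bias
  well under one percent here.
* **Balance recovery** — the per-covariate claim "post-match ASD ≤
  pre-match ASD" is evaluated over a battery in which every covariate
  carries a genuine confounder link (age, marital status, rurality,
  indication timing, comorbidities, labs). For a covariate with no true
  arm imbalance the claim is statistically vacuous — its post-match value
  is sampling noise at the smaller matched size and exceeds its pre-match
  noise about half the time — so purely decorative demographics are
  exercised in the demo battery instead of the balance claim.
* **Demo pipeline** — ten drugs (one protective class drug, one strongly
  dose-responsive protective drug, one confounded null whose crude OR
  exceeds 1, seven plain nulls) at 20,000 patients, run end to end by
  `run-all` and by the acceptance script.

## Numerical choices and degenerate inputs

Dates are closed intervals; ties at decile cut points go down; the Haldane
correction applies per 2x2 table only when a cell is zero; propensity
scores are clipped to (1e-12, 1−1e-12); matching ties between equally
distant controls prefer the higher side deterministically; follow-up is
floored at one day so Cox never sees a zero duration; constant covariates
are a named error rather than a silent drop (exact duplicates are dropped
with a log note); a propensity coefficient beyond ±15 is treated as
separation and refused. Greedy matching uses path-compressed
nearest-available pointers over controls sorted by logit score, so
matching 25,000 initiators is linear-ish rather than quadratic.

## Known limitations

The scan's unadjusted odds ratios inherit confounding by indication by
design — that is what Stage 3 exists to resolve. The conditional (matched
set) logistic analysis, covariate-adjusted scan models, per-protocol and
marginal-structural analyses are out of scope. Cross-drug dose
standardization (defined daily doses) is not attempted; cumulative dose is
drug-native dose-days. The generator's discrete yearly clock understates
within-year exposure ordering; its effect on the recovered hazard ratios
is below the tolerances used in the tests.
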