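# mwasplus

Medication-wide association scanning and target-trial emulation for
drug-repurposing screens on longitudinal EHR data.

## The problem

Repurposing an approved drug for a disease without disease-modifying
treatment — the worked example throughout is incident Alzheimer's disease
and related dementias (ADRD) — calls for a screen that is hypothesis-free
at the front and rigorous at the back. `mwasplus` implements that screen
as a three-stage pipeline:

1. **Scan (hypothesis generation).** On a matched case-control cohort,
   cumulative exposure to each drug (dose-days over the ten years before
   index, like pack-years of smoking) is cut into deciles of the user
   distribution, and each decile is contrasted against non-users in an
   unadjusted odds ratio

   *OR*<sub>d</sub> = (a<sub>d</sub>·b₀)/(b<sub>d</sub>·a₀),

   with Woolf 95% intervals. A drug is a candidate when its pooled
   treated-vs-non-treated p-value clears the Bonferroni per-drug alpha
   α/m (0.05/10 = 0.005 for a ten-drug family). Output is a ranked
   candidate table and a drugs × deciles odds-ratio heatmap.
2. **Dossier (mechanistic filtering).** A structured template per
   candidate, pre-filled with the scan numbers, for the human review of
   mechanism and prior evidence. The tool never advances a candidate on
   its own.
3. **Trial emulation (hypothesis testing).** For a selected drug class and
   its indication: sequential annual trials with a strict new-user design,
   logistic propensity scores for initiation, greedy 1:1 matching on the
   logit score within a 0.2-SD caliper, standardized-difference balance
   tables, and intention-to-treat Cox regression

   h(t|arm) = h₀(t)·exp(β·arm [+ γ·PS]),

   with Kaplan–Meier curves, incidence per 1000 patient-years, and
   propensity-adjusted subgroup contrasts by member drug.

Because real administrative EHR sources of this kind are not publicly
shareable, the package bundles a seeded synthetic-cohort generator with
known ground truth — dose-response drug effects, confounding by
indication, censoring — so every estimator is validated by parameter
recovery (see `docs/methods.md`).

## Worked example

Run the bundled demonstration end to end (20,000 synthetic patients, ten
drugs of which one is a protective statin-like class drug, one is strongly
dose-responsive protective, and one is a confounded null):

```bash
mwasplus run-all --n-patients 20000 --seed 1 --out demo/
```

which prints

```
report written to demo/report.md
  unadjusted: HR 0.828 (0.640-1.073), p=0.1534
  ps_adjusted: HR 0.829 (0.640-1.073), p=0.1538
```

`demo/candidates.csv` ranks the scanned drugs by their pooled odds ratio;
in this run the dose-responsive protective drug tops the table with
overall OR 0.52 and is the only Bonferroni-significant candidate
(p = 4e-7 < 0.005), the confounded null shows the largest spurious excess
(OR 1.25), and the statin-like class drug (true hazard ratio 0.90) sits
at OR 0.74. The trial stage then matches 1,893 initiator/non-initiator
pairs; both hazard-ratio intervals above cover the simulated truth of
0.90. `demo/report.md` embeds the heatmap, the pre/post-match balance
table (worst post-match standardized difference 4.5%), the hazard-ratio
table and the Kaplan–Meier figure. Stage-2 dossiers come from
`mwasplus dossier --scan-dir demo --drug <drug_id> --out dossier.yaml`.

Each stage is also exposed separately (`simulate`, `assemble-cohort`,
`mwas-scan`, `target-trial`), exchanging data as five flat CSVs
(demographics, encounters, diagnoses, fills, measurements) with ISO dates;
diagnosis code sets are YAML configuration matched by (code system,
prefix).

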