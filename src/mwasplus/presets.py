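"""Preset simulation scenarios used for estimator validation and the demo.

Each factory fixes one set of study conditions:

``null_scan_config``
    A medication-wide scan under the global null: every drug has zero
    effect and no confounder link, so any candidate flagged at the
    Bonferroni threshold is a family-wise false positive.

``confounded_null_config``
    One null drug whose prescription is driven by the latent confounder
    that also raises the outcome hazard — classic confounding by
    indication; its crude odds ratio should exceed 1.

``class_effect_config``
    A protective drug class (default true hazard ratio 0.90, a one-step
    effect once ever exposed) prescribed to carriers of an indication
    during the single trial-enrollment year only, so non-initiators never
    cross over and the intention-to-treat contrast equals the generating
    hazard step.  Confounding is moderate and operates through covariates
    the propensity model observes (labs, comorbidity flags), which is the
    regime in which propensity matching can be expected to recover the
    truth.

``demo_config``
    A ten-drug scan-plus-trial demonstration with one protective class
    drug, one linearly dose-responsive protective drug, one confounded
    null drug and seven plain nulls.
"""

from __future__ import annotations

import numpy as np

from mwasplus.synthetic import DrugTruth, SimulationConfig


def null_scan_config(n_patients: int, seed: int, n_drugs: int = 20) -> SimulationConfig:
    drugs = tuple(
        DrugTruth(drug_id=f"drug_{i:02d}", prescription_propensity_base=0.10)
        for i in range(n_drugs)
    )
    return SimulationConfig(
        n_patients=n_patients,
        baseline_outcome_hazard=0.01,
        confounder_effect_on_outcome=0.3,
        drug_truths=drugs,
        seed=seed,
    )


def confounded_null_config(n_patients: int, seed: int,
                           confounder_link: float = 0.8) -> SimulationConfig:
    drugs = (
        DrugTruth(drug_id="confounded_null", prescription_propensity_base=0.10,
                  confounder_link=confounder_link),
        DrugTruth(drug_id="clean_null", prescription_propensity_base=0.10),
    )
    return SimulationConfig(
        n_patients=n_patients,
        baseline_outcome_hazard=0.01,
        confounder_effect_on_outcome=0.5,
        drug_truths=drugs,
        seed=seed,
    )


#: Trial-enrollment years for the class-effect recovery scenario; one year,
#: with prescribing confined to it, keeps the ITT contrast crossover-free.
CLASS_TRIAL_YEARS = (2002,)

#: Cohort size yielding roughly 50,000 trial enrollees under
#: :func:`class_effect_config`.
CLASS_EFFECT_N_PATIENTS = 115_000

#: Covariate battery for balance-recovery validation: every member carries a
#: genuine generating-model link to the latent confounder, so its pre-match
#: imbalance is real signal that matching must remove.  Covariates without
#: such links (rare demographics, lab-missingness flags) have nothing to
#: balance and are exercised in the demo battery instead.
BALANCE_COVARIATES = (
    "age", "unmarried", "rural", "indication_year", "disease_duration_years",
    "hypertension", "diabetes", "ischemic_heart_disease", "depression",
    "bmi", "sbp", "dbp", "glucose", "total_chol", "ldl", "triglycerides",
)


def class_effect_config(n_patients: int, seed: int,
                        true_hr: float = 0.90) -> SimulationConfig:
    """Protective drug class for target-trial parameter recovery."""
    statin = DrugTruth(
        drug_id="statin_a",
        drug_class="statin",
        effect_shape="threshold" if true_hr != 1.0 else "none",
        log_hazard_effect_per_unit=float(np.log(true_hr)),
        threshold_dose=0.0,
        prescription_propensity_base=0.30,
        confounder_link=0.2,
        requires_indication=True,
        prescribing_start_year=CLASS_TRIAL_YEARS[0],
        prescribing_end_year=CLASS_TRIAL_YEARS[-1],
    )
    anchors = tuple(
        DrugTruth(drug_id=f"anchor_{i}", prescription_propensity_base=0.25)
        for i in range(3)
    )
    return SimulationConfig(
        n_patients=n_patients,
        baseline_outcome_hazard=0.01,
        confounder_effect_on_outcome=0.2,
        indication_onset_rate=0.30,
        indication_confounder_link=0.3,
        drug_truths=(statin,) + anchors,
        seed=seed,
    )


DEMO_TRIAL_YEARS = (2002, 2003, 2004, 2005)


def demo_config(n_patients: int, seed: int) -> SimulationConfig:
    """Ten-drug demonstration scenario for the end-to-end pipeline."""
    drugs = [
        # prescribed throughout the study: confining a drug to an era would
        # confound the scan through calendar coverage of exposure windows,
        # and the demo trial accepts the resulting ITT crossover dilution
        DrugTruth(
            drug_id="statin_a", drug_class="statin",
            effect_shape="threshold",
            log_hazard_effect_per_unit=float(np.log(0.90)),
            prescription_propensity_base=0.30,
            confounder_link=0.2, requires_indication=True,
            prescribing_heterogeneity_sd=2.0,
        ),
        DrugTruth(
            drug_id="dose_response_protective",
            effect_shape="linear",
            log_hazard_effect_per_unit=-1.2e-3,  # ~HR 0.70 per 300 dose-days
            prescription_propensity_base=0.15,
            prescribing_heterogeneity_sd=1.5,
        ),
        DrugTruth(
            drug_id="confounded_null",
            prescription_propensity_base=0.10,
            confounder_link=0.6,
        ),
    ]
    drugs += [
        DrugTruth(drug_id=f"null_{i}", prescription_propensity_base=0.10)
        for i in range(7)
    ]
    return SimulationConfig(
        n_patients=n_patients,
        baseline_outcome_hazard=0.01,
        confounder_effect_on_outcome=0.3,
        indication_onset_rate=0.25,
        indication_confounder_link=0.3,
        drug_truths=tuple(drugs),
        seed=seed,
    )
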