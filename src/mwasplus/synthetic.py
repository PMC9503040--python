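"""Seeded synthetic longitudinal EHR cohorts with known ground-truth drug effects.

The generator emulates the structure of a long-history administrative EHR
cohort — multi-year patient histories, outpatient/inpatient visit processes,
pharmacy fills with days' supply, periodic lab/vital panels, an incident
dementia-like outcome — together with the two features the screening
pipeline must survive: a dose-response drug effect on the outcome hazard and
confounding by indication.

Model
-----
Time is discrete in calendar years.  Each patient carries one latent
standard-normal confounder ``c`` that raises comorbidity prevalence,
shifts lab/vital values, makes the drug indication more likely, raises
prescription propensity (confounding by indication) and raises the outcome
hazard.  In year ``t`` the outcome probability is

    logit h_t = logit(h0) + gamma * c + sum_d f_d(D_d(t))

where ``D_d(t)`` is cumulative dose-days of drug ``d`` accrued before year
``t`` and ``f_d`` is the drug's effect shape: ``none`` (0), ``linear``
(``beta * D``), or ``threshold`` (a single log-hazard step ``beta`` once
``D`` exceeds a threshold).  After the event a diagnosis is emitted and
follow-up ends; death and administrative censoring apply otherwise.
Because the yearly hazards are small, ``exp(beta)`` is also the hazard
ratio a proportional-hazards analysis should recover (to first order in
``h0``).

Everything is drawn from one :func:`numpy.random.default_rng` stream in a
fixed order, so output tables are bitwise identical for identical
``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from mwasplus.data_model import DAYS_PER_YEAR, EHRDataset

#: Administrative switch date from ICD-9 to ICD-10 coding.
ICD10_START = np.datetime64("2015-10-01")

_OUTCOME_CODES = ("331.0", "G30.9")
_OTHER_DEMENTIA_CODES = ("290.40", "F01.50")
_PSYCH_CODES = ("295.90", "F20.9")
_INDICATION_CODES = ("272.4", "E78.5")

# name, icd9, icd10, baseline logit, confounder link (log-odds per unit c)
_COMORBIDITY_MODELS = (
    ("hypertension", "401.9", "I10", 0.6, 0.6),
    ("diabetes", "250.00", "E11.9", -1.1, 0.6),
    ("ischemic_heart_disease", "414.01", "I25.10", -1.4, 0.6),
    ("depression", "311", "F32.9", -1.7, 0.6),
)

# fixed links from observed demographics to the latent confounder
# (log-odds per unit c, or the stated transform); the frailty gradient the
# propensity model gets to adjust on
_AGE_CONFOUNDER_WEIGHT = 0.3      # share of c derived from standardized age
_FEMALE_LINK = -0.3
_AFRICAN_AMERICAN_LINK = 0.2
_UNMARRIED_LINK = 0.6
_RURAL_LINK = 0.6
_INCOME_SHIFT = 0.15              # uniform-score shift toward lower quartiles

# kind -> (mean, confounder slope, residual SD); units: kg/m2, mmHg, mg/dL
_MEASUREMENT_MODELS = {
    "bmi": (28.0, 1.5, 3.0),
    "sbp": (135.0, 6.0, 12.0),
    "dbp": (77.0, 3.0, 8.0),
    "glucose": (105.0, 8.0, 15.0),
    "total_chol": (205.0, 12.0, 25.0),
    "ldl": (128.0, 12.0, 7.0),
    "triglycerides": (175.0, 25.0, 40.0),
}

EFFECT_SHAPES = ("none", "threshold", "linear")


@dataclass(frozen=True)
class DrugTruth:
    """Ground-truth generating model for one drug.

    ``log_hazard_effect_per_unit`` is the log-hazard increment per dose-day
    for ``effect_shape="linear"``, the size of the single log-hazard step
    applied once cumulative dose exceeds ``threshold_dose`` for
    ``"threshold"``, and must be 0 for ``"none"``.
    """

    drug_id: str
    effect_shape: str = "none"
    log_hazard_effect_per_unit: float = 0.0
    threshold_dose: float = 0.0
    prescription_propensity_base: float = 0.10
    confounder_link: float = 0.0
    #: SD of a per-patient log-odds intercept for prescribing; nonzero values
    #: make drug use persistent at the patient level (never-users stay
    #: never-users), as with chronic-therapy drugs
    prescribing_heterogeneity_sd: float = 0.0
    drug_class: str | None = None
    requires_indication: bool = False
    prescribing_start_year: int | None = None
    prescribing_end_year: int | None = None

    def validate(self) -> None:
        if self.effect_shape not in EFFECT_SHAPES:
            raise ValueError(f"{self.drug_id}: unknown effect_shape {self.effect_shape!r}")
        if (self.effect_shape == "none") != (self.log_hazard_effect_per_unit == 0.0):
            raise ValueError(
                f"{self.drug_id}: effect_shape 'none' if and only if effect is 0")
        if not (0.0 < self.prescription_propensity_base < 1.0):
            raise ValueError(f"{self.drug_id}: prescription propensity must be in (0,1)")
        if self.prescribing_heterogeneity_sd < 0:
            raise ValueError(f"{self.drug_id}: prescribing_heterogeneity_sd must be >= 0")
        if self.threshold_dose < 0:
            raise ValueError(f"{self.drug_id}: threshold_dose must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one synthetic cohort; see module docstring for the model."""

    n_patients: int
    study_start: pd.Timestamp = pd.Timestamp("1999-01-01")
    study_end: pd.Timestamp = pd.Timestamp("2016-12-31")
    baseline_outcome_hazard: float = 0.01
    confounder_effect_on_outcome: float = 0.3
    visit_rate: float = 3.0
    hospitalization_rate: float = 0.15
    drug_truths: tuple[DrugTruth, ...] = ()
    indication_onset_rate: float = 0.0
    indication_confounder_link: float = 0.0
    measurement_panel_rate: float = 0.35
    psych_exclusion_prevalence: float = 0.01
    other_dementia_fraction: float = 0.05
    death_rate_base: float = 0.005
    death_rate_log_slope: float = 0.09
    min_age_at_start: float = 55.0
    max_age_at_start: float = 90.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not pd.Timestamp(self.study_start) < pd.Timestamp(self.study_end):
            raise ValueError("study_start must precede study_end")
        if not (0.0 < self.baseline_outcome_hazard < 1.0):
            raise ValueError("baseline_outcome_hazard must be in (0,1)")
        for name in ("visit_rate", "hospitalization_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("measurement_panel_rate", "psych_exclusion_prevalence",
                     "other_dementia_fraction", "death_rate_base"):
            value = getattr(self, name)
            if not (0.0 <= value < 1.0):
                raise ValueError(f"{name} must be in [0,1)")
        if not (0.0 <= self.indication_onset_rate < 1.0):
            raise ValueError("indication_onset_rate must be in [0,1)")
        if not self.min_age_at_start < self.max_age_at_start:
            raise ValueError("min_age_at_start must be below max_age_at_start")
        seen: set[str] = set()
        for truth in self.drug_truths:
            truth.validate()
            if truth.drug_id in seen:
                raise ValueError(f"duplicate drug_id {truth.drug_id!r}")
            seen.add(truth.drug_id)
            if truth.requires_indication and self.indication_onset_rate == 0.0:
                raise ValueError(
                    f"{truth.drug_id} requires an indication but indication_onset_rate is 0")

    def drug(self, drug_id: str) -> DrugTruth:
        for truth in self.drug_truths:
            if truth.drug_id == drug_id:
                return truth
        raise KeyError(f"unknown drug {drug_id!r}")


@dataclass
class TruthTable:
    """Ground truth accompanying a generated dataset.

    ``drugs`` holds one row per drug with its generating parameters and the
    hazard ratio for a reference contrast (one step for threshold effects,
    365 dose-days for linear ones).  ``patients`` holds the latent
    confounder and the true event/censoring dates.
    """

    drugs: pd.DataFrame
    patients: pd.DataFrame


def ground_truth_hr(config: SimulationConfig, drug_id: str, dose_contrast: float) -> float:
    """True outcome hazard ratio for a cumulative-dose contrast vs zero dose."""
    truth = config.drug(drug_id)
    if truth.effect_shape == "none":
        return 1.0
    if truth.effect_shape == "linear":
        return float(np.exp(truth.log_hazard_effect_per_unit * dose_contrast))
    if dose_contrast > truth.threshold_dose:
        return float(np.exp(truth.log_hazard_effect_per_unit))
    return 1.0


def _icd_codes(dates: np.ndarray, icd9: str, icd10: str) -> tuple[np.ndarray, np.ndarray]:
    is10 = (dates >= ICD10_START).astype(np.intp)
    codes = np.array([icd9, icd10], dtype=object)[is10]
    systems = np.array(["ICD9", "ICD10"], dtype=object)[is10]
    return codes, systems


def generate_population(config: SimulationConfig) -> tuple[EHRDataset, TruthTable]:
    """Simulate a cohort; deterministic given ``config`` (including its seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    start = np.datetime64(pd.Timestamp(config.study_start), "D")
    end = np.datetime64(pd.Timestamp(config.study_end), "D")
    start_year = pd.Timestamp(config.study_start).year
    end_year = pd.Timestamp(config.study_end).year

    # --- baseline draws (fixed order) -------------------------------------
    age0 = rng.uniform(config.min_age_at_start, config.max_age_at_start, n)
    age_sd = age0.std()
    age_z = (age0 - age0.mean()) / age_sd if age_sd > 0 else np.zeros(n)
    w = _AGE_CONFOUNDER_WEIGHT
    confounder = w * age_z + np.sqrt(1.0 - w * w) * rng.standard_normal(n)
    sex = np.where(rng.random(n) < expit(logit(0.05) + _FEMALE_LINK * confounder),
                   "female", "male")
    aa = rng.random(n) < expit(logit(0.10) + _AFRICAN_AMERICAN_LINK * confounder)
    race = np.where(aa, "african_american",
                    np.where(rng.random(n) < 0.055, "other", "white"))
    ethnicity = np.where(rng.random(n) < 0.05, "hispanic", "non_hispanic")
    marital = np.where(rng.random(n) < expit(logit(0.40) + _UNMARRIED_LINK * confounder),
                       "unmarried", "married")
    income_score = rng.random(n) - _INCOME_SHIFT * confounder
    income = np.array(["q1", "q2", "q3", "q4", "unknown"])[
        np.digitize(income_score, [0.24, 0.48, 0.72, 0.96])]
    rural = rng.random(n) < expit(logit(0.20) + _RURAL_LINK * confounder)
    birth_date = start - np.round(age0 * DAYS_PER_YEAR).astype(np.int64)

    comorbid: dict[str, np.ndarray] = {}
    comorbid_day: dict[str, np.ndarray] = {}
    for name, _, _, base_logit, link in _COMORBIDITY_MODELS:
        comorbid[name] = rng.random(n) < expit(base_logit + link * confounder)
        comorbid_day[name] = rng.integers(0, 3 * DAYS_PER_YEAR, n)
    psych = rng.random(n) < config.psych_exclusion_prevalence
    psych_day = rng.integers(0, 5 * DAYS_PER_YEAR, n)
    other_dementia = rng.random(n) < config.other_dementia_fraction
    rx_intercept = {
        t.drug_id: (rng.normal(0.0, t.prescribing_heterogeneity_sd, n)
                    if t.prescribing_heterogeneity_sd > 0 else 0.0)
        for t in config.drug_truths
    }

    # --- state ------------------------------------------------------------
    alive = np.ones(n, dtype=bool)
    evented = np.zeros(n, dtype=bool)
    event_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    death_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    indication_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    has_indication = np.zeros(n, dtype=bool)
    cumdose = {t.drug_id: np.zeros(n) for t in config.drug_truths}

    # events are buffered as integer codes; strings materialize once at the end
    enc_patient: list[np.ndarray] = []
    enc_date: list[np.ndarray] = []
    enc_setting: list[np.ndarray] = []          # 0=inpatient, 1=outpatient
    fill_patient: list[np.ndarray] = []
    fill_drug: list[np.ndarray] = []            # index into config.drug_truths
    fill_date_l: list[np.ndarray] = []
    fill_supply: list[np.ndarray] = []
    meas_patient: list[np.ndarray] = []
    meas_date: list[np.ndarray] = []
    meas_kind: list[np.ndarray] = []            # index into _MEASUREMENT_MODELS
    meas_value: list[np.ndarray] = []

    base_logit_hazard = logit(config.baseline_outcome_hazard)
    for year in range(start_year, end_year + 1):
        year_start = max(np.datetime64(f"{year}-01-01"), start)
        year_end = min(np.datetime64(f"{year}-12-31"), end)
        days_in_year = int((year_end - year_start).astype(int)) + 1
        at_risk = alive & ~evented

        # indication onset
        if config.indication_onset_rate > 0:
            p_onset = expit(logit(config.indication_onset_rate)
                            + config.indication_confounder_link * confounder)
            onset = at_risk & ~has_indication & (rng.random(n) < p_onset)
            onset_day = rng.integers(0, days_in_year, n)
            indication_date[onset] = year_start + onset_day[onset]
            has_indication |= onset

        # outcome hazard uses cumulative dose accrued before this year
        lp = base_logit_hazard + config.confounder_effect_on_outcome * confounder
        for truth in config.drug_truths:
            dose = cumdose[truth.drug_id]
            if truth.effect_shape == "linear":
                lp = lp + truth.log_hazard_effect_per_unit * dose
            elif truth.effect_shape == "threshold":
                lp = lp + truth.log_hazard_effect_per_unit * (dose > truth.threshold_dose)
        event = at_risk & (rng.random(n) < expit(lp))
        event_day = rng.integers(0, days_in_year, n)
        event_date[event] = year_start + event_day[event]
        evented |= event

        # death (only while outcome-free; follow-up ends at the event anyway)
        age_now = age0 + (year - start_year)
        p_death = np.clip(config.death_rate_base
                          * np.exp(config.death_rate_log_slope * (age_now - 60.0)), 0, 0.8)
        died = at_risk & ~event & (rng.random(n) < p_death)
        death_day = rng.integers(0, days_in_year, n)
        death_date[died] = year_start + death_day[died]
        alive &= ~died

        # prescribing; cumulative dose is credited after the hazard draw
        for drug_idx, truth in enumerate(config.drug_truths):
            if truth.prescribing_start_year is not None and year < truth.prescribing_start_year:
                continue
            if truth.prescribing_end_year is not None and year > truth.prescribing_end_year:
                continue
            eligible = at_risk
            if truth.requires_indication:
                eligible = eligible & has_indication
            p_rx = expit(logit(truth.prescription_propensity_base)
                         + truth.confounder_link * confounder
                         + rx_intercept[truth.drug_id])
            prescribed = eligible & (rng.random(n) < p_rx)
            idx = np.flatnonzero(prescribed)
            if idx.size:
                n_fills = rng.integers(3, 5, idx.size)
                rep = np.repeat(idx, n_fills)
                days = rng.integers(0, days_in_year, rep.size)
                supply = rng.choice(np.array([30, 90]), size=rep.size, p=[0.3, 0.7])
                fill_patient.append(rep)
                fill_date_l.append(year_start + days)
                fill_supply.append(supply)
                fill_drug.append(np.full(rep.size, drug_idx, dtype=np.int16))
                np.add.at(cumdose[truth.drug_id], rep, supply.astype(float))

        # visits
        for rate, setting_code in ((config.visit_rate, 1),
                                   (config.hospitalization_rate, 0)):
            counts = rng.poisson(rate, n)
            counts[~at_risk] = 0
            rep = np.repeat(np.arange(n), counts)
            if rep.size:
                days = rng.integers(0, days_in_year, rep.size)
                enc_patient.append(rep)
                enc_date.append(year_start + days)
                enc_setting.append(np.full(rep.size, setting_code, dtype=np.int8))

        # lab/vital panels
        panel = at_risk & (rng.random(n) < config.measurement_panel_rate)
        panel_day = rng.integers(0, days_in_year, n)
        idx = np.flatnonzero(panel)
        if idx.size:
            dates = year_start + panel_day[idx]
            for kind_idx, (mean, slope, sd) in enumerate(_MEASUREMENT_MODELS.values()):
                values = mean + slope * confounder[idx] + rng.normal(0.0, sd, idx.size)
                meas_patient.append(idx)
                meas_date.append(dates)
                meas_kind.append(np.full(idx.size, kind_idx, dtype=np.int8))
                meas_value.append(np.clip(values, 1.0, None))

    # --- follow-up end and table assembly ---------------------------------
    end_follow = np.full(n, end, dtype="datetime64[D]")
    has_event = ~np.isnat(event_date)
    end_follow[has_event] = event_date[has_event]
    dead_first = ~np.isnat(death_date) & (np.isnat(event_date) | (death_date < event_date))
    end_follow[dead_first] = death_date[dead_first]

    def _clip(pidx: np.ndarray, dates: np.ndarray, *cols: np.ndarray):
        keep = (dates >= start) & (dates <= end_follow[pidx])
        return (pidx[keep], dates[keep]) + tuple(c[keep] for c in cols)

    # each table is assembled and its buffers freed before the next one, to
    # keep peak memory near a single table's footprint
    # object-dtype lookups let every row share one Python string object
    patient_ids = np.array([f"P{i:07d}" for i in range(n)], dtype=object)
    enc_p = np.concatenate(enc_patient) if enc_patient else np.empty(0, dtype=np.int64)
    enc_d = np.concatenate(enc_date) if enc_date else np.empty(0, dtype="datetime64[D]")
    enc_s = np.concatenate(enc_setting) if enc_setting else np.empty(0, dtype=np.int8)
    del enc_patient, enc_date, enc_setting
    enc_p, enc_d, enc_s = _clip(enc_p, enc_d, enc_s)
    # a visit accompanies the incident diagnosis, so cases end observation there
    ev_idx = np.flatnonzero(has_event)
    enc_p = np.concatenate([enc_p, ev_idx])
    enc_d = np.concatenate([enc_d, event_date[ev_idx]])
    enc_s = np.concatenate([enc_s, np.full(ev_idx.size, 1, dtype=np.int8)])
    setting_lookup = np.array(["inpatient", "outpatient"], dtype=object)  # code order == lex order
    order = np.lexsort((enc_s, enc_d, enc_p))
    encounters = pd.DataFrame({
        "patient_id": patient_ids[enc_p[order]],
        "date": pd.to_datetime(enc_d[order]),
        "setting": setting_lookup[enc_s[order]],
    })
    del enc_p, enc_d, enc_s, order

    dx_p: list[np.ndarray] = []
    dx_d: list[np.ndarray] = []
    dx_code: list[np.ndarray] = []
    dx_sys: list[np.ndarray] = []

    def _emit_dx(idx: np.ndarray, dates: np.ndarray, icd9: str, icd10: str) -> None:
        keep = (dates >= start) & (dates <= end_follow[idx])
        idx, dates = idx[keep], dates[keep]
        if idx.size == 0:
            return
        codes, systems = _icd_codes(dates, icd9, icd10)
        dx_p.append(idx)
        dx_d.append(dates)
        dx_code.append(codes)
        dx_sys.append(systems)

    outcome_like = ev_idx
    coded_other = other_dementia[outcome_like]
    _emit_dx(outcome_like[~coded_other], event_date[outcome_like[~coded_other]],
             *_OUTCOME_CODES)
    _emit_dx(outcome_like[coded_other], event_date[outcome_like[coded_other]],
             *_OTHER_DEMENTIA_CODES)
    _emit_dx(np.flatnonzero(psych), start + psych_day[psych], *_PSYCH_CODES)
    ind_idx = np.flatnonzero(~np.isnat(indication_date))
    _emit_dx(ind_idx, indication_date[ind_idx], *_INDICATION_CODES)
    for name, icd9, icd10, _, _ in _COMORBIDITY_MODELS:
        idx = np.flatnonzero(comorbid[name])
        _emit_dx(idx, start + comorbid_day[name][idx], icd9, icd10)

    dxp = np.concatenate(dx_p) if dx_p else np.empty(0, dtype=np.int64)
    dxd = np.concatenate(dx_d) if dx_d else np.empty(0, dtype="datetime64[D]")
    dxc = np.concatenate(dx_code) if dx_code else np.empty(0, dtype=object)
    dxs = np.concatenate(dx_sys) if dx_sys else np.empty(0, dtype=object)
    order = np.lexsort((dxc, dxs, dxd, dxp))
    diagnoses = pd.DataFrame({
        "patient_id": patient_ids[dxp[order]],
        "date": pd.to_datetime(dxd[order]),
        "code": dxc[order],
        "code_system": dxs[order],
    })
    del dx_p, dx_d, dx_code, dx_sys, dxp, dxd, dxc, dxs, order

    fl_p = np.concatenate(fill_patient) if fill_patient else np.empty(0, dtype=np.int64)
    fl_d = np.concatenate(fill_date_l) if fill_date_l else np.empty(0, dtype="datetime64[D]")
    fl_s = np.concatenate(fill_supply) if fill_supply else np.empty(0, dtype=np.int64)
    fl_k = np.concatenate(fill_drug) if fill_drug else np.empty(0, dtype=np.int16)
    del fill_patient, fill_date_l, fill_supply, fill_drug
    fl_p, fl_d, fl_s, fl_k = _clip(fl_p, fl_d, fl_s, fl_k)
    drug_names = np.array([t.drug_id for t in config.drug_truths], dtype=object) \
        if config.drug_truths else np.empty(0, dtype=object)
    class_lookup = np.array([t.drug_class for t in config.drug_truths], dtype=object) \
        if config.drug_truths else np.empty(0, dtype=object)
    drug_lex_rank = (np.argsort(np.argsort(drug_names.astype(str)))
                     if drug_names.size else np.empty(0, dtype=np.int64))
    order = np.lexsort((fl_s, drug_lex_rank[fl_k] if fl_k.size else fl_k, fl_d, fl_p))
    fl_k = fl_k[order]
    fills = pd.DataFrame({
        "patient_id": patient_ids[fl_p[order]],
        "drug_id": drug_names[fl_k] if fl_k.size else np.empty(0, dtype=object),
        "drug_class": class_lookup[fl_k] if fl_k.size else np.empty(0, dtype=object),
        "fill_date": pd.to_datetime(fl_d[order]),
        "days_supply": fl_s[order].astype(np.int64),
        "daily_dose": np.ones(fl_p.size),
    })
    del fl_p, fl_d, fl_s, fl_k, order

    ms_p = np.concatenate(meas_patient) if meas_patient else np.empty(0, dtype=np.int64)
    ms_d = np.concatenate(meas_date) if meas_date else np.empty(0, dtype="datetime64[D]")
    ms_k = np.concatenate(meas_kind) if meas_kind else np.empty(0, dtype=np.int8)
    ms_v = np.concatenate(meas_value) if meas_value else np.empty(0)
    del meas_patient, meas_date, meas_kind, meas_value
    ms_p, ms_d, ms_k, ms_v = _clip(ms_p, ms_d, ms_k, ms_v)
    kind_names = np.array(list(_MEASUREMENT_MODELS), dtype=object)
    kind_lex_rank = np.argsort(np.argsort(kind_names.astype(str)))
    ms_v = np.round(ms_v, 4)
    order = np.lexsort((ms_v, kind_lex_rank[ms_k] if ms_k.size else ms_k, ms_d, ms_p))
    measurements = pd.DataFrame({
        "patient_id": patient_ids[ms_p[order]],
        "date": pd.to_datetime(ms_d[order]),
        "kind": kind_names[ms_k[order]] if ms_k.size else np.empty(0, dtype=object),
        "value": ms_v[order],
    })
    del ms_p, ms_d, ms_k, ms_v, order

    demographics = pd.DataFrame({
        "patient_id": patient_ids,
        "birth_date": pd.to_datetime(birth_date),
        "sex": sex, "race": race, "ethnicity": ethnicity,
        "marital_status": marital, "income_quartile": income,
        "rural_residence": rural,
        "death_date": pd.to_datetime(death_date),
    })
    dataset = EHRDataset(
        demographics=demographics, encounters=encounters, diagnoses=diagnoses,
        fills=fills, measurements=measurements,
        study_start=pd.Timestamp(config.study_start),
        study_end=pd.Timestamp(config.study_end),
    )

    drugs_truth = pd.DataFrame([
        {
            "drug_id": t.drug_id,
            "drug_class": t.drug_class,
            "effect_shape": t.effect_shape,
            "log_hazard_effect_per_unit": t.log_hazard_effect_per_unit,
            "threshold_dose": t.threshold_dose,
            "true_hr_reference_contrast": ground_truth_hr(
                config, t.drug_id,
                t.threshold_dose + 1.0 if t.effect_shape == "threshold" else 365.0),
        }
        for t in config.drug_truths
    ])
    patients_truth = pd.DataFrame({
        "patient_id": patient_ids,
        "confounder": confounder,
        "event_date": pd.to_datetime(event_date),
        "coded_as_other_dementia": has_event & other_dementia,
        "death_date": pd.to_datetime(death_date),
        "indication_date": pd.to_datetime(indication_date),
        "end_of_followup": pd.to_datetime(end_follow),
    })
    return dataset, TruthTable(drugs=drugs_truth, patients=patients_truth)
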