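"""Cohort construction: incident cases, eligibility, and case-control matching.

Cases are patients whose first outcome-coded diagnosis occurs during
observation, indexed at that date, with prior/concurrent carriers of any
exclusion code removed.  Controls are outcome-free patients indexed at
their last encounter.  Eligibility requires age >= 65 at index, a
"regular use" criterion (>=1 hospitalization or >=2 outpatient visits in
the 365 days before index), and >= 10 years of observed history before
index.  Cases are then matched 1:k to controls on sex, race, ethnicity and
age (within a tolerance), greedily in a seeded random case order with
nearest-age preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mwasplus.data_model import (
    DAYS_PER_YEAR,
    CodeSet,
    EHRDataset,
    first_match_dates,
    match_codeset,
)

INDEX_COLUMNS = ["patient_id", "index_date", "is_case"]


@dataclass
class CaseControlSet:
    """Matched 1:k case-control cohort.

    ``table`` has one row per member: matching_set_id, patient_id, is_case,
    index_date, age, sex, race, ethnicity.  Every set contains exactly one
    case and ``ratio`` controls; no control is reused.
    """

    table: pd.DataFrame
    ratio: int
    age_tolerance_years: float
    matching_keys: tuple[str, ...] = ("sex", "race", "ethnicity", "age")
    dropped_cases: list[str] = field(default_factory=list)
    n_controls_with_later_outcome: int = 0

    @property
    def n_sets(self) -> int:
        return int(self.table["is_case"].sum())

    def index_dates(self) -> pd.Series:
        return self.table.set_index("patient_id")["index_date"]


def identify_incident_cases(dataset: EHRDataset, outcome_codeset: CodeSet,
                            exclusion_codesets: list[CodeSet] | None = None) -> pd.DataFrame:
    """Incident cases: first outcome-coded diagnosis date, exclusions applied.

    A patient carrying any exclusion code dated on or before their index
    date is removed (not re-indexed).  Returns columns
    ``patient_id, index_date, is_case`` with ``is_case=True``.
    """
    first_outcome = first_match_dates(dataset.diagnoses, outcome_codeset)
    cases = first_outcome.rename("index_date").reset_index()
    if exclusion_codesets:
        for codeset in exclusion_codesets:
            excl = first_match_dates(dataset.diagnoses, codeset).rename("excl_date")
            cases = cases.merge(excl.reset_index(), on="patient_id", how="left")
            cases = cases[~(cases["excl_date"] <= cases["index_date"])]
            cases = cases.drop(columns="excl_date")
    cases["is_case"] = True
    return cases.sort_values("patient_id").reset_index(drop=True)


def index_controls(dataset: EHRDataset, outcome_codeset: CodeSet,
                   exclusion_codesets: list[CodeSet] | None = None) -> pd.DataFrame:
    """Control candidates: outcome-free through their index (last encounter).

    Patients with an outcome code on or before their last encounter are
    excluded (they are cases); exclusion code sets are applied at the index
    date just as for cases.  Returns ``patient_id, index_date, is_case``
    with ``is_case=False``.
    """
    last_visit = dataset.encounters.groupby("patient_id")["date"].max().rename("index_date")
    pool = last_visit.reset_index()
    first_outcome = first_match_dates(dataset.diagnoses, outcome_codeset).rename("outcome_date")
    pool = pool.merge(first_outcome.reset_index(), on="patient_id", how="left")
    pool = pool[~(pool["outcome_date"] <= pool["index_date"])]
    pool = pool.drop(columns="outcome_date")
    if exclusion_codesets:
        for codeset in exclusion_codesets:
            excl = first_match_dates(dataset.diagnoses, codeset).rename("excl_date")
            pool = pool.merge(excl.reset_index(), on="patient_id", how="left")
            pool = pool[~(pool["excl_date"] <= pool["index_date"])]
            pool = pool.drop(columns="excl_date")
    pool["is_case"] = False
    return pool.sort_values("patient_id").reset_index(drop=True)


def check_regular_use(encounters: pd.DataFrame, index_date: pd.Timestamp) -> bool:
    """Regular healthcare use in the year before index.

    True iff within ``[index-365d, index-1d]`` the patient has at least one
    inpatient encounter or at least two outpatient encounters.
    """
    lo = pd.Timestamp(index_date) - pd.Timedelta(days=DAYS_PER_YEAR)
    hi = pd.Timestamp(index_date) - pd.Timedelta(days=1)
    recent = encounters[(encounters["date"] >= lo) & (encounters["date"] <= hi)]
    n_inpatient = int((recent["setting"] == "inpatient").sum())
    n_outpatient = int((recent["setting"] == "outpatient").sum())
    return n_inpatient >= 1 or n_outpatient >= 2


def _regular_use_counts(encounters: pd.DataFrame, index_by_patient: pd.Series) -> pd.DataFrame:
    enc = encounters.merge(index_by_patient.rename("index_date"),
                           left_on="patient_id", right_index=True, how="inner")
    delta = (enc["index_date"] - enc["date"]).dt.days
    in_window = (delta >= 1) & (delta <= DAYS_PER_YEAR)
    enc = enc[in_window]
    counts = (enc.groupby(["patient_id", "setting"]).size()
              .unstack(fill_value=0).reindex(columns=["inpatient", "outpatient"], fill_value=0))
    return counts


def apply_eligibility(dataset: EHRDataset, candidates: pd.DataFrame,
                      min_age: float = 65.0, lookback_years: float = 10.0) -> pd.DataFrame:
    """Filter indexed candidates by age, regular use, and observed history.

    Keeps candidates with age >= ``min_age`` at index, the regular-use
    criterion satisfied, and at least ``lookback_years`` * 365 days between
    their first observed encounter and the index date.  Adds
    ``age_at_index``.
    """
    demo = dataset.demographics.set_index("patient_id")
    out = candidates.copy()
    birth = demo["birth_date"].reindex(out["patient_id"]).to_numpy()
    out["age_at_index"] = (out["index_date"].to_numpy() - birth) / np.timedelta64(1, "D") / DAYS_PER_YEAR
    first_enc = dataset.encounters.groupby("patient_id")["date"].min()
    first = first_enc.reindex(out["patient_id"]).to_numpy()
    history_days = (out["index_date"].to_numpy() - first) / np.timedelta64(1, "D")
    index_by_patient = out.set_index("patient_id")["index_date"]
    use = _regular_use_counts(dataset.encounters, index_by_patient)
    regular = ((use["inpatient"] >= 1) | (use["outpatient"] >= 2))
    regular = regular.reindex(out["patient_id"], fill_value=False).to_numpy()
    keep = ((out["age_at_index"] >= min_age)
            & (history_days >= lookback_years * DAYS_PER_YEAR)
            & regular)
    return out[keep].reset_index(drop=True)


def match_case_control(cases: pd.DataFrame, control_pool: pd.DataFrame,
                       demographics: pd.DataFrame, ratio: int = 5,
                       age_tolerance_years: float = 2.0, seed: int = 0) -> CaseControlSet:
    """Greedy 1:``ratio`` matching on sex, race, ethnicity and age.

    Cases are processed in a seeded random order; for each, the ``ratio``
    nearest-age unused controls with identical sex/race/ethnicity and
    |age difference| <= tolerance are drawn without replacement (ties broken
    by patient_id).  Cases with too few available controls are dropped and
    reported in ``dropped_cases``.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    overlap = set(cases["patient_id"]) & set(control_pool["patient_id"])
    if overlap:
        raise ValueError(f"{len(overlap)} patients appear as both case and control candidates")

    demo = demographics.set_index("patient_id")[["sex", "race", "ethnicity", "birth_date"]]

    def _with_keys(df: pd.DataFrame) -> pd.DataFrame:
        out = df.merge(demo, left_on="patient_id", right_index=True, how="left")
        out["age"] = ((out["index_date"] - out["birth_date"]).dt.days / DAYS_PER_YEAR)
        return out.drop(columns="birth_date")

    cases_k = _with_keys(cases)
    pool_k = _with_keys(control_pool)

    # stratified pools: per (sex, race, ethnicity), ages sorted ascending
    strata: dict[tuple, dict[str, np.ndarray]] = {}
    for key, grp in pool_k.groupby(["sex", "race", "ethnicity"], sort=True):
        grp = grp.sort_values(["age", "patient_id"], kind="mergesort")
        strata[key] = {
            "age": grp["age"].to_numpy(),
            "patient_id": grp["patient_id"].to_numpy(),
            "index_date": grp["index_date"].to_numpy(),
            "used": np.zeros(len(grp), dtype=bool),
        }

    rng = np.random.default_rng(seed)
    cases_k = cases_k.sort_values("patient_id", kind="mergesort").reset_index(drop=True)
    order = rng.permutation(len(cases_k))

    rows: list[dict] = []
    dropped: list[str] = []
    set_id = 0
    for i in order:
        case = cases_k.iloc[i]
        key = (case["sex"], case["race"], case["ethnicity"])
        stratum = strata.get(key)
        if stratum is None:
            dropped.append(case["patient_id"])
            continue
        ages = stratum["age"]
        lo = np.searchsorted(ages, case["age"] - age_tolerance_years, side="left")
        hi = np.searchsorted(ages, case["age"] + age_tolerance_years, side="right")
        window = np.arange(lo, hi)
        window = window[~stratum["used"][window]]
        if window.size < ratio:
            dropped.append(case["patient_id"])
            continue
        gaps = np.abs(ages[window] - case["age"])
        # nearest age first, ties by patient_id
        pick_order = np.lexsort((stratum["patient_id"][window], gaps))
        chosen = window[pick_order[:ratio]]
        stratum["used"][chosen] = True
        set_id += 1
        rows.append({
            "matching_set_id": set_id, "patient_id": case["patient_id"], "is_case": True,
            "index_date": case["index_date"], "age": case["age"],
            "sex": key[0], "race": key[1], "ethnicity": key[2],
        })
        for j in chosen:
            rows.append({
                "matching_set_id": set_id, "patient_id": stratum["patient_id"][j],
                "is_case": False, "index_date": pd.Timestamp(stratum["index_date"][j]),
                "age": float(stratum["age"][j]),
                "sex": key[0], "race": key[1], "ethnicity": key[2],
            })
    table = pd.DataFrame(rows, columns=[
        "matching_set_id", "patient_id", "is_case", "index_date", "age",
        "sex", "race", "ethnicity"])
    table = table.sort_values(["matching_set_id", "is_case", "patient_id"],
                              ascending=[True, False, True], kind="mergesort").reset_index(drop=True)
    return CaseControlSet(table=table, ratio=ratio,
                          age_tolerance_years=age_tolerance_years,
                          dropped_cases=sorted(dropped))


def assemble_case_control(dataset: EHRDataset, outcome_codeset: CodeSet,
                          exclusion_codesets: list[CodeSet] | None = None,
                          ratio: int = 5, age_tolerance_years: float = 2.0,
                          min_age: float = 65.0, lookback_years: float = 10.0,
                          seed: int = 0) -> CaseControlSet:
    """End-to-end cohort assembly: cases, controls, eligibility, matching."""
    cases = identify_incident_cases(dataset, outcome_codeset, exclusion_codesets)
    cases = apply_eligibility(dataset, cases, min_age=min_age, lookback_years=lookback_years)
    pool = index_controls(dataset, outcome_codeset, exclusion_codesets)
    pool = apply_eligibility(dataset, pool, min_age=min_age, lookback_years=lookback_years)
    matched = match_case_control(cases, pool, dataset.demographics, ratio=ratio,
                                 age_tolerance_years=age_tolerance_years, seed=seed)
    # incidence-density note: count controls later coded with the outcome
    outcome_dates = first_match_dates(dataset.diagnoses, outcome_codeset)
    controls = matched.table[~matched.table["is_case"]]
    later = outcome_dates.reindex(controls["patient_id"])
    matched.n_controls_with_later_outcome = int(
        (later.to_numpy() > controls["index_date"].to_numpy()).sum())
    return matched
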