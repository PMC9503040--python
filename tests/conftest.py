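"""Shared fixtures: hand-built micro datasets and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mwasplus.data_model import EHRDataset
from mwasplus.presets import demo_config, null_scan_config
from mwasplus.synthetic import generate_population


def build_dataset(demographics=None, encounters=None, diagnoses=None,
                  fills=None, measurements=None,
                  study_start="1999-01-01", study_end="2016-12-31") -> EHRDataset:
    """Assemble an EHRDataset from lists of row dicts, filling defaults."""
    demo_defaults = {
        "sex": "male", "race": "white", "ethnicity": "non_hispanic",
        "marital_status": "married", "income_quartile": "q2",
        "rural_residence": False, "death_date": None,
    }
    demo_rows = []
    for row in demographics or []:
        demo_rows.append({**demo_defaults, **row})
    demo = pd.DataFrame(demo_rows, columns=[
        "patient_id", "birth_date", "sex", "race", "ethnicity",
        "marital_status", "income_quartile", "rural_residence", "death_date"])
    demo["birth_date"] = pd.to_datetime(demo["birth_date"])
    demo["death_date"] = pd.to_datetime(demo["death_date"])

    enc = pd.DataFrame(encounters or [], columns=["patient_id", "date", "setting"])
    enc["date"] = pd.to_datetime(enc["date"])
    dx = pd.DataFrame(diagnoses or [], columns=["patient_id", "date", "code", "code_system"])
    dx["date"] = pd.to_datetime(dx["date"])
    fill_rows = []
    for row in fills or []:
        fill_rows.append({"drug_class": None, "daily_dose": 1.0, **row})
    fl = pd.DataFrame(fill_rows, columns=[
        "patient_id", "drug_id", "drug_class", "fill_date", "days_supply", "daily_dose"])
    fl["fill_date"] = pd.to_datetime(fl["fill_date"])
    if len(fl) == 0:
        fl["days_supply"] = fl["days_supply"].astype(np.int64)
        fl["daily_dose"] = fl["daily_dose"].astype(float)
    ms = pd.DataFrame(measurements or [], columns=["patient_id", "date", "kind", "value"])
    ms["date"] = pd.to_datetime(ms["date"])
    if len(ms) == 0:
        ms["value"] = ms["value"].astype(float)
    return EHRDataset(
        demographics=demo, encounters=enc, diagnoses=dx, fills=fl, measurements=ms,
        study_start=pd.Timestamp(study_start), study_end=pd.Timestamp(study_end),
    )


def yearly_visits(patient_id: str, start_year: int, end_year: int,
                  month: int = 6) -> list[dict]:
    """Two outpatient visits per year, enough for regular use and history."""
    rows = []
    for year in range(start_year, end_year + 1):
        rows.append({"patient_id": patient_id, "date": f"{year}-{month:02d}-01",
                     "setting": "outpatient"})
        rows.append({"patient_id": patient_id, "date": f"{year}-{month:02d}-15",
                     "setting": "outpatient"})
    return rows


@pytest.fixture(scope="session")
def small_population():
    """Small simulated cohort shared by read-only tests (20 null drugs)."""
    return generate_population(null_scan_config(3000, seed=5))


@pytest.fixture(scope="session")
def demo_population():
    """Demo scenario (protective class drug + dose-response + nulls)."""
    return generate_population(demo_config(8000, seed=7))
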