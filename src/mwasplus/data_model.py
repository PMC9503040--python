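"""Domain types and the delimited-table exchange format for longitudinal EHR data.

The pipeline exchanges cohorts as five flat UTF-8 CSV files with fixed
lowercase column names and ISO-8601 (``YYYY-MM-DD``) dates:

========================  =====================================================
file                      columns
========================  =====================================================
``demographics.csv``      patient_id, birth_date, sex, race, ethnicity,
                          marital_status, income_quartile, rural_residence,
                          death_date
``encounters.csv``        patient_id, date, setting
``diagnoses.csv``         patient_id, date, code, code_system
``fills.csv``             patient_id, drug_id, drug_class, fill_date,
                          days_supply, daily_dose
``measurements.csv``      patient_id, date, kind, value
========================  =====================================================

Diagnosis code sets are user configuration: named sets of
``(code_system, code-prefix)`` pairs matched by leading-string comparison
within a code system (``G30`` covers ``G30.0``–``G30.9``).  All date windows
in the pipeline are closed on both ends and one year is 365 days.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

#: One year, in days, everywhere in the pipeline (deterministic windows).
DAYS_PER_YEAR = 365

SEX_VALUES = ("female", "male")
RACE_VALUES = ("african_american", "white", "other")
ETHNICITY_VALUES = ("hispanic", "non_hispanic")
MARITAL_VALUES = ("married", "unmarried")
INCOME_VALUES = ("q1", "q2", "q3", "q4", "unknown")
SETTING_VALUES = ("inpatient", "outpatient")
CODE_SYSTEM_VALUES = ("ICD9", "ICD10")
MEASUREMENT_KINDS = ("bmi", "sbp", "dbp", "glucose", "total_chol", "ldl", "triglycerides")

TABLE_COLUMNS: dict[str, list[str]] = {
    "demographics": [
        "patient_id", "birth_date", "sex", "race", "ethnicity",
        "marital_status", "income_quartile", "rural_residence", "death_date",
    ],
    "encounters": ["patient_id", "date", "setting"],
    "diagnoses": ["patient_id", "date", "code", "code_system"],
    "fills": ["patient_id", "drug_id", "drug_class", "fill_date", "days_supply", "daily_dose"],
    "measurements": ["patient_id", "date", "kind", "value"],
}

_DATE_COLUMNS: dict[str, list[str]] = {
    "demographics": ["birth_date", "death_date"],
    "encounters": ["date"],
    "diagnoses": ["date"],
    "fills": ["fill_date"],
    "measurements": ["date"],
}

_SORT_KEYS: dict[str, list[str]] = {
    "demographics": ["patient_id"],
    "encounters": ["patient_id", "date", "setting"],
    "diagnoses": ["patient_id", "date", "code_system", "code"],
    "fills": ["patient_id", "fill_date", "drug_id", "days_supply"],
    "measurements": ["patient_id", "date", "kind", "value"],
}


@dataclass(frozen=True)
class ValidationIssue:
    """One validation failure, naming the offending table, row and field."""

    table: str
    row: int | None
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - formatting
        where = f"{self.table}" if self.row is None else f"{self.table} row {self.row}"
        return f"{where}, field '{self.field}': {self.message}"


class ValidationError(ValueError):
    """Raised when a dataset violates the exchange-format contract."""

    def __init__(self, issues: list[ValidationIssue]):
        self.issues = issues
        lines = "\n".join(f"  - {issue}" for issue in issues[:50])
        extra = "" if len(issues) <= 50 else f"\n  ... and {len(issues) - 50} more"
        super().__init__(f"{len(issues)} validation issue(s):\n{lines}{extra}")


@dataclass
class EHRDataset:
    """Container of the five longitudinal tables keyed by ``patient_id``.

    Every patient_id appearing in the four event tables must appear in
    ``demographics`` and all event dates must fall within
    ``[study_start, study_end]``.
    """

    demographics: pd.DataFrame
    encounters: pd.DataFrame
    diagnoses: pd.DataFrame
    fills: pd.DataFrame
    measurements: pd.DataFrame
    study_start: pd.Timestamp
    study_end: pd.Timestamp

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def canonical(self) -> "EHRDataset":
        """Copy with rows in canonical sort order and normalized dtypes."""
        out = {}
        for name, cols in TABLE_COLUMNS.items():
            df = self.table(name).copy()
            df = df[cols]
            for col in _DATE_COLUMNS[name]:
                df[col] = pd.to_datetime(df[col]).astype("datetime64[ns]")
            if name == "fills":
                df["days_supply"] = df["days_supply"].astype(np.int64)
                df["daily_dose"] = df["daily_dose"].astype(np.float64)
                df["drug_class"] = df["drug_class"].astype(object).where(df["drug_class"].notna(), None)
            if name == "measurements":
                df["value"] = df["value"].astype(np.float64)
            if name == "demographics":
                df["rural_residence"] = df["rural_residence"].astype(bool)
            df = df.sort_values(_SORT_KEYS[name], kind="mergesort").reset_index(drop=True)
            out[name] = df
        return EHRDataset(
            demographics=out["demographics"],
            encounters=out["encounters"],
            diagnoses=out["diagnoses"],
            fills=out["fills"],
            measurements=out["measurements"],
            study_start=pd.Timestamp(self.study_start),
            study_end=pd.Timestamp(self.study_end),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EHRDataset):
            return NotImplemented
        a, b = self.canonical(), other.canonical()
        if (a.study_start, a.study_end) != (b.study_start, b.study_end):
            return False
        for name in TABLE_COLUMNS:
            try:
                pd.testing.assert_frame_equal(a.table(name), b.table(name), check_dtype=False)
            except AssertionError:
                return False
        return True

    def validate(self) -> list[ValidationIssue]:
        """Check the container invariants; returns the list of issues found."""
        issues: list[ValidationIssue] = []
        demo = self.demographics

        def _bad(table: str, rows: Iterable[int], field: str, message: str) -> None:
            for row in rows:
                issues.append(ValidationIssue(table, int(row), field, message))

        dup = demo.index[demo["patient_id"].duplicated()]
        _bad("demographics", dup, "patient_id", "duplicate patient_id")
        for col, allowed in (
            ("sex", SEX_VALUES), ("race", RACE_VALUES), ("ethnicity", ETHNICITY_VALUES),
            ("marital_status", MARITAL_VALUES), ("income_quartile", INCOME_VALUES),
        ):
            bad = demo.index[~demo[col].isin(allowed)]
            _bad("demographics", bad, col, f"value not in {allowed}")
        death = pd.to_datetime(demo["death_date"])
        birth = pd.to_datetime(demo["birth_date"])
        bad = demo.index[death.notna() & (death < birth)]
        _bad("demographics", bad, "death_date", "death_date before birth_date")

        known = set(demo["patient_id"])
        for name in ("encounters", "diagnoses", "fills", "measurements"):
            df = self.table(name)
            missing = df.index[~df["patient_id"].isin(known)]
            _bad(name, missing, "patient_id", "patient not present in demographics")
            date_col = _DATE_COLUMNS[name][0]
            dates = pd.to_datetime(df[date_col])
            out_of_range = df.index[
                dates.notna() & ((dates < self.study_start) | (dates > self.study_end))
            ]
            _bad(name, out_of_range, date_col, "date outside [study_start, study_end]")
            _bad(name, df.index[dates.isna()], date_col, "unparseable or missing date")

        bad = self.encounters.index[~self.encounters["setting"].isin(SETTING_VALUES)]
        _bad("encounters", bad, "setting", f"value not in {SETTING_VALUES}")
        dx = self.diagnoses
        _bad("diagnoses", dx.index[dx["code"].astype(str).str.len() == 0], "code", "empty code")
        _bad("diagnoses", dx.index[~dx["code_system"].isin(CODE_SYSTEM_VALUES)],
             "code_system", f"value not in {CODE_SYSTEM_VALUES}")
        fl = self.fills
        supply = pd.to_numeric(fl["days_supply"], errors="coerce")
        _bad("fills", fl.index[~(supply >= 1)], "days_supply", "days_supply must be >= 1")
        dose = pd.to_numeric(fl["daily_dose"], errors="coerce")
        _bad("fills", fl.index[fl["daily_dose"].notna() & ~(dose > 0)],
             "daily_dose", "daily_dose must be > 0 when present")
        ms = self.measurements
        _bad("measurements", ms.index[~ms["kind"].isin(MEASUREMENT_KINDS)],
             "kind", f"value not in {MEASUREMENT_KINDS}")
        value = pd.to_numeric(ms["value"], errors="coerce")
        _bad("measurements", ms.index[~(value > 0)], "value", "value must be > 0")
        return issues


@dataclass(frozen=True)
class Dialect:
    """Exchange-format dialect: delimiter, date format and column names are fixed
    unless overridden here."""

    delimiter: str = ","
    date_format: str = "%Y-%m-%d"


def _parse_dates(df: pd.DataFrame, table: str, dialect: Dialect,
                 issues: list[ValidationIssue]) -> pd.DataFrame:
    for col in _DATE_COLUMNS[table]:
        raw = df[col]
        parsed = pd.to_datetime(raw, format=dialect.date_format, errors="coerce")
        optional = table == "demographics" and col == "death_date"
        blank = raw.isna() | (raw.astype(str).str.strip() == "")
        failed = parsed.isna() & ~blank
        for row in df.index[failed]:
            issues.append(ValidationIssue(table, int(row), col,
                                          f"unparseable date {raw.loc[row]!r}"))
        if not optional:
            for row in df.index[blank]:
                issues.append(ValidationIssue(table, int(row), col, "missing date"))
        df[col] = parsed
    return df


def read_ehr_tables(directory: str | Path, dialect: Dialect | None = None,
                    study_start: str | pd.Timestamp | None = None,
                    study_end: str | pd.Timestamp | None = None) -> EHRDataset:
    """Read and validate the five-table exchange directory.

    Study bounds are read from ``study_period.csv`` if present (written by
    :func:`write_ehr_tables`) unless overridden.  Any malformed row is
    reported with its table, row number and field; nothing is silently
    dropped.

    Raises
    ------
    FileNotFoundError
        if any of the five files is absent.
    ValidationError
        if any row fails type coercion or an invariant.
    """
    directory = Path(directory)
    dialect = dialect or Dialect()
    frames: dict[str, pd.DataFrame] = {}
    issues: list[ValidationIssue] = []
    for name, cols in TABLE_COLUMNS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing exchange file: {path}")
        df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
        missing_cols = [c for c in cols if c not in df.columns]
        if missing_cols:
            raise ValidationError([
                ValidationIssue(name, None, c, "missing column") for c in missing_cols
            ])
        df = df[cols].replace("", None)
        df = _parse_dates(df, name, dialect, issues)
        frames[name] = df

    demo = frames["demographics"]
    demo["rural_residence"] = demo["rural_residence"].map(
        {"true": True, "false": False, "True": True, "False": False})
    for row in demo.index[demo["rural_residence"].isna()]:
        issues.append(ValidationIssue("demographics", int(row), "rural_residence",
                                      "must be 'true' or 'false'"))
    fl = frames["fills"]
    fl["days_supply"] = pd.to_numeric(fl["days_supply"], errors="coerce")
    fl["daily_dose"] = pd.to_numeric(fl["daily_dose"], errors="coerce")
    frames["measurements"]["value"] = pd.to_numeric(frames["measurements"]["value"],
                                                    errors="coerce")

    period_path = directory / "study_period.csv"
    if study_start is None or study_end is None:
        if period_path.exists():
            period = pd.read_csv(period_path)
            study_start = study_start or period["study_start"].iloc[0]
            study_end = study_end or period["study_end"].iloc[0]
        else:
            all_dates = pd.concat([
                frames[t][_DATE_COLUMNS[t][0]] for t in
                ("encounters", "diagnoses", "fills", "measurements")
            ])
            study_start = study_start or all_dates.min()
            study_end = study_end or all_dates.max()

    dataset = EHRDataset(
        demographics=frames["demographics"], encounters=frames["encounters"],
        diagnoses=frames["diagnoses"], fills=frames["fills"],
        measurements=frames["measurements"],
        study_start=pd.Timestamp(study_start), study_end=pd.Timestamp(study_end),
    )
    issues.extend(dataset.validate())
    if issues:
        raise ValidationError(issues)
    return dataset.canonical()


def write_ehr_tables(dataset: EHRDataset, directory: str | Path) -> dict[str, int]:
    """Write the dataset in the canonical dialect; returns ``{file: n_rows}``.

    Output is deterministic (canonical row order, ISO dates, lowercase
    booleans) so two writes of the same dataset are byte-identical and
    ``read_ehr_tables(write_ehr_tables(d)) == d``.
    """
    issues = dataset.validate()
    if issues:
        raise ValidationError(issues)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    canonical = dataset.canonical()
    manifest: dict[str, int] = {}
    for name in TABLE_COLUMNS:
        df = canonical.table(name).copy()
        for col in _DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        if name == "demographics":
            df["rural_residence"] = np.where(df["rural_residence"], "true", "false")
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")
        manifest[f"{name}.csv"] = len(df)
    pd.DataFrame({
        "study_start": [canonical.study_start.strftime("%Y-%m-%d")],
        "study_end": [canonical.study_end.strftime("%Y-%m-%d")],
    }).to_csv(directory / "study_period.csv", index=False, lineterminator="\n")
    manifest["study_period.csv"] = 1
    return manifest


@dataclass(frozen=True)
class CodeSet:
    """Named set of ``(code_system, code-prefix)`` pairs.

    An event matches iff its code system equals a listed system and its code
    starts with the listed prefix.
    """

    name: str
    codes: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError(f"code set {self.name!r} is empty")
        for system, prefix in self.codes:
            if system not in CODE_SYSTEM_VALUES:
                raise ValueError(f"code set {self.name!r}: unknown code system {system!r}")
            if not prefix:
                raise ValueError(f"code set {self.name!r}: empty code prefix")

    @classmethod
    def from_pairs(cls, name: str, pairs: Iterable[tuple[str, str]]) -> "CodeSet":
        return cls(name=name, codes=frozenset((s, p) for s, p in pairs))


def match_codeset(diagnoses: pd.DataFrame, codeset: CodeSet) -> pd.DataFrame:
    """Diagnosis events matching the code set, sorted by (patient_id, date).

    The result is invariant to the row order of ``diagnoses``.
    """
    code = diagnoses["code"].astype(str)
    mask = np.zeros(len(diagnoses), dtype=bool)
    for system, prefix in sorted(codeset.codes):
        mask |= ((diagnoses["code_system"] == system) & code.str.startswith(prefix)).to_numpy()
    out = diagnoses.loc[mask]
    return out.sort_values(["patient_id", "date", "code_system", "code"],
                           kind="mergesort").reset_index(drop=True)


def first_match_dates(diagnoses: pd.DataFrame, codeset: CodeSet) -> pd.Series:
    """Per-patient date of the first diagnosis matching the code set."""
    matches = match_codeset(diagnoses, codeset)
    if matches.empty:
        return pd.Series(dtype="datetime64[ns]", name="date",
                         index=pd.Index([], name="patient_id"))
    return matches.groupby("patient_id")["date"].min()


def load_codesets(path: str | Path) -> dict[str, CodeSet]:
    """Load code sets from a YAML file mapping name -> list of [system, prefix]."""
    with open(path, "r", encoding="utf-8") as fh:
        raw: Mapping[str, list] = yaml.safe_load(fh)
    return {name: CodeSet.from_pairs(name, [tuple(pair) for pair in pairs])
            for name, pairs in raw.items()}


def dump_codesets(codesets: Mapping[str, CodeSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {name: sorted([list(p) for p in cs.codes]) for name, cs in codesets.items()},
            fh, sort_keys=True)
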