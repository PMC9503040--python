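"""Target-trial emulation for a drug class: sequential trials, propensity
matching, balance diagnostics, and intention-to-treat hazard estimation.

The design mimics a randomized trial on observational data.  For each
annual trial, indication carriers who fill the class drug for the first
time that year are "enrolled" as initiators (new-user design) with time
zero at the first fill; carriers with no class fill through year end and at
least one other prescription that year enter as non-initiators, anchored at
a seeded-random non-class fill date.  Each patient enrolls at most once
(earliest eligible trial).  Propensity scores for initiation are fit by
logistic regression on the covariate battery measured at index (last
observation carried forward), initiators are matched 1:1 to non-initiators
on the logit propensity within a caliper, and the arm effect on
time-to-outcome is estimated by Cox regression, unadjusted or with the
propensity score as a covariate.  Exposure is fixed at baseline
(intention-to-treat): later crossover is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from mwasplus.data_model import DAYS_PER_YEAR, CodeSet, EHRDataset, first_match_dates
from mwasplus.codesets import COMORBIDITIES

logger = logging.getLogger(__name__)

MEASUREMENT_COVARIATES = ("bmi", "sbp", "dbp", "glucose", "total_chol", "ldl",
                          "triglycerides")

_MIN_FOLLOWUP_YEARS = 1.0 / DAYS_PER_YEAR


@dataclass
class EnrolleeFrame:
    """Sequential-trial enrollees with index dates and baseline covariates."""

    frame: pd.DataFrame
    covariate_cols: list[str]
    trial_years: list[int]

    @property
    def n_initiators(self) -> int:
        return int((self.frame["arm"] == "initiator").sum())

    @property
    def n_non_initiators(self) -> int:
        return int((self.frame["arm"] == "non_initiator").sum())


@dataclass
class PropensityResult:
    """Fitted propensity model: scored enrollees plus coefficient report."""

    frame: pd.DataFrame
    coefficients: pd.DataFrame
    converged: bool
    n_iterations: int
    covariate_cols: list[str]


@dataclass
class MatchedTrialCohort:
    """1:1 propensity-matched initiator/non-initiator pairs with follow-up.

    ``frame`` is long (one row per patient) with pair_id, arm, index_date,
    propensity scores, follow_up_years and the event indicator.
    """

    frame: pd.DataFrame
    caliper: float
    logit_sd: float
    n_unmatched_initiators: int

    @property
    def n_pairs(self) -> int:
        return int((self.frame["arm"] == "initiator").sum())


@dataclass(frozen=True)
class HazardEstimate:
    """Hazard ratio with Wald CI, p-value and analysis provenance."""

    label: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    adjustment: str  # "unadjusted" | "ps_adjusted"
    n_treated: int
    n_control: int
    n_events_treated: int
    n_events_control: int


def _first_class_fill(fills: pd.DataFrame, drug_class) -> pd.DataFrame:
    """First-ever class fill per patient (date and drug filled)."""
    mask = _class_mask(fills, drug_class)
    sub = fills[mask].sort_values(["patient_id", "fill_date", "drug_id"], kind="mergesort")
    first = sub.groupby("patient_id", as_index=False).first()
    return first[["patient_id", "fill_date", "drug_id"]].rename(
        columns={"fill_date": "first_class_fill", "drug_id": "first_class_drug"})


def _class_mask(fills: pd.DataFrame, drug_class) -> pd.Series:
    if isinstance(drug_class, str):
        return fills["drug_class"] == drug_class
    return fills["drug_id"].isin(set(drug_class))


def enroll_sequential_trials(dataset: EHRDataset, indication_codeset: CodeSet,
                             drug_class, trial_years: Sequence[int],
                             outcome_codeset: CodeSet, seed: int = 0,
                             comorbidity_codesets: Mapping[str, CodeSet] | None = None,
                             ) -> EnrolleeFrame:
    """Enroll initiators and non-initiators into sequential annual trials.

    ``drug_class`` is either a class label (matched against the fills
    table's ``drug_class`` column) or an iterable of drug_ids.  Washout is
    strict new-user: the qualifying fill must be the first class fill at
    any observed time.  A patient enrolls in at most one trial (the first
    eligible one, initiator status taking precedence within a year); a
    later initiator may thus appear as a non-initiator in an earlier trial
    only, and stays in that arm (intention-to-treat).

    Raises
    ------
    ValueError
        if no trial year yields any initiator.
    """
    trial_years = sorted(trial_years)
    rng = np.random.default_rng(seed)
    fills = dataset.fills
    first_class = _first_class_fill(fills, drug_class).set_index("patient_id")
    indication = first_match_dates(dataset.diagnoses, indication_codeset)
    outcome = first_match_dates(dataset.diagnoses, outcome_codeset)

    # only fills inside the trial years can anchor a non-initiator index
    in_trial_years = fills["fill_date"].dt.year.isin(set(trial_years))
    nonclass_fills = fills[in_trial_years & ~_class_mask(fills, drug_class)]
    frozen: set[str] = set()
    rows: list[pd.DataFrame] = []
    for year in trial_years:
        year_end = pd.Timestamp(year=year, month=12, day=31)

        fc = first_class[first_class["first_class_fill"].dt.year == year]
        ind_at = indication.reindex(fc.index)
        out_at = outcome.reindex(fc.index)
        ok = (ind_at <= fc["first_class_fill"]).to_numpy()
        ok &= ~(out_at <= fc["first_class_fill"]).to_numpy()
        ok &= ~fc.index.isin(frozen)
        initiators = pd.DataFrame({
            "patient_id": fc.index[ok],
            "trial_year": year,
            "arm": "initiator",
            "index_date": fc["first_class_fill"].to_numpy()[ok],
            "drug_id": fc["first_class_drug"].to_numpy()[ok],
        })

        nc = nonclass_fills[nonclass_fills["fill_date"].dt.year == year]
        nc = nc[nc["patient_id"].isin(indication.index) & ~nc["patient_id"].isin(frozen)]
        fc_all = first_class["first_class_fill"].reindex(nc["patient_id"])
        nc = nc[~(fc_all.to_numpy() <= np.datetime64(year_end))]
        nc = nc.sort_values(["patient_id", "fill_date", "drug_id"], kind="mergesort")
        # one seeded-random fill per candidate anchors the index date
        sizes = nc.groupby("patient_id", sort=True).size()
        offsets = np.concatenate([[0], np.cumsum(sizes.to_numpy())[:-1]])
        pick = offsets + (rng.random(len(sizes)) * sizes.to_numpy()).astype(np.int64)
        chosen = nc.iloc[pick]
        idx_dates = chosen["fill_date"]
        ok = (indication.reindex(chosen["patient_id"]).to_numpy() <= idx_dates.to_numpy())
        ok &= ~(outcome.reindex(chosen["patient_id"]).to_numpy() <= idx_dates.to_numpy())
        ok &= ~chosen["patient_id"].isin(initiators["patient_id"]).to_numpy()
        chosen = chosen[ok]
        non_initiators = pd.DataFrame({
            "patient_id": chosen["patient_id"].to_numpy(),
            "trial_year": year,
            "arm": "non_initiator",
            "index_date": chosen["fill_date"].to_numpy(),
            "drug_id": None,
        })
        enrolled = pd.concat([initiators, non_initiators], ignore_index=True)
        frozen.update(enrolled["patient_id"])
        rows.append(enrolled)

    frame = pd.concat(rows, ignore_index=True)
    if (frame["arm"] == "initiator").sum() == 0:
        raise ValueError(f"no initiators in any trial year {trial_years}")

    frame, covariate_cols = _attach_covariates(
        dataset, frame, indication, outcome,
        comorbidity_codesets if comorbidity_codesets is not None else COMORBIDITIES)
    frame = frame.sort_values(["trial_year", "arm", "patient_id"],
                              kind="mergesort").reset_index(drop=True)
    return EnrolleeFrame(frame=frame, covariate_cols=covariate_cols,
                         trial_years=list(trial_years))


def _attach_covariates(dataset: EHRDataset, frame: pd.DataFrame,
                       indication: pd.Series, outcome: pd.Series,
                       comorbidity_codesets: Mapping[str, CodeSet],
                       ) -> tuple[pd.DataFrame, list[str]]:
    demo = dataset.demographics.set_index("patient_id")
    pid = frame["patient_id"]
    idx = frame["index_date"]

    frame = frame.copy()
    birth = demo["birth_date"].reindex(pid).to_numpy()
    frame["age"] = (idx.to_numpy() - birth) / np.timedelta64(1, "D") / DAYS_PER_YEAR
    frame["female"] = (demo["sex"].reindex(pid) == "female").to_numpy().astype(float)
    frame["race_african_american"] = (demo["race"].reindex(pid) == "african_american").to_numpy().astype(float)
    frame["race_other"] = (demo["race"].reindex(pid) == "other").to_numpy().astype(float)
    frame["hispanic"] = (demo["ethnicity"].reindex(pid) == "hispanic").to_numpy().astype(float)
    frame["unmarried"] = (demo["marital_status"].reindex(pid) == "unmarried").to_numpy().astype(float)
    income = demo["income_quartile"].reindex(pid)
    for q in ("q2", "q3", "q4", "unknown"):
        frame[f"income_{q}"] = (income == q).to_numpy().astype(float)
    frame["rural"] = demo["rural_residence"].reindex(pid).to_numpy().astype(float)

    ind_dates = indication.reindex(pid).to_numpy()
    frame["indication_year"] = pd.to_datetime(ind_dates).year.astype(float)
    frame["disease_duration_years"] = (idx.to_numpy() - ind_dates) / np.timedelta64(1, "D") / DAYS_PER_YEAR

    covariate_cols = ["age", "female", "race_african_american", "race_other",
                      "hispanic", "unmarried", "income_q2", "income_q3",
                      "income_q4", "income_unknown", "rural",
                      "indication_year", "disease_duration_years"]

    for name, codeset in comorbidity_codesets.items():
        first = first_match_dates(dataset.diagnoses, codeset)
        frame[name] = (first.reindex(pid).to_numpy() <= idx.to_numpy()).astype(float)
        covariate_cols.append(name)

    # labs/vitals: last observation on/before index, median-imputed with flag
    meas = dataset.measurements
    order = frame[["patient_id", "index_date"]].reset_index()  # keep original row order
    order = order.sort_values("index_date", kind="mergesort")
    for kind in MEASUREMENT_COVARIATES:
        sub = meas[meas["kind"] == kind].sort_values("date", kind="mergesort")
        merged = pd.merge_asof(order, sub[["patient_id", "date", "value"]],
                               left_on="index_date", right_on="date",
                               by="patient_id", direction="backward")
        values = merged.set_index("index")["value"].reindex(frame.index)
        missing = values.isna()
        median = values.median()
        frame[kind] = values.fillna(median if np.isfinite(median) else 0.0)
        frame[f"{kind}_missing"] = missing.to_numpy().astype(float)
        covariate_cols.extend([kind, f"{kind}_missing"])

    # follow-up anchors for downstream survival analysis
    frame["outcome_date"] = outcome.reindex(pid).to_numpy()
    frame["death_date"] = demo["death_date"].reindex(pid).to_numpy()
    return frame, covariate_cols


def estimate_propensity(enrollees: EnrolleeFrame | pd.DataFrame,
                        covariate_cols: Sequence[str] | None = None,
                        separation_bound: float = 15.0) -> PropensityResult:
    """Logistic-regression propensity of initiation given baseline covariates.

    Returns the enrollee frame with ``propensity_score`` and ``logit_ps``
    columns plus the fitted coefficient report.

    Raises
    ------
    ValueError
        if a covariate is constant (named in the message) or a coefficient
        magnitude exceeds ``separation_bound`` (suggesting separation).
    """
    if isinstance(enrollees, EnrolleeFrame):
        frame = enrollees.frame
        covariate_cols = list(covariate_cols or enrollees.covariate_cols)
    else:
        frame = enrollees
        covariate_cols = list(covariate_cols or [])
    if not covariate_cols:
        raise ValueError("covariate_cols must be provided")
    constant = [c for c in covariate_cols if frame[c].nunique(dropna=False) <= 1]
    if constant:
        raise ValueError(f"constant covariate(s): {', '.join(constant)}")
    # exact duplicates (e.g. missingness flags of jointly sampled labs) would
    # make the design singular; keep the first of each duplicate group
    seen: dict[bytes, str] = {}
    kept: list[str] = []
    for col in covariate_cols:
        key = frame[col].to_numpy(dtype=float).tobytes()
        if key in seen:
            logger.info("covariate %s duplicates %s; dropped from the PS model",
                        col, seen[key])
            continue
        seen[key] = col
        kept.append(col)
    covariate_cols = kept

    y = (frame["arm"] == "initiator").to_numpy(dtype=float)
    X = sm.add_constant(frame[covariate_cols].astype(float), has_constant="add")
    model = sm.Logit(y, X)
    res = model.fit(disp=0, maxiter=200, method="newton")
    big = res.params.drop("const")[np.abs(res.params.drop("const")) > separation_bound]
    if len(big):
        raise ValueError(
            "possible separation; inspect covariate(s) with extreme coefficients: "
            + ", ".join(big.index))
    converged = bool(res.mle_retvals.get("converged", True))
    if not converged:
        logger.warning("propensity model did not fully converge after %s iterations",
                       res.mle_retvals.get("iterations"))
    score = np.clip(res.predict(X), 1e-12, 1 - 1e-12)
    out = frame.copy()
    out["propensity_score"] = score
    out["logit_ps"] = np.log(score / (1 - score))
    coefficients = pd.DataFrame({
        "coefficient": res.params, "std_error": res.bse,
        "z": res.tvalues, "p_value": res.pvalues,
    })
    return PropensityResult(frame=out, coefficients=coefficients,
                            converged=converged,
                            n_iterations=int(res.mle_retvals.get("iterations", 0)),
                            covariate_cols=covariate_cols)


def _greedy_nearest_match(treated_logits: np.ndarray, control_logits: np.ndarray,
                          caliper: float, rng: np.random.Generator,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Greedy nearest-neighbor matching without replacement on sorted controls.

    Returns (treated_idx, control_idx) pairs; treated processed in a seeded
    random order.  Control indices refer to the original control array.
    """
    m = control_logits.size
    order_c = np.argsort(control_logits, kind="stable")
    vals = control_logits[order_c]
    # next-available pointer arrays with sentinels at both ends
    right = np.arange(m + 1)          # right[i]: candidate >= slot i (m = none)
    left = np.arange(m + 1) - 1       # left[i]: candidate <= slot i-1 (-1 = none)

    def find_right(i: int) -> int:
        path = []
        while i < m and right[i] != i:
            path.append(i)
            i = right[i]
        for p in path:
            right[p] = i
        return i if i < m else m

    def find_left(i: int) -> int:
        path = []
        j = i + 1
        while j > 0 and left[j] != j - 1:
            path.append(j)
            j = left[j] + 1
        for p in path:
            left[p] = j - 1
        return j - 1

    t_order = rng.permutation(treated_logits.size)
    t_pick: list[int] = []
    c_pick: list[int] = []
    for t in t_order:
        x = treated_logits[t]
        pos = int(np.searchsorted(vals, x))
        r = find_right(pos)
        l = find_left(pos - 1)
        d_r = vals[r] - x if r < m else np.inf
        d_l = x - vals[l] if l >= 0 else np.inf
        j = r if d_r <= d_l else l
        d = min(d_r, d_l)
        if d > caliper:
            continue
        # remove slot j
        right[j] = j + 1
        left[j + 1] = j - 1
        t_pick.append(t)
        c_pick.append(order_c[j])
    return np.asarray(t_pick, dtype=np.int64), np.asarray(c_pick, dtype=np.int64)


def match_1to1(propensity: PropensityResult, study_end: pd.Timestamp,
               caliper_sd_multiplier: float = 0.2, seed: int = 0,
               ) -> MatchedTrialCohort:
    """Greedy 1:1 nearest-neighbor matching on the logit propensity score.

    The caliper is ``caliper_sd_multiplier`` times the SD of the pooled
    logit scores.  Follow-up runs from index to the earliest of outcome,
    death and ``study_end``; the event indicator marks the outcome coming
    first.

    Raises
    ------
    RuntimeError
        if no pair can be formed (with overlap diagnostics).
    """
    frame = propensity.frame
    treated = frame[frame["arm"] == "initiator"].reset_index(drop=True)
    control = frame[frame["arm"] == "non_initiator"].reset_index(drop=True)
    if treated.empty or control.empty:
        raise RuntimeError("both arms must be non-empty for matching")
    pooled_sd = float(frame["logit_ps"].std(ddof=1))
    caliper = caliper_sd_multiplier * pooled_sd
    rng = np.random.default_rng(seed)
    t_idx, c_idx = _greedy_nearest_match(
        treated["logit_ps"].to_numpy(), control["logit_ps"].to_numpy(), caliper, rng)
    if t_idx.size == 0:
        raise RuntimeError(
            "zero pairs formed: treated logit range "
            f"[{treated['logit_ps'].min():.3f}, {treated['logit_ps'].max():.3f}] vs "
            f"control [{control['logit_ps'].min():.3f}, {control['logit_ps'].max():.3f}], "
            f"caliper {caliper:.4f}")
    pair_ids = np.arange(1, t_idx.size + 1)
    t_rows = treated.iloc[t_idx].copy()
    t_rows["pair_id"] = pair_ids
    c_rows = control.iloc[c_idx].copy()
    c_rows["pair_id"] = pair_ids
    matched = pd.concat([t_rows, c_rows], ignore_index=True)
    matched = matched.sort_values(["pair_id", "arm"], kind="mergesort").reset_index(drop=True)

    death = matched["death_date"].to_numpy()
    se = np.datetime64(pd.Timestamp(study_end))
    end = np.minimum(np.where(pd.isna(death), se, death), se)
    outcome = matched["outcome_date"]
    event = outcome.notna().to_numpy() & (outcome.to_numpy() <= end)
    end = np.where(event, outcome.to_numpy(), end)
    follow_up = (end - matched["index_date"].to_numpy()) / np.timedelta64(1, "D") / DAYS_PER_YEAR
    matched["event"] = event.astype(int)
    matched["follow_up_years"] = np.maximum(follow_up, _MIN_FOLLOWUP_YEARS)
    return MatchedTrialCohort(
        frame=matched, caliper=caliper, logit_sd=pooled_sd,
        n_unmatched_initiators=len(treated) - t_idx.size)


def standardized_difference(summary_a, summary_b, kind: str = "continuous") -> float:
    """Absolute standardized difference between two arm summaries, in percent.

    ``continuous``: summaries are ``(mean, sd)`` pairs and the result is
    ``100*|m_a - m_b| / sqrt((s_a^2 + s_b^2)/2)``.  ``binary``: summaries
    are proportions ``p`` and the pooled SD uses ``p(1-p)``.  A zero pooled
    variance with unequal means yields ``inf``; with equal means, 0.
    """
    if kind == "continuous":
        (m_a, s_a), (m_b, s_b) = summary_a, summary_b
        pooled = np.sqrt((s_a**2 + s_b**2) / 2.0)
    elif kind == "binary":
        p_a, p_b = float(summary_a), float(summary_b)
        if not (0.0 <= p_a <= 1.0 and 0.0 <= p_b <= 1.0):
            raise ValueError("proportions must be in [0,1]")
        m_a, m_b = p_a, p_b
        pooled = np.sqrt((p_a * (1 - p_a) + p_b * (1 - p_b)) / 2.0)
    else:
        raise ValueError("kind must be 'continuous' or 'binary'")
    diff = abs(m_a - m_b)
    if pooled == 0.0:
        return 0.0 if diff == 0.0 else float("inf")
    return float(100.0 * diff / pooled)


def _is_binary(values: pd.Series) -> bool:
    uniq = set(pd.unique(values.dropna()))
    return uniq <= {0, 0.0, 1, 1.0}


def balance_report(enrollees: EnrolleeFrame | pd.DataFrame,
                   matched: MatchedTrialCohort,
                   covariate_cols: Sequence[str] | None = None) -> pd.DataFrame:
    """Pre- and post-match covariate balance table.

    One row per covariate and phase with per-arm summaries, a two-sample
    p-value (Welch t-test for continuous, chi-square for binary) and the
    standardized difference (exact and rounded to integer percent).
    """
    if isinstance(enrollees, EnrolleeFrame):
        pre = enrollees.frame
        covariate_cols = list(covariate_cols or enrollees.covariate_cols)
    else:
        pre = enrollees
        covariate_cols = list(covariate_cols or [])
    phases = [("pre_match", pre), ("post_match", matched.frame)]
    rows = []
    for phase, frame in phases:
        a = frame[frame["arm"] == "initiator"]
        b = frame[frame["arm"] == "non_initiator"]
        for cov in covariate_cols:
            if cov not in frame.columns:
                rows.append({"covariate": cov, "phase": phase, "missing": True})
                continue
            xa, xb = a[cov].dropna(), b[cov].dropna()
            if _is_binary(frame[cov]):
                p_a, p_b = float(xa.mean()), float(xb.mean())
                asd = standardized_difference(p_a, p_b, kind="binary")
                ct = np.array([[xa.sum(), len(xa) - xa.sum()],
                               [xb.sum(), len(xb) - xb.sum()]], dtype=float)
                if ct[:, 0].sum() in (0.0, ct.sum()):
                    p_value = 1.0
                else:
                    p_value = float(stats.chi2_contingency(ct, correction=False)[1])
                rows.append({
                    "covariate": cov, "phase": phase, "kind": "binary",
                    "initiator_summary": p_a, "non_initiator_summary": p_b,
                    "p_value": p_value, "asd": asd,
                    "asd_percent": int(round(asd)) if np.isfinite(asd) else np.inf,
                    "missing": False,
                })
            else:
                sa, sb = (float(xa.mean()), float(xa.std(ddof=1))), \
                         (float(xb.mean()), float(xb.std(ddof=1)))
                asd = standardized_difference(sa, sb, kind="continuous")
                p_value = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
                rows.append({
                    "covariate": cov, "phase": phase, "kind": "continuous",
                    "initiator_summary": sa[0], "non_initiator_summary": sb[0],
                    "initiator_sd": sa[1], "non_initiator_sd": sb[1],
                    "p_value": p_value, "asd": asd,
                    "asd_percent": int(round(asd)) if np.isfinite(asd) else np.inf,
                    "missing": False,
                })
    return pd.DataFrame(rows)


def fit_itt_hazard(matched: MatchedTrialCohort, adjustment: str = "unadjusted",
                   label: str = "class vs none") -> HazardEstimate:
    """Intention-to-treat Cox hazard ratio for initiation.

    ``adjustment="ps_adjusted"`` adds the propensity score as a covariate.
    Ties are handled by the Efron approximation.

    Raises
    ------
    ValueError
        if either arm has no events.
    """
    if adjustment not in ("unadjusted", "ps_adjusted"):
        raise ValueError("adjustment must be 'unadjusted' or 'ps_adjusted'")
    frame = matched.frame if isinstance(matched, MatchedTrialCohort) else matched
    return _cox_arm_effect(frame, adjustment, label)


def _cox_arm_effect(frame: pd.DataFrame, adjustment: str, label: str) -> HazardEstimate:
    df = pd.DataFrame({
        "duration": frame["follow_up_years"].to_numpy(dtype=float),
        "event": frame["event"].to_numpy(dtype=int),
        "treated": (frame["arm"] == "initiator").to_numpy(dtype=float),
    })
    ev_t = int(df.loc[df["treated"] == 1, "event"].sum())
    ev_c = int(df.loc[df["treated"] == 0, "event"].sum())
    if ev_t == 0 or ev_c == 0:
        raise ValueError(f"no events in one arm (treated={ev_t}, control={ev_c})")
    if adjustment == "ps_adjusted":
        df["propensity_score"] = frame["propensity_score"].to_numpy(dtype=float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="duration", event_col="event")  # Efron ties
    row = cph.summary.loc["treated"]
    return HazardEstimate(
        label=label,
        hazard_ratio=float(row["exp(coef)"]),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        p_value=float(row["p"]),
        adjustment=adjustment,
        n_treated=int((df["treated"] == 1).sum()),
        n_control=int((df["treated"] == 0).sum()),
        n_events_treated=ev_t,
        n_events_control=ev_c,
    )


def km_curves(matched: MatchedTrialCohort) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimates per arm.

    Returns per arm a frame with ``timeline`` and ``survival`` columns.
    """
    frame = matched.frame if isinstance(matched, MatchedTrialCohort) else matched
    out: dict[str, pd.DataFrame] = {}
    for arm, grp in frame.groupby("arm"):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["follow_up_years"], grp["event"], label=arm)
        sf = kmf.survival_function_
        out[arm] = pd.DataFrame({"timeline": sf.index.to_numpy(),
                                 "survival": sf[arm].to_numpy()})
    return out


def plot_km(matched: MatchedTrialCohort, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = km_curves(matched)
    fig, ax = plt.subplots(figsize=(7, 5))
    for arm, sf in sorted(curves.items()):
        ax.step(sf["timeline"], sf["survival"], where="post", label=arm)
    ax.set_xlabel("years since index")
    ax.set_ylabel("outcome-free survival")
    ax.legend()
    ax.set_title("Product-limit survival by arm")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def incidence_rate(n_events: float, person_years: float) -> float:
    """Events per 1000 person-years."""
    if person_years <= 0:
        raise ValueError("person_years must be > 0")
    return 1000.0 * n_events / person_years


def incidence_table(matched: MatchedTrialCohort) -> pd.DataFrame:
    """Per-arm events, follow-up, time-to-event and incidence per 1000 PY."""
    rows = []
    for arm, grp in matched.frame.groupby("arm"):
        events = int(grp["event"].sum())
        py = float(grp["follow_up_years"].sum())
        tte = grp.loc[grp["event"] == 1, "follow_up_years"]
        rows.append({
            "arm": arm, "n": len(grp), "n_events": events,
            "pct_events": 100.0 * events / len(grp),
            "mean_follow_up_years": float(grp["follow_up_years"].mean()),
            "mean_time_to_event_years": float(tte.mean()) if len(tte) else np.nan,
            "person_years": py,
            "incidence_per_1000py": incidence_rate(events, py),
        })
    return pd.DataFrame(rows).sort_values("arm").reset_index(drop=True)


def subgroup_hazards(matched: MatchedTrialCohort,
                     subgroup_spec: Mapping[str, Iterable[str]],
                     ) -> tuple[list[HazardEstimate], dict[str, str]]:
    """Propensity-adjusted hazard ratios for initiator subgroups by drug.

    Each subgroup's initiators (by the drug of their qualifying fill) are
    compared against all matched non-initiators, with the propensity score
    as a Cox covariate (no re-matching).  Subgroups with fewer than two
    events are skipped and reported.
    """
    frame = matched.frame
    controls = frame[frame["arm"] == "non_initiator"]
    estimates: list[HazardEstimate] = []
    skipped: dict[str, str] = {}
    for label, drug_ids in subgroup_spec.items():
        sub_init = frame[(frame["arm"] == "initiator")
                         & frame["drug_id"].isin(set(drug_ids))]
        if sub_init.empty:
            skipped[label] = "empty subgroup"
            continue
        population = pd.concat([sub_init, controls], ignore_index=True)
        if int(sub_init["event"].sum()) < 2:
            skipped[label] = f"only {int(sub_init['event'].sum())} events in subgroup"
            continue
        estimates.append(_cox_arm_effect(population, "ps_adjusted",
                                         label=f"{label} vs non-initiators"))
    return estimates, skipped
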