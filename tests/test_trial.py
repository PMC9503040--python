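"""Target-trial engine: enrollment, propensity, matching, balance, hazards."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from mwasplus.codesets import COMORBIDITIES, DEFAULT_CODESETS
from mwasplus.presets import CLASS_TRIAL_YEARS, class_effect_config
from mwasplus.synthetic import generate_population
from mwasplus.trial import (
    MatchedTrialCohort,
    PropensityResult,
    enroll_sequential_trials,
    estimate_propensity,
    fit_itt_hazard,
    incidence_rate,
    incidence_table,
    km_curves,
    match_1to1,
    standardized_difference,
    subgroup_hazards,
    balance_report,
)

from conftest import build_dataset, yearly_visits

OUTCOME = DEFAULT_CODESETS["adrd_outcome"]
INDICATION = DEFAULT_CODESETS["hyperlipidemia"]
TRIAL_YEARS = [2002, 2003, 2004, 2005]


def _trial_dataset(extra_fills=(), extra_dx=()):
    # A: hyperlipidemia 2001, first statin 2003, no other scripts -> initiator 2003
    # B: hyperlipidemia 2000, other scripts every year -> non-initiator 2002
    # C: hyperlipidemia 2000, first statin 2002 -> initiator 2002
    pids = ["A", "B", "C"]
    enc = []
    for p in pids:
        enc += yearly_visits(p, 1999, 2016)
    dx = [
        {"patient_id": "A", "date": "2001-03-01", "code": "272.4",
         "code_system": "ICD9"},
        {"patient_id": "B", "date": "2000-03-01", "code": "272.4",
         "code_system": "ICD9"},
        {"patient_id": "C", "date": "2000-05-01", "code": "272.4",
         "code_system": "ICD9"},
    ] + list(extra_dx)
    fills = [
        {"patient_id": "A", "drug_id": "statin_a", "drug_class": "statin",
         "fill_date": "2003-04-02", "days_supply": 90},
        {"patient_id": "C", "drug_id": "statin_a", "drug_class": "statin",
         "fill_date": "2002-06-01", "days_supply": 90},
    ] + [
        {"patient_id": "B", "drug_id": "other", "fill_date": f"{y}-02-10",
         "days_supply": 30}
        for y in TRIAL_YEARS
    ] + list(extra_fills)
    return build_dataset(
        demographics=[{"patient_id": p, "birth_date": "1935-01-01"} for p in pids],
        encounters=enc, diagnoses=dx, fills=fills)


class TestEnrollment:
    def test_new_user_becomes_initiator_at_first_fill(self):
        ds = _trial_dataset()
        enr = enroll_sequential_trials(ds, INDICATION, "statin", TRIAL_YEARS,
                                       OUTCOME, seed=0)
        a = enr.frame[enr.frame["patient_id"] == "A"].iloc[0]
        assert a["arm"] == "initiator"
        assert a["trial_year"] == 2003
        assert a["index_date"] == pd.Timestamp("2003-04-02")
        assert a["drug_id"] == "statin_a"

    def test_prevalent_user_excluded_from_all_trials(self):
        ds = _trial_dataset(extra_fills=[
            {"patient_id": "B", "drug_id": "statin_a", "drug_class": "statin",
             "fill_date": "2001-05-01", "days_supply": 90}])
        enr = enroll_sequential_trials(ds, INDICATION, "statin", TRIAL_YEARS,
                                       OUTCOME, seed=0)
        assert "B" not in set(enr.frame["patient_id"])

    def test_non_initiator_anchored_at_nonclass_fill(self):
        ds = _trial_dataset()
        enr = enroll_sequential_trials(ds, INDICATION, "statin", TRIAL_YEARS,
                                       OUTCOME, seed=0)
        b = enr.frame[enr.frame["patient_id"] == "B"].iloc[0]
        assert b["arm"] == "non_initiator"
        assert b["trial_year"] == 2002
        assert b["index_date"] == pd.Timestamp("2002-02-10")

    def test_each_patient_enrolls_once(self):
        ds = _trial_dataset()
        enr = enroll_sequential_trials(ds, INDICATION, "statin", TRIAL_YEARS,
                                       OUTCOME, seed=0)
        assert enr.frame["patient_id"].is_unique

    def test_outcome_before_index_blocks_enrollment(self):
        ds = _trial_dataset(extra_dx=[
            {"patient_id": "A", "date": "2002-01-01", "code": "331.0",
             "code_system": "ICD9"}])
        enr = enroll_sequential_trials(ds, INDICATION, "statin", TRIAL_YEARS,
                                       OUTCOME, seed=0)
        assert "A" not in set(enr.frame["patient_id"])

    def test_no_initiators_anywhere_fatal(self):
        ds = _trial_dataset()
        with pytest.raises(ValueError, match="no initiators"):
            enroll_sequential_trials(ds, INDICATION, "no_such_class",
                                     TRIAL_YEARS, OUTCOME, seed=0)

    def test_enrollment_deterministic_under_seed(self, demo_population):
        ds, _ = demo_population
        kwargs = dict(indication_codeset=INDICATION, drug_class="statin",
                      trial_years=TRIAL_YEARS, outcome_codeset=OUTCOME,
                      comorbidity_codesets=COMORBIDITIES)
        a = enroll_sequential_trials(ds, seed=3, **kwargs)
        b = enroll_sequential_trials(ds, seed=3, **kwargs)
        pd.testing.assert_frame_equal(a.frame, b.frame)


def _enrollee_frame(n_per_arm, rng, covariates=None, logits=None):
    n = 2 * n_per_arm
    frame = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "arm": ["initiator"] * n_per_arm + ["non_initiator"] * n_per_arm,
        "trial_year": 2002,
        "index_date": pd.Timestamp("2002-06-01"),
        "drug_id": ["drug_x"] * n_per_arm + [None] * n_per_arm,
        "outcome_date": pd.NaT,
        "death_date": pd.NaT,
    })
    for name, values in (covariates or {}).items():
        frame[name] = values
    if logits is not None:
        frame["logit_ps"] = logits
        frame["propensity_score"] = 1 / (1 + np.exp(-np.asarray(logits)))
    return frame


def _ps_result(frame):
    return PropensityResult(frame=frame, coefficients=pd.DataFrame(),
                            converged=True, n_iterations=1, covariate_cols=[])


class TestPropensity:
    def test_no_signal_covariates_give_chance_auc(self):
        rng = np.random.default_rng(0)
        frame = _enrollee_frame(5000, rng, covariates={
            "x1": rng.normal(size=10000), "x2": rng.normal(size=10000),
            "x3": rng.random(10000) < 0.4})
        res = estimate_propensity(frame, ["x1", "x2", "x3"])
        treated = res.frame["arm"] == "initiator"
        scores = res.frame["propensity_score"]
        u = mannwhitneyu(scores[treated], scores[~treated]).statistic
        auc = u / (treated.sum() * (~treated).sum())
        assert abs(auc - 0.5) <= 0.02

    def test_known_log_odds_recovered_within_three_se(self):
        rng = np.random.default_rng(1)
        n = 20000
        x = (rng.random(n) < 0.5).astype(float)
        p = 1 / (1 + np.exp(-(-1.0 + 1.0 * x)))
        treated = rng.random(n) < p
        frame = pd.DataFrame({
            "arm": np.where(treated, "initiator", "non_initiator"), "x": x})
        res = estimate_propensity(frame, ["x"])
        coef = res.coefficients.loc["x", "coefficient"]
        se = res.coefficients.loc["x", "std_error"]
        assert abs(coef - 1.0) <= 3 * se

    def test_constant_covariate_error_names_it(self):
        rng = np.random.default_rng(2)
        frame = _enrollee_frame(50, rng, covariates={"flat": 1.0,
                                                     "ok": rng.normal(size=100)})
        with pytest.raises(ValueError, match="flat"):
            estimate_propensity(frame, ["flat", "ok"])


class TestMatching:
    def test_identical_score_lists_pair_perfectly(self):
        rng = np.random.default_rng(3)
        logits = np.concatenate([np.linspace(-1, 1, 200)] * 2)
        frame = _enrollee_frame(200, rng, logits=logits)
        matched = match_1to1(_ps_result(frame), study_end=pd.Timestamp("2016-12-31"),
                             seed=0)
        assert matched.n_pairs == 200
        assert matched.n_unmatched_initiators == 0
        diffs = matched.frame.groupby("pair_id")["logit_ps"].agg(np.ptp)
        assert diffs.max() == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_score_ranges_fatal(self):
        rng = np.random.default_rng(4)
        logits = np.concatenate([np.full(50, -5.0) + rng.normal(0, 0.01, 50),
                                 np.full(50, 5.0) + rng.normal(0, 0.01, 50)])
        frame = _enrollee_frame(50, rng, logits=logits)
        with pytest.raises(RuntimeError, match="zero pairs"):
            match_1to1(_ps_result(frame), study_end=pd.Timestamp("2016-12-31"),
                       seed=0)

    def test_caliper_respected_and_counts_add_up(self):
        rng = np.random.default_rng(5)
        logits = np.concatenate([rng.normal(0.3, 1.0, 600),
                                 rng.normal(-0.3, 1.0, 600)])
        frame = _enrollee_frame(600, rng, logits=logits)
        matched = match_1to1(_ps_result(frame), study_end=pd.Timestamp("2016-12-31"),
                             caliper_sd_multiplier=0.2, seed=1)
        diffs = matched.frame.groupby("pair_id")["logit_ps"].agg(np.ptp)
        assert (diffs <= matched.caliper + 1e-12).all()
        assert matched.n_pairs + matched.n_unmatched_initiators == 600
        controls = matched.frame[matched.frame["arm"] == "non_initiator"]
        assert controls["patient_id"].is_unique


class TestStandardizedDifference:
    def test_identical_summaries_are_balanced(self):
        assert standardized_difference((10.0, 2.0), (10.0, 2.0)) == 0.0
        assert standardized_difference(0.3, 0.3, kind="binary") == 0.0

    def test_zero_variance_unequal_means_is_infinite(self):
        assert standardized_difference((1.0, 0.0), (2.0, 0.0)) == np.inf

    def test_continuous_formula(self):
        # 100*|1.5| / sqrt((10.4^2+9.7^2)/2)
        asd = standardized_difference((65.1, 10.4), (66.6, 9.7))
        assert asd == pytest.approx(14.916, abs=1e-2)

    def test_binary_formula(self):
        asd = standardized_difference(0.037, 0.025, kind="binary")
        assert asd == pytest.approx(6.928, abs=1e-2)


class TestBalanceReport:
    def test_identity_matching_reproduces_pre_panel(self):
        rng = np.random.default_rng(6)
        logits = np.concatenate([np.linspace(-1, 1, 150)] * 2)
        frame = _enrollee_frame(150, rng, logits=logits, covariates={
            "age": rng.normal(70, 5, 300), "flag": (rng.random(300) < 0.3).astype(float)})
        matched = match_1to1(_ps_result(frame), study_end=pd.Timestamp("2016-12-31"),
                             seed=0)
        report = balance_report(frame, matched, ["age", "flag"])
        pre = report[report["phase"] == "pre_match"].set_index("covariate")
        post = report[report["phase"] == "post_match"].set_index("covariate")
        for cov in ("age", "flag"):
            assert pre.loc[cov, "asd"] == pytest.approx(post.loc[cov, "asd"])

    def test_absent_covariate_flagged_missing(self):
        rng = np.random.default_rng(7)
        logits = np.concatenate([np.linspace(-1, 1, 30)] * 2)
        frame = _enrollee_frame(30, rng, logits=logits,
                                covariates={"age": rng.normal(70, 5, 60)})
        matched = match_1to1(_ps_result(frame), study_end=pd.Timestamp("2016-12-31"),
                             seed=0)
        report = balance_report(frame, matched, ["age", "ghost"])
        ghost = report[report["covariate"] == "ghost"]
        assert ghost["missing"].all()


def _survival_frame(durations, events, treated, ps=0.5):
    n = len(durations)
    return pd.DataFrame({
        "follow_up_years": durations,
        "event": events,
        "arm": np.where(np.asarray(treated) == 1, "initiator", "non_initiator"),
        "propensity_score": ps,
        "drug_id": np.where(np.asarray(treated) == 1, "drug_x", None),
        "patient_id": [f"p{i}" for i in range(n)],
        "pair_id": np.arange(n),
    })


def _as_matched(frame):
    return MatchedTrialCohort(frame=frame, caliper=0.1, logit_sd=1.0,
                              n_unmatched_initiators=0)


class TestCoxHazard:
    def test_four_patient_fixture_matches_grid_search_oracle(self):
        durations = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 0]
        treated = [1, 0, 1, 0]
        matched = _as_matched(_survival_frame(durations, events, treated))
        est = fit_itt_hazard(matched, "unadjusted")

        def neg_log_partial_likelihood(beta):
            # no ties: Breslow/Efron coincide; risk sets by event time
            ll = 0.0
            for i in range(4):
                if events[i]:
                    risk = [j for j in range(4) if durations[j] >= durations[i]]
                    ll += beta * treated[i] - np.log(
                        sum(np.exp(beta * treated[j]) for j in risk))
            return -ll

        grid = np.arange(-3.0, 3.0, 1e-4)
        best = grid[np.argmin([neg_log_partial_likelihood(b) for b in grid])]
        assert np.log(est.hazard_ratio) == pytest.approx(best, abs=2e-3)

    def test_no_events_in_one_arm_fatal(self):
        matched = _as_matched(_survival_frame([1, 2, 3, 4], [0, 1, 0, 1],
                                              [1, 0, 1, 0]))
        with pytest.raises(ValueError, match="no events"):
            fit_itt_hazard(matched)

    def test_null_hazard_ci_coverage(self):
        rng = np.random.default_rng(8)
        covered = 0
        reps = 10
        for _ in range(reps):
            n = 3000
            durations = rng.exponential(10.0, n)
            censor = rng.uniform(5, 15, n)
            obs = np.minimum(durations, censor)
            events = (durations <= censor).astype(int)
            treated = (rng.random(n) < 0.5).astype(int)
            matched = _as_matched(_survival_frame(obs, events, treated))
            est = fit_itt_hazard(matched, "unadjusted")
            covered += est.ci_low <= 1.0 <= est.ci_high
        assert covered >= 8

    def test_ps_adjusted_reports_adjustment(self):
        rng = np.random.default_rng(9)
        n = 400
        matched = _as_matched(_survival_frame(
            rng.exponential(5, n), rng.random(n) < 0.7,
            (rng.random(n) < 0.5).astype(int), ps=rng.random(n)))
        est = fit_itt_hazard(matched, "ps_adjusted")
        assert est.adjustment == "ps_adjusted"
        assert est.ci_low <= est.hazard_ratio <= est.ci_high


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        matched = _as_matched(_survival_frame([1, 2, 3, 4], [0, 0, 0, 0],
                                              [1, 1, 0, 0]))
        for sf in km_curves(matched).values():
            assert (sf["survival"] == 1.0).all()

    def test_hand_product_limit(self):
        # events at t=1 and t=2, censoring at 1.5:
        # S(1) = 2/3, S(2) = (2/3)*(1 - 1/1) = 0
        matched = _as_matched(_survival_frame([1.0, 1.5, 2.0], [1, 0, 1],
                                              [1, 1, 1]))
        sf = km_curves(matched)["initiator"].set_index("timeline")["survival"]
        assert sf.loc[1.0] == pytest.approx(2 / 3)
        assert sf.loc[2.0] == pytest.approx(0.0)

    def test_exponential_survival_recovered(self):
        rng = np.random.default_rng(10)
        lam = 0.2
        n = 4000
        durations = rng.exponential(1 / lam, n)
        censor = np.full(n, 8.0)
        obs = np.minimum(durations, censor)
        events = (durations <= censor).astype(int)
        matched = _as_matched(_survival_frame(obs, events, np.ones(n, dtype=int)))
        sf = km_curves(matched)["initiator"]
        for t in (1.0, 3.0, 5.0):
            s_hat = sf.loc[sf["timeline"] <= t, "survival"].iloc[-1]
            assert s_hat == pytest.approx(np.exp(-lam * t), abs=0.03)


class TestIncidence:
    def test_rate_per_1000_person_years(self):
        assert incidence_rate(100, 10000) == 10.0

    def test_zero_events_zero_rate(self):
        assert incidence_rate(0, 123.4) == 0.0

    def test_nonpositive_person_years_fatal(self):
        with pytest.raises(ValueError):
            incidence_rate(5, 0.0)

    def test_incidence_table_consistent(self):
        rng = np.random.default_rng(11)
        n = 200
        matched = _as_matched(_survival_frame(
            rng.uniform(1, 10, n), (rng.random(n) < 0.3).astype(int),
            np.repeat([1, 0], n // 2)))
        table = incidence_table(matched)
        for _, row in table.iterrows():
            assert row["incidence_per_1000py"] == pytest.approx(
                1000 * row["n_events"] / row["person_years"])


class TestSubgroups:
    def test_whole_class_subgroup_equals_ps_adjusted_fit(self):
        rng = np.random.default_rng(12)
        n = 600
        matched = _as_matched(_survival_frame(
            rng.exponential(5, n), (rng.random(n) < 0.6).astype(int),
            np.repeat([1, 0], n // 2), ps=rng.random(n)))
        whole = fit_itt_hazard(matched, "ps_adjusted")
        subs, skipped = subgroup_hazards(matched, {"class": {"drug_x"}})
        assert not skipped
        assert subs[0].hazard_ratio == pytest.approx(whole.hazard_ratio)
        assert subs[0].p_value == pytest.approx(whole.p_value)

    def test_effect_carrying_member_has_lower_hr_than_class(self):
        rng = np.random.default_rng(13)
        n_each = 1500
        # two member drugs; only drug_a is protective (HR 0.6), controls HR 1
        dur_a = rng.exponential(1 / 0.06, n_each)
        dur_b = rng.exponential(1 / 0.10, n_each)
        dur_c = rng.exponential(1 / 0.10, 2 * n_each)
        durations = np.concatenate([dur_a, dur_b, dur_c])
        censor = 12.0
        obs = np.minimum(durations, censor)
        events = (durations <= censor).astype(int)
        treated = np.concatenate([np.ones(2 * n_each), np.zeros(2 * n_each)])
        frame = _survival_frame(obs, events, treated,
                                ps=rng.uniform(0.3, 0.7, 4 * n_each))
        frame.loc[:n_each - 1, "drug_id"] = "drug_a"
        frame.loc[n_each:2 * n_each - 1, "drug_id"] = "drug_b"
        matched = _as_matched(frame)
        subs, _ = subgroup_hazards(matched, {"a": {"drug_a"},
                                             "class": {"drug_a", "drug_b"}})
        by_label = {s.label.split(" ")[0]: s for s in subs}
        assert by_label["a"].hazard_ratio < by_label["class"].hazard_ratio

    def test_empty_subgroup_skipped(self):
        rng = np.random.default_rng(14)
        n = 100
        matched = _as_matched(_survival_frame(
            rng.exponential(5, n), (rng.random(n) < 0.5).astype(int),
            np.repeat([1, 0], n // 2), ps=0.5))
        subs, skipped = subgroup_hazards(matched, {"ghost": {"drug_zzz"}})
        assert not subs
        assert "ghost" in skipped
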