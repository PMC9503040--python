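"""Pipeline orchestration: configuration, end-to-end runs, and dossiers.

``run_pipeline`` executes simulate -> assemble-cohort -> mwas-scan ->
target-trial on one seed, writes every artifact (tables, figures, a
manifest capturing config/seed/version so a rerun is bitwise reproducible)
and renders a Markdown summary report.

The mechanistic-review stage between the scan and the trial is a human
step; ``make_dossier`` only emits a structured template pre-filled with
the scan numbers for a drug, and ``validate_dossier`` refuses an
``advance``/``reject`` decision whose expert free-text fields are empty.
The tool never advances a candidate on its own.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from mwasplus import __version__
from mwasplus.codesets import COMORBIDITIES, DEFAULT_CODESETS
from mwasplus.cohort import assemble_case_control
from mwasplus.data_model import CodeSet, EHRDataset, load_codesets, write_ehr_tables
from mwasplus.mwas import ScanResult, mwas_screen, render_heatmap
from mwasplus.presets import DEMO_TRIAL_YEARS, demo_config
from mwasplus.synthetic import DrugTruth, SimulationConfig, generate_population
from mwasplus.trial import (
    balance_report,
    enroll_sequential_trials,
    estimate_propensity,
    fit_itt_hazard,
    incidence_table,
    match_1to1,
    plot_km,
    subgroup_hazards,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """End-to-end run configuration (simulation plus analysis settings)."""

    simulation: SimulationConfig
    out_dir: Path
    seed: int
    alpha: float = 0.05
    window_years: float = 10.0
    ratio: int = 5
    age_tolerance_years: float = 2.0
    min_age: float = 65.0
    lookback_years: float = 10.0
    trial_years: tuple[int, ...] = DEMO_TRIAL_YEARS
    drug_class: str = "statin"
    indication: str = "hyperlipidemia"
    outcome: str = "adrd_outcome"
    exclusions: tuple[str, ...] = ("dementia_other_causes", "severe_psychiatric")
    caliper_sd_multiplier: float = 0.2
    codesets_file: Path | None = None

    def codesets(self) -> dict[str, CodeSet]:
        sets = dict(DEFAULT_CODESETS)
        if self.codesets_file is not None:
            if not Path(self.codesets_file).exists():
                raise FileNotFoundError(f"codesets file not found: {self.codesets_file}")
            sets.update(load_codesets(self.codesets_file))
        missing = [name for name in
                   (self.outcome, self.indication, *self.exclusions) if name not in sets]
        if missing:
            raise ValueError(f"unknown code set(s): {', '.join(missing)}")
        return sets


def simulation_config_to_dict(config: SimulationConfig) -> dict:
    out = dataclasses.asdict(config)
    out["study_start"] = str(pd.Timestamp(config.study_start).date())
    out["study_end"] = str(pd.Timestamp(config.study_end).date())
    out["drug_truths"] = [dataclasses.asdict(t) for t in config.drug_truths]
    return out


def simulation_config_from_dict(raw: Mapping[str, Any]) -> SimulationConfig:
    data = dict(raw)
    data["drug_truths"] = tuple(DrugTruth(**t) for t in data.get("drug_truths", ()))
    if "study_start" in data:
        data["study_start"] = pd.Timestamp(data["study_start"])
    if "study_end" in data:
        data["study_end"] = pd.Timestamp(data["study_end"])
    return SimulationConfig(**data)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return simulation_config_from_dict(yaml.safe_load(fh))


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run all stages; returns a result bundle and writes all artifacts.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    codesets = config.codesets()  # validate configuration before touching disk
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    timers: dict[str, float] = {}
    results: dict[str, Any] = {}

    def _stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                logger.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timers[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                logger.info("stage %s: done in %.1fs", name, timers[name])

        return _Timer()

    with _stage("simulate"):
        dataset, truth = generate_population(sim)
        data_dir = out / "data"
        write_ehr_tables(dataset, data_dir)
        truth.drugs.to_csv(out / "truth_drugs.csv", index=False)
        truth.patients.to_csv(out / "truth_patients.csv", index=False)
        results["dataset"] = dataset
        results["truth"] = truth

    with _stage("assemble-cohort"):
        cc = assemble_case_control(
            dataset, codesets[config.outcome],
            [codesets[name] for name in config.exclusions],
            ratio=config.ratio, age_tolerance_years=config.age_tolerance_years,
            min_age=config.min_age, lookback_years=config.lookback_years,
            seed=config.seed)
        cc.table.to_csv(out / "cohort.csv", index=False)
        results["case_control"] = cc

    with _stage("mwas-scan"):
        drug_list = [t.drug_id for t in sim.drug_truths]
        scan = mwas_screen(cc, dataset, drug_list, alpha=config.alpha,
                           window_years=config.window_years)
        scan.candidates.to_csv(out / "candidates.csv", index=False)
        scan.heatmap.to_csv(out / "heatmap.csv")
        render_heatmap(scan, out / "heatmap.png")
        with open(out / "scan_skipped.json", "w", encoding="utf-8") as fh:
            json.dump(scan.skipped, fh, indent=2)
        results["scan"] = scan

    with _stage("target-trial"):
        enrollees = enroll_sequential_trials(
            dataset, codesets[config.indication], config.drug_class,
            config.trial_years, codesets[config.outcome], seed=config.seed,
            comorbidity_codesets={k: codesets[k] for k in COMORBIDITIES})
        ps = estimate_propensity(enrollees)
        matched = match_1to1(ps, study_end=sim.study_end,
                             caliper_sd_multiplier=config.caliper_sd_multiplier,
                             seed=config.seed)
        balance = balance_report(enrollees, matched)
        hazards = [fit_itt_hazard(matched, "unadjusted"),
                   fit_itt_hazard(matched, "ps_adjusted")]
        class_drugs = sorted({t.drug_id for t in sim.drug_truths
                              if t.drug_class == config.drug_class})
        subgroups, sub_skipped = subgroup_hazards(
            matched, {d: {d} for d in class_drugs})
        incidence = incidence_table(matched)

        enrollees.frame.to_csv(out / "enrollees.csv", index=False)
        matched.frame.to_csv(out / "pairs.csv", index=False)
        balance.to_csv(out / "balance_pre_post.csv", index=False)
        hazards_df = pd.DataFrame([dataclasses.asdict(h) for h in hazards + subgroups])
        hazards_df.to_csv(out / "hazards.csv", index=False)
        incidence.to_csv(out / "events_incidence.csv", index=False)
        plot_km(matched, out / "km.png")
        results.update(enrollees=enrollees, propensity=ps, matched=matched,
                       balance=balance, hazards=hazards, subgroups=subgroups,
                       incidence=incidence, subgroups_skipped=sub_skipped)

    with _stage("report"):
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "simulation_config": simulation_config_to_dict(sim),
            "analysis": {
                "alpha": config.alpha, "window_years": config.window_years,
                "ratio": config.ratio,
                "age_tolerance_years": config.age_tolerance_years,
                "min_age": config.min_age, "lookback_years": config.lookback_years,
                "trial_years": list(config.trial_years),
                "drug_class": config.drug_class, "indication": config.indication,
                "outcome": config.outcome, "exclusions": list(config.exclusions),
                "caliper_sd_multiplier": config.caliper_sd_multiplier,
            },
            "timers_seconds": timers,
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        _write_report(out, results)
        results["manifest"] = manifest

    return results


def _write_report(out: Path, results: dict[str, Any]) -> None:
    scan: ScanResult = results["scan"]
    cc = results["case_control"]
    lines = [
        "# Screening run summary", "",
        f"Matched case-control cohort: {cc.n_sets} sets "
        f"(1:{cc.ratio}, {len(cc.table)} patients); "
        f"{len(cc.dropped_cases)} cases dropped for lack of matches.", "",
        "## Medication-wide scan", "",
        f"Bonferroni-corrected per-drug alpha: {scan.threshold:.6g} "
        f"(family alpha {scan.alpha}, {len(scan.candidates) + len(scan.skipped)} drugs).", "",
    ]
    candidates = scan.candidates[scan.candidates["candidate"]]
    if candidates.empty:
        lines.append("No drug cleared the threshold.")
    else:
        lines.append(candidates.to_markdown(index=False))
    if scan.skipped:
        lines += ["", "Skipped drugs: "
                  + "; ".join(f"{k} ({v})" for k, v in sorted(scan.skipped.items()))]
    lines += ["", "![decile heatmap](heatmap.png)", "",
              "## Target-trial emulation", ""]
    matched = results["matched"]
    lines.append(
        f"Matched pairs: {matched.n_pairs} "
        f"(caliper {matched.caliper:.4f} on logit propensity; "
        f"{matched.n_unmatched_initiators} initiators unmatched).")
    lines += ["", "### Hazard ratios", ""]
    hz = pd.DataFrame([dataclasses.asdict(h)
                       for h in results["hazards"] + results["subgroups"]])
    lines.append(hz.to_markdown(index=False))
    lines += ["", "### Incidence", "", results["incidence"].to_markdown(index=False),
              "", "![survival](km.png)", ""]
    post = results["balance"]
    post = post[(post["phase"] == "post_match") & ~post["missing"]]
    lines += [f"Worst post-match standardized difference: "
              f"{post['asd'].max():.1f}%.", ""]
    (out / "report.md").write_text("\n".join(lines), encoding="utf-8")


DOSSIER_DECISIONS = ("advance", "hold", "reject")
_DOSSIER_TEXT_FIELDS = ("mechanism", "observational_evidence", "rct_evidence")


def make_dossier(scan: ScanResult, drug_id: str) -> dict[str, Any]:
    """Structured mechanistic-review template pre-filled with scan numbers.

    The expert free-text fields start empty and ``decision`` starts at
    ``hold``; see :func:`validate_dossier`.
    """
    if drug_id in scan.skipped:
        raise KeyError(f"drug {drug_id!r} was skipped in the scan: {scan.skipped[drug_id]}")
    if drug_id not in scan.tables:
        raise KeyError(f"drug {drug_id!r} not in scan output")
    table = scan.tables[drug_id]
    row = scan.candidates.set_index("drug_id").loc[drug_id]
    return {
        "drug_id": drug_id,
        "step1": {
            "overall_or": float(table.overall_or),
            "overall_ci": [float(table.overall_ci[0]), float(table.overall_ci[1])],
            "overall_p": float(table.overall_p),
            "decile_or": [float(x) for x in table.deciles["odds_ratio"]],
            "candidate": bool(row["candidate"]),
            "below_threshold": not bool(row["candidate"]),
            "bonferroni_threshold": float(scan.threshold),
        },
        "mechanism": "",
        "observational_evidence": "",
        "rct_evidence": "",
        "decision": "hold",
    }


def validate_dossier(dossier: Mapping[str, Any]) -> None:
    """Enforce dossier rules: a decision needs completed expert fields."""
    decision = dossier.get("decision")
    if decision not in DOSSIER_DECISIONS:
        raise ValueError(f"decision must be one of {DOSSIER_DECISIONS}")
    if decision != "hold":
        empty = [f for f in _DOSSIER_TEXT_FIELDS if not str(dossier.get(f, "")).strip()]
        if empty:
            raise ValueError(
                f"decision {decision!r} requires non-empty field(s): {', '.join(empty)}")
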