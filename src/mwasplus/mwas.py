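"""Medication-wide association scan: cumulative dose, deciles, odds ratios.

For each drug, cumulative exposure is summed as dose-days over the ten
years before each subject's index date, users are cut into deciles of the
pooled user-only dose distribution, and each decile is contrasted against
non-users in an unadjusted 2x2 odds ratio with a Woolf (log-OR) confidence
interval.  A drug is a screening candidate when its overall treated-vs-
non-treated p-value clears the Bonferroni-corrected threshold
``alpha / n_drugs``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mwasplus.data_model import DAYS_PER_YEAR, EHRDataset
from mwasplus.cohort import CaseControlSet

logger = logging.getLogger(__name__)

N_DECILES = 10


class DrugSkipped(RuntimeError):
    """A drug that cannot be scanned (too few users, empty reference cell)."""


@dataclass
class DecileORTable:
    """Per-decile odds ratios for one drug against the non-user reference.

    ``deciles`` has one row per decile (1..10) with case/control counts,
    OR, Woolf 95% CI, two-sided p, and a flag where the Haldane-Anscombe
    +0.5 correction was applied.  ``overall_*`` pools all users.
    """

    drug_id: str
    deciles: pd.DataFrame
    n_cases_nonuser: int
    n_controls_nonuser: int
    overall_or: float
    overall_ci: tuple[float, float]
    overall_p: float
    degenerate: bool = False

    def heatmap_row(self) -> np.ndarray:
        """Non-user reference (OR=1) followed by the ten decile ORs."""
        return np.concatenate([[1.0], self.deciles["odds_ratio"].to_numpy()])


def cumulative_dose(fills: pd.DataFrame, drug_id: str, index_date: pd.Timestamp,
                    window_years: float = 10.0) -> float:
    """Cumulative dose-days of one drug for one patient's fills.

    Sums ``days_supply * daily_dose`` (dose defaulting to 1 when absent)
    over the fill days overlapping the closed window
    ``[index - window_years*365, index]``; fills straddling either window
    edge contribute only their in-window days.
    """
    sub = fills[fills["drug_id"] == drug_id]
    if sub.empty:
        return 0.0
    doses = _overlap_dose_days(sub, pd.Timestamp(index_date), window_years)
    return float(doses.sum())


def _overlap_dose_days(fills: pd.DataFrame, index_date, window_years: float) -> np.ndarray:
    window_days = int(round(window_years * DAYS_PER_YEAR))
    fill_start = fills["fill_date"].to_numpy()
    supply = fills["days_supply"].to_numpy()
    fill_end = fill_start + (supply - 1).astype("timedelta64[D]")
    index = np.asarray(index_date, dtype="datetime64[ns]")
    win_start = index - np.timedelta64(window_days, "D")
    lo = np.maximum(fill_start, win_start)
    hi = np.minimum(fill_end, index)
    days = ((hi - lo) / np.timedelta64(1, "D")).astype(np.int64) + 1
    days = np.clip(days, 0, None)
    dose = fills["daily_dose"].to_numpy(dtype=float)
    dose = np.where(np.isfinite(dose), dose, 1.0)
    return days * dose


def cumulative_doses(fills: pd.DataFrame, cohort: pd.DataFrame, drug_id: str,
                     window_years: float = 10.0) -> pd.Series:
    """Vectorized per-patient cumulative dose-days over the cohort table.

    ``cohort`` must carry ``patient_id`` and ``index_date``; the result is
    indexed by patient_id with 0.0 for patients without qualifying fills.
    """
    sub = fills[fills["drug_id"] == drug_id]
    index_dates = cohort.set_index("patient_id")["index_date"]
    sub = sub[sub["patient_id"].isin(index_dates.index)]
    if sub.empty:
        return pd.Series(0.0, index=index_dates.index, name="cumulative_dose")
    idx = index_dates.reindex(sub["patient_id"]).to_numpy()
    doses = _overlap_dose_days(sub, idx, window_years)
    per_patient = pd.Series(doses).groupby(sub["patient_id"].to_numpy()).sum()
    return per_patient.reindex(index_dates.index, fill_value=0.0).rename("cumulative_dose")


def assign_deciles(doses: pd.Series) -> tuple[pd.Series, bool]:
    """Decile labels (1-10) for users; non-users (dose 0) get <NA>.

    Cut points are the 10-quantiles of the user-only dose distribution
    pooled over cases and controls; a dose tied with a cut point falls in
    the lower decile.  Returns ``(labels, degenerate)`` where ``degenerate``
    marks a collapsed dose distribution (non-increasing cut points).

    Raises
    ------
    DrugSkipped
        if there are fewer than 10 users.
    """
    users = doses[doses > 0]
    if len(users) < N_DECILES:
        raise DrugSkipped(f"only {len(users)} users (<{N_DECILES})")
    cuts = np.quantile(users.to_numpy(), np.arange(1, N_DECILES) / N_DECILES)
    labels = pd.Series(pd.NA, index=doses.index, dtype="Int64")
    user_labels = 1 + np.searchsorted(cuts, users.to_numpy(), side="left")
    labels[users.index] = user_labels
    degenerate = int(pd.unique(user_labels).size) == 1
    return labels, degenerate


def _or_2x2(a: float, b: float, a0: float, b0: float) -> dict:
    """Odds ratio with Woolf CI and z-test p for the table [[a,b],[a0,b0]].

    Applies the Haldane-Anscombe +0.5 to all four cells iff any cell is 0.
    """
    corrected = min(a, b, a0, b0) == 0
    if corrected:
        a, b, a0, b0 = a + 0.5, b + 0.5, a0 + 0.5, b0 + 0.5
    or_ = (a * b0) / (b * a0)
    se = np.sqrt(1 / a + 1 / b + 1 / a0 + 1 / b0)
    z = np.log(or_) / se
    return {
        "odds_ratio": or_,
        "ci_low": float(np.exp(np.log(or_) - 1.959963984540054 * se)),
        "ci_high": float(np.exp(np.log(or_) + 1.959963984540054 * se)),
        "p_value": float(2 * stats.norm.sf(abs(z))),
        "zero_cell_corrected": corrected,
    }


def decile_odds_ratios(case_control: CaseControlSet | pd.DataFrame,
                       exposures: pd.Series, drug_id: str = "") -> DecileORTable:
    """Per-decile and overall odds ratios vs non-users for one drug.

    ``exposures`` is the per-patient cumulative dose over the case-control
    membership (see :func:`cumulative_doses`).

    Raises
    ------
    DrugSkipped
        if there is no case or no control among non-users, or <10 users.
    """
    table = case_control.table if isinstance(case_control, CaseControlSet) else case_control
    is_case = table.set_index("patient_id")["is_case"]
    exposures = exposures.reindex(is_case.index)
    labels, degenerate = assign_deciles(exposures)

    nonuser = exposures == 0
    a0 = int((is_case & nonuser).sum())
    b0 = int((~is_case & nonuser).sum())
    if a0 == 0 or b0 == 0:
        raise DrugSkipped(f"empty non-user reference cell (cases={a0}, controls={b0})")

    rows = []
    for d in range(1, N_DECILES + 1):
        in_d = labels == d
        a = int((is_case & in_d).sum())
        b = int((~is_case & in_d).sum())
        rows.append({"decile": d, "n_cases": a, "n_controls": b,
                     **_or_2x2(a, b, a0, b0)})
    deciles = pd.DataFrame(rows)

    a_all = int((is_case & ~nonuser).sum())
    b_all = int((~is_case & ~nonuser).sum())
    overall = _or_2x2(a_all, b_all, a0, b0)
    return DecileORTable(
        drug_id=drug_id, deciles=deciles,
        n_cases_nonuser=a0, n_controls_nonuser=b0,
        overall_or=float(overall["odds_ratio"]),
        overall_ci=(overall["ci_low"], overall["ci_high"]),
        overall_p=overall["p_value"],
        degenerate=degenerate,
    )


def bonferroni_threshold(alpha: float, n_drugs: int) -> float:
    """Per-drug significance threshold ``alpha / n_drugs``."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0,1)")
    if n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    return alpha / n_drugs


@dataclass
class ScanResult:
    """Medication-wide scan output.

    ``candidates`` is sorted by overall OR ascending (strongest apparent
    protection first) and flags drugs clearing the Bonferroni threshold;
    ``heatmap`` is the drugs x (non-user + 10 deciles) OR matrix;
    ``skipped`` maps drug -> reason for drugs that could not be scanned.
    """

    candidates: pd.DataFrame
    heatmap: pd.DataFrame
    tables: dict[str, DecileORTable]
    skipped: dict[str, str]
    alpha: float
    threshold: float


def mwas_screen(case_control: CaseControlSet, dataset: EHRDataset,
                drug_list: list[str], alpha: float = 0.05,
                window_years: float = 10.0) -> ScanResult:
    """Scan every drug in ``drug_list`` against the matched cohort.

    Per-drug failures (too few users, empty reference) are recorded in
    ``skipped`` and never abort the scan.  Output is invariant to the
    order of ``drug_list``.
    """
    if not drug_list:
        raise ValueError("drug_list must be non-empty")
    threshold = bonferroni_threshold(alpha, len(drug_list))
    members = case_control.table[["patient_id", "index_date"]]
    fills = dataset.fills[dataset.fills["patient_id"].isin(set(members["patient_id"]))]

    tables: dict[str, DecileORTable] = {}
    skipped: dict[str, str] = {}
    for drug in sorted(set(drug_list)):
        doses = cumulative_doses(fills, members, drug, window_years=window_years)
        try:
            tables[drug] = decile_odds_ratios(case_control, doses, drug_id=drug)
        except DrugSkipped as exc:
            skipped[drug] = str(exc)
            logger.info("drug %s skipped: %s", drug, exc)

    rows = []
    for drug, tab in tables.items():
        rows.append({
            "drug_id": drug,
            "overall_or": tab.overall_or,
            "ci_low": tab.overall_ci[0],
            "ci_high": tab.overall_ci[1],
            "p_value": tab.overall_p,
            "candidate": tab.overall_p < threshold,
            "degenerate_doses": tab.degenerate,
        })
    candidates = pd.DataFrame(rows, columns=[
        "drug_id", "overall_or", "ci_low", "ci_high", "p_value",
        "candidate", "degenerate_doses"])
    candidates = candidates.sort_values(
        ["overall_or", "drug_id"], kind="mergesort").reset_index(drop=True)

    heatmap = pd.DataFrame(
        [tables[d].heatmap_row() for d in candidates["drug_id"]],
        index=candidates["drug_id"],
        columns=["nonuser"] + [f"decile_{d}" for d in range(1, N_DECILES + 1)],
    )
    return ScanResult(candidates=candidates, heatmap=heatmap, tables=tables,
                      skipped=skipped, alpha=alpha, threshold=threshold)


def render_heatmap(scan: ScanResult, path) -> None:
    """Render the decile-OR heatmap (log2 color scale centered at OR=1)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = np.log2(scan.heatmap.to_numpy())
    fig, ax = plt.subplots(figsize=(8, max(2, 0.4 * len(scan.heatmap))))
    lim = max(0.5, np.nanmax(np.abs(data)))
    im = ax.imshow(data, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
    ax.set_xticks(range(scan.heatmap.shape[1]),
                  labels=list(scan.heatmap.columns), rotation=45, ha="right")
    ax.set_yticks(range(len(scan.heatmap)), labels=list(scan.heatmap.index))
    fig.colorbar(im, ax=ax, label="log2 odds ratio vs non-users")
    ax.set_title("Cumulative-dose deciles vs incident outcome")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
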