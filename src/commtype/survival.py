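"""Incident-disease screening with Cox proportional-hazards models.

Per disease: exclude subjects who already had the diagnosis at baseline, fit
a Cox model of time-to-first-diagnosis on cluster membership plus baseline
covariates (age, BMI, gender, Bristol stool score), test the cluster term
globally by likelihood ratio against the covariate-only model, check the
proportional-hazards assumption via scaled Schoenfeld residuals, and correct
across the disease panel with Benjamini-Hochberg FDR.  Ties are handled by
Efron's method (the lifelines default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from .association import bh_fdr

__all__ = [
    "SurvivalResult",
    "exclude_prevalent",
    "cox_incident",
    "ph_test",
    "screen_incident",
]

log = logging.getLogger(__name__)


@dataclass
class SurvivalResult:
    disease_id: str
    representation: str
    n_at_risk: int
    n_events: int
    hazard_ratios: dict[str, float] = field(default_factory=dict)
    ci_lower: dict[str, float] = field(default_factory=dict)
    ci_upper: dict[str, float] = field(default_factory=dict)
    global_statistic: Optional[float] = None
    global_df: Optional[int] = None
    global_p: Optional[float] = None
    q_value: Optional[float] = None
    ph_term_p: dict[str, float] = field(default_factory=dict)
    ph_global_p: Optional[float] = None
    reason: Optional[str] = None
    flags: list[str] = field(default_factory=list)
    fitter: Optional[CoxPHFitter] = None
    fit_frame: Optional[pd.DataFrame] = None


def exclude_prevalent(
    incident_table: pd.DataFrame,
    prevalent_table: pd.DataFrame,
    disease_id: str,
) -> pd.DataFrame:
    """Drop follow-up rows for subjects with a prevalent record of the disease.

    ``incident_table`` must hold rows for one disease (or be pre-filtered by
    ``disease_id``); prevalent carriers are matched on ``sample_id`` against
    prevalent records whose ICD-10 category equals ``disease_id``.
    """
    rows = incident_table[incident_table["disease_id"] == disease_id]
    prev_ids = set(
        prevalent_table.loc[prevalent_table["icd10"] == disease_id, "sample_id"]
        .astype(str)
    )
    kept = rows[~rows["sample_id"].astype(str).isin(prev_ids)]
    n_removed = len(rows) - len(kept)
    if n_removed:
        log.info("disease %s: excluded %d prevalent subjects", disease_id, n_removed)
    return kept.reset_index(drop=True)


def _cluster_design(labels: pd.Series) -> tuple[pd.DataFrame, list[str]]:
    counts = labels.value_counts()
    reference = counts.index[0]
    levels = [lv for lv in sorted(counts.index) if lv != reference]
    cols = pd.DataFrame(index=labels.index)
    for lv in levels:
        cols[f"cluster_{lv}"] = (labels == lv).astype(float)
    return cols, [f"cluster_{lv}" for lv in levels]


def cox_incident(
    cohort: pd.DataFrame,
    cluster_labels: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    representation_name: str = "CT",
    run_ph_test: bool = True,
) -> SurvivalResult:
    """Cox PH fit of one incident disease on cluster membership.

    ``cohort`` needs columns ``sample_id``, ``disease_id``, ``time_years``,
    ``event``.  Cluster labels enter as indicator contrasts against the
    largest cluster; a numeric gradient enters as a single column.  The
    headline p-value is the likelihood-ratio test of the cluster term versus
    the covariate-only model.
    """
    disease_id = str(cohort["disease_id"].iloc[0]) if len(cohort) else "unknown"
    ids = cohort["sample_id"].astype(str)
    frame = pd.DataFrame(
        {
            "time": cohort["time_years"].to_numpy(dtype=float),
            "event": cohort["event"].to_numpy(dtype=int),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    labels = cluster_labels.reindex(frame.index)
    from .association import _is_cluster_representation

    if not _is_cluster_representation(labels.dropna()):
        rep_cols = pd.DataFrame({"gradient": labels.astype(float)}, index=frame.index)
        term_names = ["gradient"]
    else:
        rep_cols, term_names = _cluster_design(labels)
    frame = frame.join(rep_cols)
    if covariates is not None:
        frame = frame.join(covariates.astype(float))
    frame = frame.dropna()

    res = SurvivalResult(
        disease_id=disease_id,
        representation=representation_name,
        n_at_risk=len(frame),
        n_events=int(frame["event"].sum()),
    )
    if res.n_at_risk == 0:
        res.reason = "empty cohort after prevalent-case exclusion"
        return res
    if res.n_events == 0:
        res.reason = "no events observed"
        return res
    if not term_names:
        res.global_statistic, res.global_df, res.global_p = 0.0, 1, 1.0
        res.reason = "cluster labels constant"
        return res

    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time", event_col="event")
    except Exception as exc:
        res.reason = f"fit failed: {exc}"
        return res
    if covariates is not None and len(covariates.columns):
        reduced_frame = frame.drop(columns=term_names)
        red = CoxPHFitter()
        try:
            red.fit(reduced_frame, duration_col="time", event_col="event")
            ll_reduced = red.log_likelihood_
        except Exception as exc:  # pragma: no cover
            res.reason = f"reduced fit failed: {exc}"
            return res
    else:
        # no covariates: the reduced model is the null partial likelihood,
        # recovered from lifelines' own likelihood-ratio test
        lrt = cph.log_likelihood_ratio_test()
        ll_reduced = cph.log_likelihood_ - lrt.test_statistic / 2.0
    stat = max(2.0 * (cph.log_likelihood_ - ll_reduced), 0.0)
    df = len(term_names)
    res.global_statistic = float(stat)
    res.global_df = df
    res.global_p = float(stats.chi2.sf(stat, df))

    summ = cph.summary
    for term in term_names:
        res.hazard_ratios[term] = float(np.exp(summ.loc[term, "coef"]))
        res.ci_lower[term] = float(np.exp(summ.loc[term, "coef lower 95%"]))
        res.ci_upper[term] = float(np.exp(summ.loc[term, "coef upper 95%"]))
    res.fitter = cph
    res.fit_frame = frame

    if run_ph_test and res.n_events >= 2:
        try:
            term_p, global_p = ph_test(res)
            res.ph_term_p = term_p
            res.ph_global_p = global_p
        except Exception as exc:
            res.flags.append(f"ph_test_failed: {exc}")
    return res


def ph_test(result: SurvivalResult, time_transform: str = "km"):
    """Proportional-hazards check via scaled Schoenfeld residuals.

    Correlates each term's scaled Schoenfeld residuals with the transformed
    event times (Kaplan-Meier transform by default) and reports per-term
    chi-squared p-values plus a global statistic formed by summing the
    per-term chi-squared contributions (an approximation that treats terms
    as weakly correlated).
    """
    if result.fitter is None or result.fit_frame is None:
        raise ValueError("ph_test needs a converged Cox fit")
    if result.n_events < 2:
        raise ValueError("too few events for a PH test")
    test = proportional_hazard_test(
        result.fitter, result.fit_frame, time_transform=time_transform
    )
    summ = test.summary
    term_p = {str(idx[0] if isinstance(idx, tuple) else idx): float(row["p"])
              for idx, row in summ.iterrows()}
    total_stat = float(summ["test_statistic"].sum())
    total_df = len(summ)
    global_p = float(stats.chi2.sf(total_stat, total_df))
    return term_p, global_p


def screen_incident(
    incident_table: pd.DataFrame,
    prevalent_table: pd.DataFrame,
    representations: dict[str, pd.Series],
    covariates: Optional[pd.DataFrame] = None,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Cox screen across the incident-disease panel.

    One row per disease x representation; BH-FDR is applied across diseases
    within each representation family.  Per-disease failures are recorded in
    the ``reason`` column rather than raised.
    """
    diseases = sorted(incident_table["disease_id"].unique())
    rows = []
    results: dict[tuple[str, str], SurvivalResult] = {}
    for rep_name, labels in representations.items():
        for disease in diseases:
            cohort = exclude_prevalent(incident_table, prevalent_table, disease)
            res = cox_incident(cohort, labels, covariates, rep_name)
            results[(rep_name, disease)] = res
    for rep_name in representations:
        ps = [results[(rep_name, d)].global_p for d in diseases]
        qs = bh_fdr([np.nan if p is None else p for p in ps])
        for d, q in zip(diseases, qs):
            results[(rep_name, d)].q_value = None if np.isnan(q) else float(q)
    for (rep_name, disease), res in results.items():
        rows.append(
            {
                "disease_id": disease,
                "representation": rep_name,
                "n_at_risk": res.n_at_risk,
                "n_events": res.n_events,
                "global_statistic": res.global_statistic,
                "global_df": res.global_df,
                "global_p": res.global_p,
                "q_value": res.q_value,
                "ph_global_p": res.ph_global_p,
                "significant_fdr": (
                    res.q_value is not None and res.q_value <= fdr_threshold
                ),
                "reason": res.reason,
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["representation", "disease_id"]
    ).reset_index(drop=True)
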