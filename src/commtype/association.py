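"""Phenotype-community association testing.

For each phenotype factor and each community representation (discrete cluster
labels or the continuous Prevotella/Bacteroides gradient) the factor is
regressed on the representation: logistic regression for binary factors,
ordinary least squares for continuous/ordinal ones, with a likelihood-ratio
test of the representation term against the covariate-only (or
intercept-only) null.  Categorical factors use a Pearson chi-squared test
against the cluster composition.  Families of tests are corrected by
Benjamini-Hochberg FDR.  Covariate-adjusted disease models, a post-hoc
drug-confounding scan, and an AIC-based comparison of cluster vs gradient
representations complete the screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssociationResult",
    "RepresentationComparison",
    "ConfoundingReport",
    "ScreenSummary",
    "associate_factor",
    "bh_fdr",
    "screen_factors",
    "adjusted_disease_test",
    "drug_confounding_scan",
    "compare_representations",
    "subdiagnosis_test",
]

log = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    factor_name: str
    representation: str  # e.g. "ET", "CT", "gradient"
    test: str  # logistic_LRT | linear_LRT | chi_squared
    statistic: Optional[float]
    df: Optional[int]
    p_value: Optional[float]
    q_value: Optional[float] = None
    per_cluster_summary: Optional[dict] = None
    adjusted: bool = False
    covariates: list[str] = field(default_factory=list)
    n_used: int = 0
    reason: Optional[str] = None
    flags: list[str] = field(default_factory=list)


@dataclass
class RepresentationComparison:
    factor_name: str
    aic_ET: Optional[float]
    aic_CT: Optional[float]
    aic_gradient: Optional[float]
    best: Optional[str]
    partial: bool = False


@dataclass
class ConfoundingReport:
    disease: str
    representation: str
    baseline_p: float
    confounded: bool
    confounding_drugs: dict[str, float] = field(default_factory=dict)
    skipped_drugs: dict[str, str] = field(default_factory=dict)


@dataclass
class ScreenSummary:
    results: list[AssociationResult]
    fdr_significant: dict[str, set]
    nominal_significant: dict[str, set]
    shared_fdr: set
    specific_fdr: dict[str, set]


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def _is_cluster_representation(values: pd.Series | np.ndarray) -> bool:
    arr = np.asarray(values)
    if arr.dtype.kind in "OUS":
        return True
    uniq = np.unique(arr[~pd.isna(arr)])
    return len(uniq) <= 12 and np.allclose(uniq, np.round(uniq))


def _representation_design(values: pd.Series) -> tuple[pd.DataFrame, int, str]:
    """Encode a representation as regression columns.

    Cluster labels become dummy indicators with the largest cluster as the
    reference level; a continuous gradient stays a single numeric column.
    Returns (columns, df of the term, kind).
    """
    if _is_cluster_representation(values):
        counts = values.value_counts()
        reference = counts.index[0]  # largest cluster
        levels = [lv for lv in sorted(counts.index) if lv != reference]
        cols = pd.DataFrame(index=values.index)
        for lv in levels:
            cols[f"cluster_{lv}"] = (values == lv).astype(float)
        return cols, len(levels), "cluster"
    cols = pd.DataFrame({"gradient": pd.to_numeric(values)}, index=values.index)
    return cols, 1, "gradient"


def _fit_glm(y: pd.Series, X: pd.DataFrame, binary: bool):
    Xc = sm.add_constant(X, has_constant="add")
    if binary:
        model = sm.GLM(y, Xc, family=sm.families.Binomial())
    else:
        model = sm.OLS(y, Xc)
    return model.fit()


def _loglik_lrt(y, X_full, X_reduced, binary):
    full = _fit_glm(y, X_full, binary)
    red = _fit_glm(y, X_reduced, binary)
    stat = 2.0 * (full.llf - red.llf)
    return max(float(stat), 0.0), full, red


def _per_cluster_summary(factor: pd.Series, kind: str, values: pd.Series):
    if not _is_cluster_representation(values):
        return None
    out = {}
    for lv, sub in factor.groupby(values):
        sub = sub.dropna()
        if kind in ("binary",):
            out[lv] = float(sub.mean()) if len(sub) else np.nan  # proportion
        elif kind in ("continuous", "ordinal"):
            out[lv] = float(sub.mean()) if len(sub) else np.nan
        else:
            out[lv] = sub.value_counts(normalize=True).to_dict()
    return out


# ---------------------------------------------------------------------------
# core tests
# ---------------------------------------------------------------------------

def associate_factor(
    factor: pd.Series,
    kind: str,
    representation_values: pd.Series,
    representation_name: str = "CT",
    covariates: Optional[pd.DataFrame] = None,
) -> AssociationResult:
    """Test one factor against one community representation.

    Binary factors: logistic regression of the factor on the representation
    (plus covariates when given), with a likelihood-ratio test against the
    model without the representation term.  Continuous and ordinal factors:
    the same with OLS.  Categorical factors: Pearson chi-squared of the
    factor x cluster contingency table (no covariates supported).
    Complete-case rows only.
    """
    name = factor.name if factor.name is not None else "factor"
    frame = pd.DataFrame({"y": factor, "rep": representation_values})
    if covariates is not None:
        if kind == "categorical":
            raise ValueError("chi-squared test does not support covariates")
        frame = frame.join(covariates.astype(float))
    frame = frame.dropna()
    n_used = len(frame)
    summary = _per_cluster_summary(frame["y"], kind, frame["rep"])

    base = AssociationResult(
        factor_name=str(name),
        representation=representation_name,
        test="",
        statistic=None,
        df=None,
        p_value=None,
        per_cluster_summary=summary,
        adjusted=covariates is not None,
        covariates=[] if covariates is None else list(covariates.columns),
        n_used=n_used,
    )

    if frame["y"].nunique() < 2:
        base.test = "chi_squared" if kind == "categorical" else (
            "logistic_LRT" if kind == "binary" else "linear_LRT")
        base.reason = "factor constant in complete cases"
        return base

    if kind == "categorical":
        tab = pd.crosstab(frame["y"], frame["rep"])
        base.test = "chi_squared"
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            base.reason = "degenerate contingency table"
            return base
        stat, p, df, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
        base.statistic, base.p_value, base.df = float(stat), float(p), int(df)
        return base

    rep_cols, rep_df, _ = _representation_design(frame["rep"])
    cov_cols = frame.drop(columns=["y", "rep"])
    X_full = pd.concat([cov_cols, rep_cols], axis=1)
    X_reduced = cov_cols
    binary = kind == "binary"
    base.test = "logistic_LRT" if binary else "linear_LRT"
    if rep_df == 0:
        base.statistic, base.df, base.p_value = 0.0, 1, 1.0
        base.reason = "representation constant"
        return base
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, full, _ = _loglik_lrt(frame["y"], X_full, X_reduced, binary)
        if binary and not np.isfinite(full.llf):
            base.reason = "non-finite likelihood (separation?)"
            base.flags.append("separation")
            return base
        if binary:
            fitted = np.asarray(full.fittedvalues)
            if (fitted > 1 - 1e-10).any() or (fitted < 1e-10).any():
                base.flags.append("separation")
        base.statistic = float(stat)
        base.df = int(rep_df)
        base.p_value = float(stats.chi2.sf(stat, rep_df))
    except Exception as exc:
        base.reason = f"fit failed: {exc}"
    return base


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the sorted scale, capped at 1,
    mapped back to the input order.  NaN entries are excluded from ``m`` and
    stay NaN.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[mask] = qv
    return q


def screen_factors(
    phenotypes,
    representations: dict[str, pd.Series],
    fdr_threshold: float = 0.1,
    nominal: float = 0.05,
    covariates: Optional[pd.DataFrame] = None,
) -> ScreenSummary:
    """Run every factor against every representation with per-representation
    BH-FDR families, and summarize FDR/nominal/shared/specific sets."""
    results: list[AssociationResult] = []
    for rep_name, rep_values in representations.items():
        family: list[AssociationResult] = []
        for fname in phenotypes.factor_names:
            kind = phenotypes.kinds[fname]
            cov = None
            if covariates is not None and kind != "categorical":
                cov = covariates
            res = associate_factor(
                phenotypes.data[fname], kind, rep_values, rep_name, cov
            )
            family.append(res)
        qs = bh_fdr([r.p_value if r.p_value is not None else np.nan for r in family])
        for r, q in zip(family, qs):
            r.q_value = None if np.isnan(q) else float(q)
        results.extend(family)

    fdr_sig = {
        rep: {r.factor_name for r in results
              if r.representation == rep and r.q_value is not None
              and r.q_value <= fdr_threshold}
        for rep in representations
    }
    nom_sig = {
        rep: {r.factor_name for r in results
              if r.representation == rep and r.p_value is not None
              and r.p_value <= nominal}
        for rep in representations
    }
    reps = list(representations)
    shared = set.intersection(*fdr_sig.values()) if fdr_sig else set()
    specific = {rep: fdr_sig[rep] - set.union(*(fdr_sig[o] for o in reps if o != rep))
                if len(reps) > 1 else fdr_sig[rep]
                for rep in reps}
    return ScreenSummary(results, fdr_sig, nom_sig, shared, specific)


def adjusted_disease_test(
    disease: pd.Series,
    representation_values: pd.Series,
    covariates: pd.DataFrame,
    representation_name: str = "CT",
) -> AssociationResult:
    """Covariate-adjusted logistic LRT for a binary disease indicator.

    Fits disease ~ covariates + representation and tests the representation
    term against disease ~ covariates (chi-squared with K-1 df for cluster
    labels, 1 for the gradient).
    """
    return associate_factor(
        disease, "binary", representation_values, representation_name, covariates
    )


def drug_confounding_scan(
    disease: pd.Series,
    representation_values: pd.Series,
    covariates: pd.DataFrame,
    drug_matrix: pd.DataFrame,
    alpha: float = 0.05,
    representation_name: str = "CT",
) -> ConfoundingReport:
    """Post-hoc scan for drugs that explain away a disease-cluster signal.

    For each drug column the cluster term is re-tested in a model already
    containing the covariates and that drug.  If the cluster no longer
    improves the fit (LRT p > alpha) for at least one drug, the association
    is reported as confounded and the drugs are listed with their p-values.
    Constant drugs or drugs collinear with the disease are skipped.
    """
    baseline = adjusted_disease_test(
        disease, representation_values, covariates, representation_name
    )
    report = ConfoundingReport(
        disease=str(disease.name),
        representation=representation_name,
        baseline_p=baseline.p_value if baseline.p_value is not None else np.nan,
        confounded=False,
    )
    for drug in drug_matrix.columns:
        dcol = drug_matrix[drug]
        frame = pd.DataFrame({"y": disease, "rep": representation_values,
                              "drug": dcol}).join(covariates.astype(float)).dropna()
        if frame["drug"].nunique() < 2:
            report.skipped_drugs[drug] = "constant"
            continue
        if (frame["drug"] == frame["y"]).all() or (frame["drug"] == 1 - frame["y"]).all():
            report.skipped_drugs[drug] = "collinear with disease"
            continue
        rep_cols, rep_df, _ = _representation_design(frame["rep"])
        base_cols = frame.drop(columns=["y", "rep"])
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, _, _ = _loglik_lrt(
                    frame["y"], pd.concat([base_cols, rep_cols], axis=1),
                    base_cols, binary=True,
                )
            p = float(stats.chi2.sf(stat, rep_df))
        except Exception as exc:
            report.skipped_drugs[drug] = f"fit failed: {exc}"
            continue
        if p > alpha:
            report.confounded = True
            report.confounding_drugs[drug] = p
    return report


def compare_representations(
    factor: pd.Series,
    kind: str,
    labels_ET: pd.Series,
    labels_CT: pd.Series,
    gradient: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
) -> RepresentationComparison:
    """AIC comparison of the ET, CT and gradient representations of a factor.

    All three are fits of the same family (logistic for binary, OLS for
    continuous/ordinal) differing only in the representation term;
    ``AIC = 2 * n_params - 2 * loglik`` and the minimum wins.
    """
    if kind == "categorical":
        raise ValueError("AIC comparison needs a binary or continuous factor")
    binary = kind == "binary"
    frame = pd.DataFrame(
        {"y": factor, "ET": labels_ET, "CT": labels_CT, "gradient": gradient}
    )
    if covariates is not None:
        frame = frame.join(covariates.astype(float))
    frame = frame.dropna()
    cov_cols = frame.drop(columns=["y", "ET", "CT", "gradient"])
    aics: dict[str, Optional[float]] = {}
    partial = False
    for rep in ("ET", "CT", "gradient"):
        rep_cols, _, _ = _representation_design(frame[rep])
        X = pd.concat([cov_cols, rep_cols], axis=1)
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = _fit_glm(frame["y"], X, binary)
            aics[rep] = float(fit.aic)
        except Exception as exc:
            log.warning("representation %s fit failed: %s", rep, exc)
            aics[rep] = None
            partial = True
    valid = {k: v for k, v in aics.items() if v is not None}
    best = min(valid, key=valid.get) if valid else None
    return RepresentationComparison(
        factor_name=str(factor.name),
        aic_ET=aics["ET"],
        aic_CT=aics["CT"],
        aic_gradient=aics["gradient"],
        best=best,
        partial=partial,
    )


def subdiagnosis_test(
    subcode_labels: pd.Series,
    cluster_labels: pd.Series,
    pool_small: bool = False,
) -> AssociationResult:
    """Chi-squared test of subdiagnosis composition across clusters.

    Restricted to carriers of the parent code (rows with a subcode).  Cells
    with expected count < 1 trigger a small-cell flag; with ``pool_small``
    the rarest subcodes are pooled into ``"other"`` until no such cell
    remains (or only two categories are left).
    """
    frame = pd.DataFrame({"sub": subcode_labels, "cluster": cluster_labels}).dropna()
    res = AssociationResult(
        factor_name=str(subcode_labels.name),
        representation="cluster",
        test="chi_squared",
        statistic=None,
        df=None,
        p_value=None,
        n_used=len(frame),
    )
    if frame["sub"].nunique() < 2:
        res.reason = "single subcode observed"
        return res
    tab = pd.crosstab(frame["sub"], frame["cluster"])

    def expected(t: pd.DataFrame) -> np.ndarray:
        o = t.to_numpy(dtype=float)
        return np.outer(o.sum(1), o.sum(0)) / o.sum()

    if pool_small:
        while tab.shape[0] > 2 and (expected(tab) < 1.0).any():
            rarest = tab.sum(axis=1).idxmin()
            other = tab.loc[[rarest]].sum()
            tab = tab.drop(index=rarest)
            if "other" in tab.index:
                tab.loc["other"] += other
            else:
                tab.loc["other"] = other
    if (expected(tab) < 1.0).any():
        res.flags.append("small_expected_cells")
        log.warning("subdiagnosis table has expected cell counts < 1")
    stat, p, df, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    res.statistic, res.p_value, res.df = float(stat), float(p), int(df)
    res.per_cluster_summary = {
        c: tab[c].to_dict() for c in tab.columns
    }
    return res
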