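"""Community-level descriptors built on top of DMM fits.

Covers the model-fit curve over K with elbow-style selection, the fixed
3-cluster enterotype (ET) and selected-K community type (CT) models, the
ET-CT correspondence table, per-cluster driving genera, the continuous
log Prevotella/Bacteroides "gradient" representation, per-sample diversity,
and Bray-Curtis principal coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .dmm import DMMFit, fit_dmm, laplace_evidence
from .tables import TaxaCountTable

__all__ = [
    "ModelFitCurve",
    "fit_curve",
    "select_k",
    "crosstab_models",
    "driving_genera",
    "gradient_score",
    "diversity",
    "bray_curtis_pcoa",
]

log = logging.getLogger(__name__)

ENTEROTYPE_K = 3


@dataclass
class ModelFitCurve:
    """Laplace score (negative log evidence) as a function of K."""

    k_values: list[int]
    scores: list[float]
    fits: dict[int, DMMFit] = field(default_factory=dict)
    partial: bool = False

    def __post_init__(self) -> None:
        if list(self.k_values) != sorted(set(self.k_values)):
            raise ValueError("k_values must be strictly increasing")
        if len(self.k_values) != len(self.scores):
            raise ValueError("one score per k required")


def fit_curve(
    genus_counts,
    k_max: int = 10,
    seed: int = 0,
    n_starts: int = 3,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> ModelFitCurve:
    """Fit DMMs for K = 1..k_max and score each by Laplace evidence.

    Per-K failures are logged and skipped, marking the curve as partial.
    Each K gets an independent seed stream derived from ``seed`` so the curve
    does not depend on evaluation order.
    """
    ks: list[int] = []
    scores: list[float] = []
    fits: dict[int, DMMFit] = {}
    partial = False
    for k in range(1, k_max + 1):
        try:
            fit = fit_dmm(
                genus_counts, k, seed=seed + 1000 * k, n_starts=n_starts,
                tol=tol, max_iter=max_iter,
            )
            score = laplace_evidence(fit, genus_counts)
        except Exception as exc:  # pragma: no cover - defensive per-K guard
            log.warning("DMM fit failed for K=%d: %s", k, exc)
            partial = True
            continue
        ks.append(k)
        scores.append(score)
        fits[k] = fit
    return ModelFitCurve(ks, scores, fits, partial)


def select_k(curve: ModelFitCurve, rule: str = "elbow", tau: float = 0.05) -> int:
    """Choose the number of clusters from a model-fit curve.

    The default ``elbow`` rule returns the smallest k after which there is no
    substantial improvement: the first k whose gain ``score(k) - score(k+1)``
    falls below ``tau`` times the initial gain ``score(1) - score(2)``.  The
    ``min`` rule returns the global minimum.  A non-positive initial gain
    makes the elbow undefined, in which case the global minimum is returned
    with a warning.
    """
    if len(curve.k_values) < 2:
        if not curve.k_values:
            raise ValueError("empty model-fit curve")
        return curve.k_values[0]
    ks = list(curve.k_values)
    scores = np.asarray(curve.scores, dtype=float)
    if rule == "min":
        return ks[int(np.argmin(scores))]
    if rule != "elbow":
        raise ValueError(f"unknown selection rule {rule!r}")
    first_gain = scores[0] - scores[1]
    if first_gain <= 0:
        log.warning("score(2) >= score(1); falling back to the global minimum")
        return ks[int(np.argmin(scores))]
    threshold = tau * first_gain
    for i in range(len(ks) - 1):
        gain = scores[i] - scores[i + 1]
        if gain < threshold:
            return ks[i]
    return ks[-1]


def crosstab_models(labels_a, labels_b, names=("model_a", "model_b")) -> pd.DataFrame:
    """Contingency table of two cluster labelings over the same samples."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    tab = pd.crosstab(
        pd.Series(labels_a, name=names[0]), pd.Series(labels_b, name=names[1])
    )
    return tab


def driving_genera(fit: DMMFit, top_m: int = 10) -> dict[int, pd.DataFrame]:
    """Rank genera per cluster by deviation of the expected proportion from
    the across-cluster mean.

    Returns, per 1-based cluster index, a DataFrame with columns ``genus``,
    ``expected_proportion`` and ``deviation`` sorted by absolute deviation
    (descending; alphabetical on ties).
    """
    m = fit.expected_compositions()  # (K, G)
    center = m.mean(axis=0)
    out: dict[int, pd.DataFrame] = {}
    for k in range(fit.K):
        dev = m[k] - center
        df = pd.DataFrame(
            {
                "genus": fit.genus_ids,
                "expected_proportion": m[k],
                "deviation": dev,
            }
        )
        df["_absdev"] = df["deviation"].abs()
        df = df.sort_values(
            ["_absdev", "genus"], ascending=[False, True], kind="mergesort"
        ).drop(columns="_absdev")
        out[k + 1] = df.head(top_m).reset_index(drop=True)
    return out


def gradient_score(
    genus_counts: TaxaCountTable,
    pseudocount: float = 0.5,
    prevotella: str = "Prevotella",
    bacteroides: str = "Bacteroides",
) -> pd.Series:
    """Per-sample natural-log Prevotella/Bacteroides ratio on counts.

    ``g_i = ln((P_i + c) / (B_i + c))`` with pseudocount ``c`` guarding
    against zeros.  Genus columns are matched by exact name.
    """
    for name in (prevotella, bacteroides):
        if name not in genus_counts.counts.columns:
            raise ValueError(f"genus column {name!r} not found in the table")
    P = genus_counts.counts[prevotella].to_numpy(dtype=float)
    B = genus_counts.counts[bacteroides].to_numpy(dtype=float)
    g = np.log((P + pseudocount) / (B + pseudocount))
    return pd.Series(g, index=genus_counts.counts.index, name="gradient")


def diversity(table: TaxaCountTable) -> pd.DataFrame:
    """Observed richness and Shannon index (natural log) per sample."""
    X = table.counts.to_numpy(dtype=float)
    depths = X.sum(axis=1)
    if (depths <= 0).any():
        bad = table.counts.index[depths <= 0][0]
        raise ValueError(f"zero-depth sample {bad!r}; filter before computing diversity")
    richness = (X > 0).sum(axis=1)
    P = X / depths[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    shannon = -plogp.sum(axis=1)
    return pd.DataFrame(
        {"observed_richness": richness, "shannon": shannon}, index=table.counts.index
    )


def bray_curtis_pcoa(
    species_counts: TaxaCountTable, n_axes: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates of Bray-Curtis dissimilarities on proportions.

    Classical metric scaling via double-centering; negative eigenvalues are
    reported as-is (no Lingoes/Cailliez correction).  Returns the first
    ``n_axes`` sample coordinates and the full eigenvalue spectrum.
    """
    if species_counts.n_samples < 3:
        raise ValueError("PCoA needs at least 3 samples")
    P = species_counts.proportions().to_numpy()
    D = squareform(pdist(P, metric="braycurtis"))
    if np.allclose(D, 0.0):
        log.warning("all pairwise Bray-Curtis distances are zero")
        coords = pd.DataFrame(
            np.zeros((species_counts.n_samples, n_axes)),
            index=species_counts.counts.index,
            columns=[f"PC{i + 1}" for i in range(n_axes)],
        )
        return coords, np.zeros(species_counts.n_samples)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ord_res = _skbio_pcoa(
            DistanceMatrix(D, ids=[str(s) for s in species_counts.sample_ids]),
            method="eigh",
        )
    eigvals = ord_res.eigvals.to_numpy()
    coords = ord_res.samples.iloc[:, :n_axes].copy()
    coords.index = species_counts.counts.index
    coords.columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return coords, eigvals
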