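"""Synthetic microbiome cohort generator with known ground truth.

Emulates the statistical structure a community-typing analysis assumes:
genus counts from a K-component Dirichlet-multinomial mixture, phenotype
factors with cluster-specific / gradient / null effects on top of standard
covariates (age, gender, BMI, Bristol stool score), drug-usage indicators
with a built-in confounding pathway, and incident-disease event times from a
Weibull proportional-hazards model with administrative censoring.

Every generator is a pure function of its spec and seed: identical inputs
give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .tables import PhenotypeTable, TaxaCountTable

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "DrugConfounder",
    "SurvivalSpec",
    "SyntheticTruth",
    "three_cluster_preset",
    "five_cluster_preset",
    "generate_counts",
    "generate_phenotypes",
    "generate_survival",
]

NAMED_ROLES = ("Bacteroides", "Prevotella", "Clostridium")

#: Firmicutes-like genus names used to fill the spread component
FIRMICUTES_GENERA = (
    "Faecalibacterium", "Blautia", "Roseburia", "Ruminococcus", "Dorea",
    "Coprococcus", "Eubacterium", "Anaerostipes", "Lachnospira", "Butyrivibrio",
)


@dataclass
class CohortSpec:
    """Generative description of a synthetic microbiome cohort."""

    n_samples: int
    n_genera: int
    K_true: int
    mixing_weights: np.ndarray
    alpha_matrix: np.ndarray  # (K_true, n_genera), all > 0
    depth_log_mean: float = float(np.log(1e4))
    depth_log_sd: float = 0.3
    named_genus_indices: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.mixing_weights = np.asarray(self.mixing_weights, dtype=float)
        self.alpha_matrix = np.asarray(self.alpha_matrix, dtype=float)
        if self.n_samples < 1 or self.n_genera < 1 or self.K_true < 1:
            raise ValueError("n_samples, n_genera, K_true must be positive")
        if self.mixing_weights.shape != (self.K_true,):
            raise ValueError("mixing_weights must have length K_true")
        if abs(self.mixing_weights.sum() - 1.0) > 1e-12:
            raise ValueError("mixing_weights must sum to 1")
        if self.alpha_matrix.shape != (self.K_true, self.n_genera):
            raise ValueError("alpha_matrix must be K_true x n_genera")
        if (self.alpha_matrix <= 0).any():
            raise ValueError("all alpha entries must be > 0")
        if not np.isfinite([self.depth_log_mean, self.depth_log_sd]).all():
            raise ValueError("depth parameters must be finite")
        idx = list(self.named_genus_indices.values())
        if len(idx) != len(set(idx)):
            raise ValueError("named genus indices must be distinct")
        if any(i < 0 or i >= self.n_genera for i in idx):
            raise ValueError("named genus index out of range")

    def genus_names(self) -> list[str]:
        names = [f"Genus_{j:03d}" for j in range(self.n_genera)]
        reserved = dict(self.named_genus_indices)
        # fill remaining slots with Firmicutes-like names for readability
        free = [j for j in range(self.n_genera) if j not in reserved.values()]
        for name, j in zip(FIRMICUTES_GENERA, free):
            names[j] = name
        for role, j in reserved.items():
            names[j] = role
        return names


@dataclass
class DrugConfounder:
    """Drug-usage indicator entangled with a disease factor.

    Two generative pathways are supported:

    * indication: drug use depends on realized disease status
      (``p_use_given_disease`` / ``p_use_given_healthy``);
    * mediation: drug use depends on the cluster (``cluster_use_logits``) and
      the drug shifts the factor by ``drug_effect_on_factor`` log-odds, so a
      cluster-disease association can be carried entirely by the drug.
    """

    atc_code: str
    p_use_given_disease: float = 0.0
    p_use_given_healthy: float = 0.0
    drug_effect_on_factor: float = 0.0
    cluster_use_logits: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for p in (self.p_use_given_disease, self.p_use_given_healthy):
            if not 0.0 <= p <= 1.0:
                raise ValueError("drug usage probabilities must be in [0, 1]")


@dataclass
class EffectSpec:
    """How one phenotype factor depends on the community structure."""

    factor_name: str
    factor_kind: str  # binary | continuous | categorical | ordinal
    effect_mode: str  # cluster_specific | gradient | null
    baseline: float = 0.0  # intercept (log-odds or mean)
    beta_cluster: Optional[np.ndarray] = None
    beta_gradient: float = 0.0
    covariate_betas: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    n_levels: int = 3  # categorical factors only
    drug_confounder: Optional[DrugConfounder] = None

    def __post_init__(self) -> None:
        if self.factor_kind not in ("binary", "continuous", "categorical", "ordinal"):
            raise ValueError(f"unknown factor kind {self.factor_kind!r}")
        if self.effect_mode not in ("cluster_specific", "gradient", "null"):
            raise ValueError(f"unknown effect mode {self.effect_mode!r}")
        if self.effect_mode == "cluster_specific" and self.beta_cluster is None:
            raise ValueError("cluster_specific effect needs beta_cluster")
        if self.beta_cluster is not None:
            self.beta_cluster = np.asarray(self.beta_cluster, dtype=float)


@dataclass
class SurvivalSpec:
    """Weibull proportional-hazards generator for one incident disease."""

    disease_id: str
    log_hazard_ratios: np.ndarray  # per cluster, reference cluster = 0
    baseline_rate: float = 0.05  # events per person-year at reference
    weibull_shape: float = 1.0
    admin_censor_time: float = 3.1  # years; median follow-up target
    censor_jitter: float = 0.5  # uniform entry jitter, fraction of censor time
    covariate_log_hrs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.log_hazard_ratios = np.asarray(self.log_hazard_ratios, dtype=float)
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be > 0")
        if self.admin_censor_time < 0:
            raise ValueError("admin_censor_time must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside generated data, for recovery tests."""

    true_labels: np.ndarray  # 1..K_true per sample
    mixing_weights: np.ndarray
    alpha_matrix: np.ndarray
    sample_ids: list[str]
    genus_names: list[str]
    named_genus_indices: dict[str, int]
    effects: list[EffectSpec] = field(default_factory=list)
    survival_specs: list[SurvivalSpec] = field(default_factory=list)

    def to_yaml(self, path) -> None:
        meta = {
            "mixing_weights": [float(v) for v in self.mixing_weights],
            "alpha_matrix": [[float(v) for v in row] for row in self.alpha_matrix],
            "genus_names": list(self.genus_names),
            "named_genus_indices": {k: int(v) for k, v in self.named_genus_indices.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)

    def labels_to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample_id": self.sample_ids, "true_label": self.true_labels}
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _base_alpha(n_genera: int, rng: np.random.Generator) -> np.ndarray:
    """Common low-level background so components share a taxon inventory."""
    return 0.05 + 0.15 * rng.random(n_genera)


def three_cluster_preset(
    n_samples: int = 600,
    n_genera: int = 40,
    seed: int = 0,
    mixing_weights=(0.45, 0.25, 0.30),
    depth_log_mean: float = float(np.log(5e3)),
    depth_log_sd: float = 0.3,
) -> CohortSpec:
    """Well-separated three-component cohort: Bacteroides-heavy,
    Prevotella-heavy, and a component spread over Firmicutes-like genera."""
    rng = np.random.default_rng(seed + 104729)
    named = {"Bacteroides": 0, "Prevotella": 1, "Clostridium": 2}
    firmicutes_cols = list(range(3, 13))
    alpha = np.stack([_base_alpha(n_genera, rng) for _ in range(3)])
    alpha[0, 0] += 18.0  # Bacteroides-dominated
    alpha[0, firmicutes_cols] += 0.4
    alpha[1, 1] += 18.0  # Prevotella-dominated
    alpha[1, firmicutes_cols] += 0.4
    alpha[2, firmicutes_cols] += 2.2  # spread over Firmicutes genera
    alpha[2, 2] += 1.5  # Clostridium enriched in the spread component
    return CohortSpec(
        n_samples=n_samples,
        n_genera=n_genera,
        K_true=3,
        mixing_weights=np.asarray(mixing_weights, dtype=float),
        alpha_matrix=alpha,
        depth_log_mean=depth_log_mean,
        depth_log_sd=depth_log_sd,
        named_genus_indices=named,
        seed=seed,
    )


def five_cluster_preset(
    n_samples: int = 1000,
    n_genera: int = 40,
    seed: int = 0,
    mixing_weights=(0.18, 0.26, 0.24, 0.20, 0.12),
    depth_log_mean: float = float(np.log(5e3)),
    depth_log_sd: float = 0.3,
) -> CohortSpec:
    """Five components along the Bacteroides-Prevotella gradient: extreme
    Bacteroides, moderate Bacteroides, Firmicutes spread, moderate Prevotella,
    extreme Prevotella."""
    rng = np.random.default_rng(seed + 15485863)
    named = {"Bacteroides": 0, "Prevotella": 1, "Clostridium": 2}
    firmicutes_cols = list(range(3, 13))
    alpha = np.stack([_base_alpha(n_genera, rng) for _ in range(5)])
    alpha[0, 0] += 30.0  # extreme Bacteroides
    alpha[1, 0] += 7.0  # moderate Bacteroides
    alpha[1, firmicutes_cols] += 1.0
    alpha[2, firmicutes_cols] += 2.2  # Firmicutes spread
    alpha[2, 2] += 1.5
    alpha[3, 1] += 7.0  # moderate Prevotella
    alpha[3, firmicutes_cols] += 1.0
    alpha[4, 1] += 30.0  # extreme Prevotella
    return CohortSpec(
        n_samples=n_samples,
        n_genera=n_genera,
        K_true=5,
        mixing_weights=np.asarray(mixing_weights, dtype=float),
        alpha_matrix=alpha,
        depth_log_mean=depth_log_mean,
        depth_log_sd=depth_log_sd,
        named_genus_indices=named,
        seed=seed,
    )


#: collapse map from the five-cluster preset onto the three canonical
#: enterotype roles (1 = Bacteroides, 2 = Prevotella, 3 = Firmicutes-spread)
FIVE_TO_THREE = {1: 1, 2: 1, 3: 3, 4: 2, 5: 2}


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_counts(spec: CohortSpec) -> tuple[TaxaCountTable, SyntheticTruth]:
    """Draw a genus count table from the Dirichlet-multinomial mixture.

    Per sample: cluster ``z ~ Categorical(pi)``, composition
    ``p ~ Dirichlet(alpha_z)``, depth ``n ~ round(LogNormal)`` (at least 1),
    counts ``x ~ Multinomial(n, p)``.
    """
    rng = np.random.default_rng(spec.seed)
    N, G = spec.n_samples, spec.n_genera
    z = rng.choice(spec.K_true, size=N, p=spec.mixing_weights) + 1
    depths = np.maximum(
        1, np.round(rng.lognormal(spec.depth_log_mean, spec.depth_log_sd, size=N))
    ).astype(np.int64)
    counts = np.empty((N, G), dtype=np.int64)
    for i in range(N):
        p = rng.dirichlet(spec.alpha_matrix[z[i] - 1])
        counts[i] = rng.multinomial(depths[i], p)
    sample_ids = [f"S{i + 1:04d}" for i in range(N)]
    genus_names = spec.genus_names()
    table = TaxaCountTable(
        pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"),
                     columns=genus_names)
    )
    truth = SyntheticTruth(
        true_labels=z,
        mixing_weights=spec.mixing_weights.copy(),
        alpha_matrix=spec.alpha_matrix.copy(),
        sample_ids=sample_ids,
        genus_names=genus_names,
        named_genus_indices=dict(spec.named_genus_indices),
    )
    return table, truth


def _default_covariates(rng: np.random.Generator, truth: SyntheticTruth,
                        stool_cluster_shift: float = 0.0) -> pd.DataFrame:
    """Age ~ N(50, 10) truncated to [23, 89]; gender ~ Bernoulli(0.7) female;
    BMI ~ N(26, 4); Bristol stool score ordinal 1-7 around a latent normal,
    optionally shifted per cluster."""
    N = len(truth.sample_ids)
    age = rng.normal(50.0, 10.0, size=N)
    while True:  # redraw out-of-range values; keeps the target shape
        bad = (age < 23.0) | (age > 89.0)
        if not bad.any():
            break
        age[bad] = rng.normal(50.0, 10.0, size=int(bad.sum()))
    gender = rng.binomial(1, 0.7, size=N)  # 1 = female
    bmi = rng.normal(26.0, 4.0, size=N)
    z = truth.true_labels
    latent = rng.normal(3.8 + stool_cluster_shift * (z - z.mean()), 1.2, size=N)
    stool = np.clip(np.round(latent), 1, 7).astype(int)
    return pd.DataFrame(
        {"age": age, "gender": gender, "bmi": bmi, "stool": stool},
        index=pd.Index(truth.sample_ids, name="sample_id"),
    )


def _standardized(cov: pd.DataFrame) -> pd.DataFrame:
    out = cov.astype(float).copy()
    for c in out.columns:
        sd = out[c].std()
        out[c] = (out[c] - out[c].mean()) / (sd if sd > 0 else 1.0)
    return out


def _gradient_from_counts(counts: TaxaCountTable, truth: SyntheticTruth,
                          pseudocount: float = 0.5) -> np.ndarray:
    named = truth.named_genus_indices
    P = counts.counts.iloc[:, named["Prevotella"]].to_numpy(dtype=float)
    B = counts.counts.iloc[:, named["Bacteroides"]].to_numpy(dtype=float)
    return np.log((P + pseudocount) / (B + pseudocount))


def generate_phenotypes(
    truth: SyntheticTruth,
    effects: list[EffectSpec],
    seed: int = 0,
    counts: Optional[TaxaCountTable] = None,
    stool_cluster_shift: float = 0.0,
) -> PhenotypeTable:
    """Draw phenotype factors conditioned on the true cluster labels.

    Binary factors follow a logistic model ``logit p = baseline +
    beta_cluster[z] + sum beta_cov * cov_std (+ beta_gradient * g)``;
    continuous factors a Normal with the analogous mean; categorical factors a
    softmax whose first level is shifted; ordinal factors a binned latent
    normal.  Gradient-mode effects need ``counts`` to compute the per-sample
    log Prevotella/Bacteroides ratio.  Drug confounders add a companion
    ``drug_<ATC>`` column.
    """
    rng = np.random.default_rng(seed)
    cov = _default_covariates(rng, truth, stool_cluster_shift)
    cov_std = _standardized(cov)
    z = truth.true_labels
    g = None
    if counts is not None:
        g = _gradient_from_counts(counts, truth)
    elif any(e.effect_mode == "gradient" for e in effects):
        raise ValueError("gradient-mode effects require the count table")

    data = cov.copy()
    kinds: dict[str, str] = {}
    for eff in effects:
        for name in eff.covariate_betas:
            if name not in cov.columns:
                raise ValueError(f"effect on unknown covariate {name!r}")
        eta = np.full(len(z), float(eff.baseline))
        if eff.effect_mode == "cluster_specific":
            if len(eff.beta_cluster) < z.max():
                raise ValueError("beta_cluster shorter than the number of clusters")
            eta = eta + eff.beta_cluster[z - 1]
        elif eff.effect_mode == "gradient":
            eta = eta + eff.beta_gradient * g
        for name, b in eff.covariate_betas.items():
            eta = eta + b * cov_std[name].to_numpy()

        drug_col = None
        conf = eff.drug_confounder
        if conf is not None and conf.cluster_use_logits is not None:
            logits = np.asarray(conf.cluster_use_logits, dtype=float)[z - 1]
            drug_col = rng.binomial(1, 1.0 / (1.0 + np.exp(-logits)))
            eta = eta + conf.drug_effect_on_factor * drug_col

        if eff.factor_kind == "binary":
            p = 1.0 / (1.0 + np.exp(-eta))
            vals = rng.binomial(1, p).astype(float)
        elif eff.factor_kind == "continuous":
            vals = eta + rng.normal(0.0, eff.noise_sd, size=len(z))
        elif eff.factor_kind == "ordinal":
            latent = eta + rng.normal(0.0, eff.noise_sd, size=len(z))
            vals = np.clip(np.round(latent - latent.min()) + 1, 1, 7).astype(float)
        else:  # categorical: shift the first level's log-probability
            L = eff.n_levels
            logits = np.zeros((len(z), L))
            logits[:, 0] = eta
            pmat = np.exp(logits - logits.max(axis=1, keepdims=True))
            pmat /= pmat.sum(axis=1, keepdims=True)
            u = rng.random(len(z))
            vals = (u[:, None] > pmat.cumsum(axis=1)).sum(axis=1).astype(float)

        data[eff.factor_name] = vals
        kinds[eff.factor_name] = eff.factor_kind

        if conf is not None and conf.cluster_use_logits is None:
            if eff.factor_kind != "binary":
                raise ValueError("indication-pathway drugs need a binary factor")
            p_use = np.where(vals == 1.0, conf.p_use_given_disease,
                             conf.p_use_given_healthy)
            drug_col = rng.binomial(1, p_use)
        if drug_col is not None:
            dname = f"drug_{conf.atc_code}"
            data[dname] = drug_col.astype(float)
            kinds[dname] = "binary"

    truth.effects = list(effects)
    return PhenotypeTable(data, kinds)


def generate_survival(
    truth: SyntheticTruth,
    spec: SurvivalSpec,
    covariates: Optional[pd.DataFrame] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw incident-disease follow-up from a Weibull PH model.

    The per-sample log hazard is ``log_hazard_ratios[z] + sum covariate
    terms`` (covariates standardized internally).  Event time follows a
    Weibull with shape ``s`` and baseline rate ``lambda0``:
    ``T = (E / (lambda0 * exp(h)))**(1/s)`` with ``E ~ Exp(1)``.  Observed
    time is ``min(T, C)`` where the administrative censor time ``C`` is
    jittered uniformly around ``admin_censor_time`` to emulate staggered
    study entry.
    """
    rng = np.random.default_rng(seed)
    z = truth.true_labels
    if len(spec.log_hazard_ratios) < z.max():
        raise ValueError("log_hazard_ratios shorter than the number of clusters")
    h = spec.log_hazard_ratios[z - 1].astype(float)
    if covariates is not None:
        cov_std = _standardized(covariates.loc[truth.sample_ids])
        for name, b in spec.covariate_log_hrs.items():
            if name not in cov_std.columns:
                raise ValueError(f"survival effect on unknown covariate {name!r}")
            h = h + b * cov_std[name].to_numpy()
    E = rng.exponential(1.0, size=len(z))
    T = (E / (spec.baseline_rate * np.exp(h))) ** (1.0 / spec.weibull_shape)
    jitter = spec.censor_jitter
    C = spec.admin_censor_time * rng.uniform(1.0 - jitter, 1.0 + jitter, size=len(z))
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    if spec.admin_censor_time == 0:
        time = np.zeros_like(time)
        event = np.zeros_like(event)
    if event.sum() == 0:
        import logging

        logging.getLogger(__name__).warning(
            "disease %s: all observations censored", spec.disease_id
        )
    out = pd.DataFrame(
        {
            "sample_id": truth.sample_ids,
            "disease_id": spec.disease_id,
            "time_years": time,
            "event": event,
        }
    )
    truth.survival_specs.append(spec)
    return out
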