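"""End-to-end orchestration: preprocess → fit → select K → describe → screen.

``run_pipeline`` drives the whole analysis from a :class:`RunConfig` and
writes every artifact as TSV/YAML/JSON under the output directory, plus a
run manifest capturing thresholds and seeds so any artifact can be
regenerated.  ``make_demo`` builds a fully synthetic demo cohort (counts,
phenotypes, EHR tables) with known ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import prep, simulate
from .association import (
    compare_representations,
    drug_confounding_scan,
    screen_factors,
)
from .community import (
    ENTEROTYPE_K,
    bray_curtis_pcoa,
    crosstab_models,
    diversity,
    driving_genera,
    fit_curve,
    gradient_score,
    select_k,
)
from .dmm import assign_clusters, save_fit
from .survival import screen_incident
from .tables import (
    read_count_table,
    read_phenotype_table,
    write_count_table,
    write_ehr_tables,
    write_phenotype_table,
)

__all__ = ["RunConfig", "run_pipeline", "make_demo", "artifact_checksums"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (also the YAML schema)."""

    counts_path: str
    output_dir: str
    phenotypes_path: Optional[str] = None
    prevalent_path: Optional[str] = None
    drugs_path: Optional[str] = None
    incident_path: Optional[str] = None
    min_reads: int = 500
    prevalence_frac: float = 0.10
    rel_abund: float = 0.001
    aggregate_genus: bool = False  # input already genus-level by default
    k_max: int = 5
    n_starts: int = 2
    tau: float = 0.05
    pseudocount: float = 0.5
    fdr_threshold: float = 0.1
    nominal: float = 0.05
    confounding_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("prevalence_frac", 0.0, 1.0),
            ("rel_abund", 0.0, 1.0),
            ("fdr_threshold", 0.0, 1.0),
            ("nominal", 0.0, 1.0),
            ("confounding_alpha", 0.0, 1.0),
            ("tau", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def artifact_checksums(directory) -> dict[str, str]:
    """SHA-256 of every file under a directory, keyed by relative path."""
    directory = Path(directory)
    out = {}
    for p in sorted(directory.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(directory))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis and return the artifact directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read"
    try:
        table = read_count_table(config.counts_path)

        stage = "preprocess"
        table, removal = prep.drop_low_depth_samples(table, min_reads=config.min_reads)
        species_table = prep.filter_prevalent_taxa(
            table, config.prevalence_frac, config.rel_abund
        )
        if config.aggregate_genus:
            genus_table = prep.aggregate_to_genus(species_table)
        else:
            genus_table = species_table
        write_count_table(genus_table, out / "genus_counts.tsv")

        stage = "fit_curve"
        curve = fit_curve(
            genus_table, k_max=config.k_max, seed=config.seed,
            n_starts=config.n_starts,
        )
        selected_k = select_k(curve, tau=config.tau)
        pd.DataFrame({"K": curve.k_values, "laplace_score": curve.scores}).to_csv(
            out / "model_fit_curve.tsv", sep="\t", index=False
        )

        stage = "assign"
        fit_et = curve.fits[min(ENTEROTYPE_K, max(curve.fits))]
        fit_ct = curve.fits[selected_k]
        save_fit(fit_et, out / "fit_ET")
        save_fit(fit_ct, out / "fit_CT")
        labels_et = assign_clusters(fit_et, genus_table)
        labels_ct = assign_clusters(fit_ct, genus_table)
        idx = pd.Index(genus_table.sample_ids, name="sample_id")
        et = pd.Series(labels_et.labels, index=idx, name="ET")
        ct = pd.Series(labels_ct.labels, index=idx, name="CT")
        grad = gradient_score(genus_table, pseudocount=config.pseudocount)
        pd.DataFrame({"ET": et, "CT": ct, "gradient": grad}).to_csv(
            out / "cluster_assignments.tsv", sep="\t"
        )

        stage = "descriptors"
        crosstab_models(ct, et, names=("CT", "ET")).to_csv(
            out / "ct_et_correspondence.tsv", sep="\t"
        )
        drivers = driving_genera(fit_ct)
        pd.concat(
            [df.assign(cluster=k) for k, df in drivers.items()], ignore_index=True
        ).to_csv(out / "driving_genera.tsv", sep="\t", index=False)
        diversity(genus_table).to_csv(out / "diversity.tsv", sep="\t")
        coords, eigvals = bray_curtis_pcoa(species_table)
        coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t")

        representations = {"ET": et, "CT": ct, "gradient": grad}
        manifest_extra: dict = {}

        if config.phenotypes_path is not None:
            stage = "associate"
            pheno = read_phenotype_table(config.phenotypes_path)
            pheno.data.index = pheno.data.index.astype(str)
            covs = pheno.covariates()
            summary = screen_factors(
                pheno, representations, config.fdr_threshold, config.nominal
            )
            rows = [
                {
                    "factor": r.factor_name,
                    "representation": r.representation,
                    "test": r.test,
                    "statistic": r.statistic,
                    "df": r.df,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                    "n_used": r.n_used,
                    "reason": r.reason,
                }
                for r in summary.results
            ]
            pd.DataFrame(rows).to_csv(out / "associations.tsv", sep="\t", index=False)
            cells = []
            for r in summary.results:
                if r.per_cluster_summary:
                    for cl, v in r.per_cluster_summary.items():
                        if isinstance(v, dict):
                            continue
                        cells.append(
                            {"factor": r.factor_name, "representation": r.representation,
                             "cluster": cl, "value": v}
                        )
            pd.DataFrame(cells).to_csv(
                out / "per_cluster_summaries.tsv", sep="\t", index=False
            )
            manifest_extra["n_fdr_significant"] = {
                k: len(v) for k, v in summary.fdr_significant.items()
            }

            stage = "compare_representations"
            comp_rows = []
            for fname in pheno.factor_names:
                kind = pheno.kinds[fname]
                if kind == "categorical":
                    continue
                comp = compare_representations(
                    pheno.data[fname], kind, et, ct, grad
                )
                comp_rows.append(
                    {"factor": fname, "aic_ET": comp.aic_ET, "aic_CT": comp.aic_CT,
                     "aic_gradient": comp.aic_gradient, "best": comp.best}
                )
            pd.DataFrame(comp_rows).to_csv(
                out / "representation_aic.tsv", sep="\t", index=False
            )

            stage = "deconfound"
            if config.drugs_path is not None and len(covs.columns):
                drug_cols = [c for c in pheno.data.columns if c.startswith("drug_")]
                disease_cols = [
                    c for c in pheno.factor_names
                    if c.startswith("disease_") or (
                        pheno.kinds[c] == "binary" and not c.startswith("drug_")
                    )
                ]
                drug_matrix = pheno.data[drug_cols]
                conf_rows = []
                for rep_name in ("ET", "CT"):
                    for disease in disease_cols:
                        rep = representations[rep_name]
                        report = drug_confounding_scan(
                            pheno.data[disease], rep, covs, drug_matrix,
                            alpha=config.confounding_alpha,
                            representation_name=rep_name,
                        )
                        if report.baseline_p is not None and not np.isnan(
                            report.baseline_p
                        ) and report.baseline_p <= config.nominal:
                            conf_rows.append(
                                {
                                    "disease": disease,
                                    "representation": rep_name,
                                    "baseline_p": report.baseline_p,
                                    "confounded": report.confounded,
                                    "confounding_drugs": ";".join(
                                        sorted(report.confounding_drugs)
                                    ),
                                }
                            )
                pd.DataFrame(conf_rows).to_csv(
                    out / "confounding_report.tsv", sep="\t", index=False
                )

        if config.incident_path is not None and config.prevalent_path is not None:
            stage = "survive"
            incident = pd.read_csv(config.incident_path, sep="\t",
                                   dtype={"sample_id": str})
            prevalent = pd.read_csv(config.prevalent_path, sep="\t",
                                    dtype={"sample_id": str})
            covs = None
            if config.phenotypes_path is not None:
                covs = read_phenotype_table(config.phenotypes_path).covariates()
            surv = screen_incident(
                incident, prevalent, representations, covs, config.fdr_threshold
            )
            surv.to_csv(out / "incident_screen.tsv", sep="\t", index=False)
        elif config.incident_path is None:
            log.warning("no incident table given; survival stage skipped")

        stage = "manifest"
        manifest = {
            "config": asdict(config),
            "selected_k": int(selected_k),
            "enterotype_k": int(fit_et.K),
            "n_samples": int(genus_table.n_samples),
            "n_genera": int(genus_table.n_taxa),
            "removed_low_depth": removal.removed_ids,
            **manifest_extra,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception:
        log.error("pipeline failed at stage %r; partial artifacts kept in %s",
                  stage, out)
        raise
    return out


# ---------------------------------------------------------------------------
# demo cohort
# ---------------------------------------------------------------------------

def make_demo(seed: int = 0, out_dir=None, n_samples: int = 1000,
              n_genera: int = 50):
    """Generate the bundled demo cohort: counts, phenotypes, EHR tables.

    The demo uses the well-separated three-component preset, a small factor
    panel including one cluster-specific disease, one gradient-shaped factor
    and null factors, one fully drug-mediated disease (so the deconfounding
    scan has a true positive) and one clean disease with a direct cluster
    effect, plus one incident disease with a cluster-dependent hazard.
    """
    spec = simulate.three_cluster_preset(
        n_samples=n_samples, n_genera=n_genera, seed=seed
    )
    counts, truth = simulate.generate_counts(spec)
    effects = [
        simulate.EffectSpec(
            "disease_K29", "binary", "cluster_specific",
            baseline=-1.8, beta_cluster=np.array([1.2, 0.0, 0.0]),
        ),
        simulate.EffectSpec(
            "disease_E78", "binary", "cluster_specific",
            baseline=-1.6, beta_cluster=np.array([0.0, 0.0, 0.0]),
            drug_confounder=simulate.DrugConfounder(
                atc_code="C10AA05",
                cluster_use_logits=np.array([1.0, -2.5, -2.5]),
                drug_effect_on_factor=1.8,
            ),
        ),
        simulate.EffectSpec(
            "antibiotics_courses", "continuous", "gradient",
            baseline=2.0, beta_gradient=-0.4, noise_sd=1.0,
        ),
        simulate.EffectSpec("diet_fruit", "continuous", "null", baseline=0.0),
        simulate.EffectSpec("smoker", "binary", "null", baseline=-1.0),
    ]
    pheno = simulate.generate_phenotypes(truth, effects, seed=seed + 1,
                                         counts=counts)
    surv_spec = simulate.SurvivalSpec(
        disease_id="G43",
        log_hazard_ratios=np.array([0.0, 0.0, -0.9]),
        baseline_rate=0.06,
    )
    incident = simulate.generate_survival(
        truth, surv_spec, covariates=pheno.covariates(), seed=seed + 2
    )
    null_spec = simulate.SurvivalSpec(
        disease_id="I10", log_hazard_ratios=np.zeros(3), baseline_rate=0.05
    )
    incident = pd.concat(
        [incident,
         simulate.generate_survival(truth, null_spec,
                                    covariates=pheno.covariates(), seed=seed + 3)],
        ignore_index=True,
    )
    rng = np.random.default_rng(seed + 4)
    prev_mask = rng.random(n_samples) < 0.02
    prevalent = pd.DataFrame(
        {
            "sample_id": np.asarray(truth.sample_ids)[prev_mask],
            "icd10": "G43",
            "subcode": "G43.0",
        }
    )
    drugs = pd.DataFrame(
        {
            "sample_id": truth.sample_ids,
            "atc": "C10AA05",
            "used": pheno.data["drug_C10AA05"].astype(int).to_numpy(),
        }
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_count_table(counts, out_dir / "counts.tsv")
        write_phenotype_table(pheno, out_dir / "phenotypes.tsv")
        from .tables import EHRTables

        write_ehr_tables(
            EHRTables(prevalent, drugs, incident),
            out_dir / "prevalent.tsv", out_dir / "drugs.tsv",
            out_dir / "incident.tsv",
        )
        truth.to_yaml(out_dir / "truth.yaml")
        truth.labels_to_tsv(out_dir / "truth_labels.tsv")
    return counts, pheno, prevalent, drugs, incident, truth
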