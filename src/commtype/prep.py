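"""Preprocessing of taxonomic count tables and EHR factor grouping.

The standard path for a metagenomic cohort is: drop samples with an
exceptionally low read count, keep species detected in more than a given
fraction of samples at a minimum relative abundance, then aggregate the
species table to the genus level for community typing.  EHR-derived factors
are thresholded on case counts, with ATC drug codes rolled up the
classification hierarchy (level 5 → 4 → 3) until enough cases accumulate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import EHRTables, PhenotypeTable, TaxaCountTable

__all__ = [
    "RemovalReport",
    "drop_low_depth_samples",
    "filter_prevalent_taxa",
    "aggregate_to_genus",
    "group_ehr_factors",
    "genus_from_lineage",
]

log = logging.getLogger(__name__)

GENUS_PREFIXES = ("g__",)
UNCLASSIFIED_GENUS = "unclassified"


@dataclass
class RemovalReport:
    """Samples removed by the low-depth filter, with their depths."""

    removed_ids: list[str]
    depths: dict[str, int]
    threshold: float | None = None


def drop_low_depth_samples(
    table: TaxaCountTable,
    min_reads: int | None = None,
    n_lowest: int | None = None,
) -> tuple[TaxaCountTable, RemovalReport]:
    """Remove low-depth samples, either below ``min_reads`` or the ``n_lowest``.

    Exactly one of ``min_reads`` / ``n_lowest`` must be given.  ``n_lowest``
    removes that many smallest-depth samples (ties broken by sample id) and
    mirrors the common practice of dropping a handful of visibly failed
    libraries when no hard cutoff is published.
    """
    if (min_reads is None) == (n_lowest is None):
        raise ValueError("give exactly one of min_reads or n_lowest")
    depths = table.depths()
    if min_reads is not None:
        removed = depths.index[depths < min_reads]
        threshold: float | None = float(min_reads)
    else:
        if n_lowest < 0 or n_lowest > table.n_samples:
            raise ValueError(f"n_lowest={n_lowest} out of range")
        order = depths.reset_index()
        order.columns = ["sample_id", "depth"]
        order = order.sort_values(["depth", "sample_id"], kind="mergesort")
        removed = pd.Index(order["sample_id"].head(n_lowest))
        threshold = None
    if len(removed) == table.n_samples:
        raise ValueError("low-depth filter would remove every sample")
    kept = [s for s in table.sample_ids if s not in set(removed)]
    report = RemovalReport(
        removed_ids=list(removed),
        depths={s: int(depths[s]) for s in removed},
        threshold=threshold,
    )
    if report.removed_ids:
        log.info("removed %d low-depth samples: %s", len(removed), report.depths)
    return table.subset_samples(kept), report


def filter_prevalent_taxa(
    table: TaxaCountTable,
    prevalence_frac: float = 0.10,
    rel_abund: float = 0.001,
) -> TaxaCountTable:
    """Keep taxa detected (relative abundance ≥ ``rel_abund``) in strictly
    more than ``prevalence_frac`` of samples.

    Detection is per-sample relative abundance, inclusive at the abundance
    threshold; the prevalence comparison is strict (``> prevalence_frac``).
    """
    props = table.proportions().to_numpy()
    detected = props >= rel_abund
    prevalence = detected.mean(axis=0)
    keep = prevalence > prevalence_frac
    if not keep.any():
        raise ValueError(
            "prevalence/abundance filter removed every taxon; "
            f"lower prevalence_frac (={prevalence_frac}) or rel_abund (={rel_abund})"
        )
    return table.subset_taxa(np.asarray(table.taxon_ids)[keep])


def genus_from_lineage(lineage: str) -> str | None:
    """Extract the genus rank from a semicolon-separated lineage string.

    Accepts rank-prefixed tokens (``g__Bacteroides``) or plain 7-rank
    kingdom→species lineages where genus is the 6th field.  Returns ``None``
    when no informative genus label is present.
    """
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        return None
    parts = [p.strip() for p in str(lineage).split(";")]
    for p in parts:
        for pref in GENUS_PREFIXES:
            if p.startswith(pref):
                name = p[len(pref):].strip()
                return name or None
    if len(parts) >= 6 and parts[5]:
        return parts[5]
    return None


def aggregate_to_genus(
    table: TaxaCountTable, keep_unclassified: bool = True
) -> TaxaCountTable:
    """Sum species-level counts into genera using the taxonomy lineage.

    Species without a genus label are pooled into an ``unclassified`` column
    (kept by default so per-sample depths are conserved for the multinomial
    model; pass ``keep_unclassified=False`` to drop them).
    """
    if table.lineage is None:
        raise ValueError("genus aggregation requires a taxonomy lineage")
    genera = {t: genus_from_lineage(table.lineage[t]) for t in table.taxon_ids}
    if all(g is None for g in genera.values()):
        raise ValueError("no genus rank found in any lineage")
    labels = [g if g is not None else UNCLASSIFIED_GENUS for g in genera.values()]
    grouped = table.counts.T.groupby(pd.Index(labels, name="genus"), sort=True).sum().T
    if not keep_unclassified and UNCLASSIFIED_GENUS in grouped.columns:
        grouped = grouped.drop(columns=[UNCLASSIFIED_GENUS])
    if UNCLASSIFIED_GENUS in grouped.columns:
        log.info(
            "pooled %d unclassified species into %r",
            sum(g is None for g in genera.values()),
            UNCLASSIFIED_GENUS,
        )
    return TaxaCountTable(grouped)


# ---------------------------------------------------------------------------
# EHR factor grouping
# ---------------------------------------------------------------------------

#: ATC hierarchy levels by code length; roll-up truncates to the parent length
_ATC_LEVEL_LEN = {5: 7, 4: 5, 3: 4}


@dataclass
class EHRGrouping:
    """Provenance of the EHR factor grouping step."""

    kept_diseases: list[str] = field(default_factory=list)
    dropped_diseases: dict[str, int] = field(default_factory=dict)
    drug_roll_up: dict[str, str] = field(default_factory=dict)
    dropped_drugs: dict[str, int] = field(default_factory=dict)


def _atc_parent(code: str) -> str | None:
    if len(code) == 7:
        return code[:5]
    if len(code) == 5:
        return code[:4]
    return None


def group_ehr_factors(
    ehr: EHRTables, sample_ids, min_cases: int = 20
) -> tuple[PhenotypeTable, EHRGrouping]:
    """Turn EHR tables into binary phenotype indicators.

    Disease indicators (one per 3-digit ICD-10 category) are kept only with at
    least ``min_cases`` cases.  Drug indicators are reported at the deepest
    ATC level reaching ``min_cases`` cases, rolling codes up level 5 → 4 → 3;
    codes that never reach the threshold are dropped.
    """
    sample_ids = [str(s) for s in sample_ids]
    id_set = set(sample_ids)
    cols: dict[str, pd.Series] = {}
    kinds: dict[str, str] = {}
    grouping = EHRGrouping()

    zero = pd.Series(0.0, index=pd.Index(sample_ids, name="sample_id"))
    for code, sub in ehr.prevalent.groupby("icd10"):
        ids = [s for s in sub["sample_id"].astype(str).unique() if s in id_set]
        if len(ids) >= min_cases:
            col = zero.copy()
            col.loc[ids] = 1.0
            cols[f"disease_{code}"] = col
            kinds[f"disease_{code}"] = "binary"
            grouping.kept_diseases.append(str(code))
        else:
            grouping.dropped_diseases[str(code)] = len(ids)

    # direct users per observed ATC code (finest recorded level)
    used = ehr.drugs[ehr.drugs["used"] == 1]
    direct: dict[str, set[str]] = {
        str(code): set(sub["sample_id"].astype(str)) & id_set
        for code, sub in used.groupby("atc")
    }

    # deep-to-shallow pass: a code keeps its level with >= min_cases users,
    # otherwise its users flow into the parent code (level 5 -> 4 -> 3)
    reported: dict[str, set[str]] = {}
    pool: dict[str, set[str]] = {}
    for length in (7, 6, 5, 4):
        codes = sorted(
            c for c in set(direct) | set(pool) if len(c) == length
        )
        for code in codes:
            ids = direct.get(code, set()) | pool.pop(code, set())
            if len(ids) >= min_cases:
                reported[code] = ids
            else:
                parent = _atc_parent(code)
                if parent is None:
                    grouping.dropped_drugs[code] = len(ids)
                else:
                    grouping.drug_roll_up[code] = parent
                    pool.setdefault(parent, set()).update(ids)
    for code, ids in sorted(reported.items()):
        col = zero.copy()
        col.loc[list(ids)] = 1.0
        cols[f"drug_{code}"] = col
        kinds[f"drug_{code}"] = "binary"

    if not cols:
        log.warning("EHR grouping produced no factors at min_cases=%d", min_cases)
        data = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    else:
        data = pd.DataFrame(cols)
    return PhenotypeTable(data, kinds), grouping
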