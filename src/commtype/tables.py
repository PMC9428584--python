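"""Core data containers: taxon count tables, phenotype tables, and EHR tables.

Count tables are stored samples-by-taxa as integer :class:`pandas.DataFrame`
objects with an optional per-taxon taxonomy lineage (semicolon-separated,
kingdom → species).  The on-disk format is TSV with taxa in rows, the first
column holding the taxon id and an optional ``taxonomy`` column, which is the
layout most taxonomic profilers emit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaxaCountTable",
    "PhenotypeTable",
    "EHRTables",
    "read_count_table",
    "write_count_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_ehr_tables",
    "write_ehr_tables",
]

FACTOR_KINDS = ("binary", "continuous", "categorical", "ordinal")
#: reserved covariate column names in a phenotype table
COVARIATE_NAMES = ("age", "gender", "bmi", "stool")

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}$")


@dataclass
class TaxaCountTable:
    """Samples × taxa non-negative integer count matrix with optional lineages.

    Parameters
    ----------
    counts:
        DataFrame indexed by sample id with taxon ids as columns.  Values must
        be finite, non-negative integers.
    lineage:
        Optional Series mapping taxon id to a semicolon-separated taxonomy
        string (``k__...;p__...;...;g__...;s__...`` or plain rank names).
    """

    counts: pd.DataFrame
    lineage: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise ValueError(f"duplicate taxon id: {dup!r}")
        arr = c.to_numpy()
        if not np.isfinite(arr).all():
            bad = c.columns[np.argwhere(~np.isfinite(arr))[0][1]]
            raise ValueError(f"non-finite count in taxon column {bad!r}")
        if (arr < 0).any():
            bad = c.columns[np.argwhere(arr < 0)[0][1]]
            raise ValueError(f"negative count in taxon column {bad!r}")
        if not np.allclose(arr, np.round(arr)):
            bad = c.columns[np.argwhere(~np.isclose(arr, np.round(arr)))[0][1]]
            raise ValueError(f"non-integer count in taxon column {bad!r}")
        if self.counts.to_numpy().dtype.kind != "i":
            self.counts = c.astype(np.int64)
        if self.lineage is not None:
            missing = [t for t in c.columns if t not in self.lineage.index]
            if missing:
                raise ValueError(f"lineage missing for taxa: {missing[:5]}")
            self.lineage = self.lineage.reindex(c.columns)

    # -- convenience --------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample total counts (sequencing depth at the table level)."""
        return self.counts.sum(axis=1)

    def proportions(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1; zero-depth → NaN)."""
        d = self.depths().to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts.to_numpy(dtype=float) / d[:, None]
        return pd.DataFrame(p, index=self.counts.index, columns=self.counts.columns)

    def subset_samples(self, sample_ids) -> "TaxaCountTable":
        return TaxaCountTable(self.counts.loc[list(sample_ids)].copy(), self.lineage)

    def subset_taxa(self, taxon_ids) -> "TaxaCountTable":
        lin = None if self.lineage is None else self.lineage.loc[list(taxon_ids)]
        return TaxaCountTable(self.counts[list(taxon_ids)].copy(), lin)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxaCountTable):
            return NotImplemented
        same_counts = self.counts.equals(other.counts)
        if self.lineage is None or other.lineage is None:
            return same_counts and (self.lineage is None) == (other.lineage is None)
        return same_counts and self.lineage.equals(other.lineage)


@dataclass
class PhenotypeTable:
    """Per-sample phenotype factors with declared measurement kinds.

    ``data`` holds one column per factor plus the reserved covariates
    (``age``, ``gender``, ``bmi``, ``stool``) when available.  ``kinds`` maps
    each non-covariate factor to one of ``binary | continuous | categorical |
    ordinal``.  Missing values stay as NaN and are never imputed.
    """

    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids in phenotype table")
        for name, kind in self.kinds.items():
            if kind not in FACTOR_KINDS:
                raise ValueError(f"unknown factor kind {kind!r} for {name!r}")
            if name not in self.data.columns:
                raise ValueError(f"declared factor {name!r} not in table")
            if kind == "binary":
                vals = self.data[name].dropna().unique()
                if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
                    raise ValueError(f"binary factor {name!r} not coded 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def factor_names(self) -> list[str]:
        return list(self.kinds)

    def covariates(self, names=COVARIATE_NAMES) -> pd.DataFrame:
        present = [n for n in names if n in self.data.columns]
        return self.data[present]


@dataclass
class EHRTables:
    """Electronic-health-record style tables in long format.

    prevalent: columns ``sample_id``, ``icd10`` (3-digit category, e.g. K29)
        and optional ``subcode`` (4-character subdiagnosis, e.g. K29.3).
    drugs: columns ``sample_id``, ``atc`` (4–7 character ATC code), ``used``
        (0/1) and optional ``n_prescriptions``.
    incident: columns ``sample_id``, ``disease_id``, ``time_years`` (≥ 0) and
        ``event`` (0/1).
    """

    prevalent: pd.DataFrame
    drugs: pd.DataFrame
    incident: pd.DataFrame

    def __post_init__(self) -> None:
        p, d, i = self.prevalent, self.drugs, self.incident
        if len(p):
            bad = [c for c in p["icd10"].unique() if not _ICD10_RE.match(str(c))]
            if bad:
                raise ValueError(f"malformed ICD-10 3-digit codes: {bad[:5]}")
        if len(d):
            bad = [c for c in d["atc"].unique() if not (4 <= len(str(c)) <= 7)]
            if bad:
                raise ValueError(f"ATC codes must be 4-7 characters: {bad[:5]}")
        if len(i) and (i["time_years"] < 0).any():
            raise ValueError("negative follow-up time in incident table")


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_count_table(path, orientation: str = "auto") -> TaxaCountTable:
    """Read a TSV count table.

    Parameters
    ----------
    path:
        Tab-separated file; ``#`` lines are comments.  Taxa-in-rows layout has
        the taxon id in the first column and an optional ``taxonomy`` column;
        samples-in-rows has the sample id first.
    orientation:
        ``"taxa_rows"``, ``"samples_rows"`` or ``"auto"``.  Auto-detection
        picks taxa-in-rows when a ``taxonomy`` column is present, otherwise it
        assumes the declared default of taxa in rows.
    """
    if orientation not in ("auto", "taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    # pandas silently renames duplicate header ids; catch them on the raw line
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                break
        else:
            raise ValueError("empty count table")
    seen: set[str] = set()
    for col in header:
        if col in seen and col != "taxonomy":
            raise ValueError(f"duplicate id in header: {col!r}")
        seen.add(col)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    lineage = None
    if "taxonomy" in df.columns:
        if orientation == "samples_rows":
            raise ValueError("taxonomy column implies taxa-in-rows layout")
        orientation = "taxa_rows"
        lineage = df.pop("taxonomy")
    if orientation == "auto":
        orientation = "taxa_rows"
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        col = numeric.columns[numeric.isna().any()][0]
        raise ValueError(f"non-numeric count cell in column {col!r}")
    if orientation == "taxa_rows":
        counts = numeric.T
    else:
        counts = numeric
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    counts.index.name = "sample_id"
    counts.columns.name = None
    if lineage is not None:
        lineage.index = lineage.index.astype(str)
    return TaxaCountTable(counts, lineage)


def write_count_table(table: TaxaCountTable, path) -> None:
    """Write taxa-in-rows TSV (first column taxon id, optional taxonomy)."""
    out = table.counts.T.copy()
    out.index.name = "taxon_id"
    if table.lineage is not None:
        out.insert(0, "taxonomy", table.lineage.reindex(out.index))
    out.to_csv(path, sep="\t")


def read_phenotype_table(path, kinds_path=None) -> PhenotypeTable:
    """Read a phenotype TSV plus its sidecar YAML of factor kinds."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    kinds: dict[str, str] = {}
    if kinds_path is None:
        kinds_path = Path(str(path)).with_suffix(".kinds.yaml")
    if Path(kinds_path).exists():
        with open(kinds_path) as fh:
            kinds = yaml.safe_load(fh) or {}
    return PhenotypeTable(df, kinds)


def write_phenotype_table(pheno: PhenotypeTable, path, kinds_path=None) -> None:
    df = pheno.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
    if kinds_path is None:
        kinds_path = Path(str(path)).with_suffix(".kinds.yaml")
    with open(kinds_path, "w") as fh:
        yaml.safe_dump(dict(pheno.kinds), fh, sort_keys=True)


def read_ehr_tables(prevalent_path, drugs_path, incident_path) -> EHRTables:
    read = lambda p: pd.read_csv(p, sep="\t", comment="#", dtype={"sample_id": str})
    return EHRTables(read(prevalent_path), read(drugs_path), read(incident_path))


def write_ehr_tables(ehr: EHRTables, prevalent_path, drugs_path, incident_path) -> None:
    ehr.prevalent.to_csv(prevalent_path, sep="\t", index=False)
    ehr.drugs.to_csv(drugs_path, sep="\t", index=False)
    ehr.incident.to_csv(incident_path, sep="\t", index=False)
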