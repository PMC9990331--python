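"""File contracts: tab-delimited expression matrices and comma-delimited tables.

Expression files store genes as rows (first column ``gene_id``, remaining
columns sample ids, tab-delimited) and round-trip bit-stably at 10
significant digits; in memory the matrix is samples x genes. Phenotype
files are CSV with columns ``subject_id,age,hba1c`` (extra columns are
ignored); rows with missing covariates are returned separately so the
complete-case filter is an explicit, visible step.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .allocation import BatchAssignment
from .cohort import Cohort

__all__ = [
    "read_expression",
    "write_expression",
    "read_phenotypes",
    "write_phenotypes",
    "write_cohort",
    "read_assignment",
    "write_assignment",
    "load_config",
]


def read_expression(path) -> pd.DataFrame:
    """Read a genes-as-rows TSV into a samples x genes DataFrame."""
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    if raw.shape[1] < 2 or raw.columns[0] != "gene_id":
        raise ValueError("expression file must start with a 'gene_id' column")
    if raw["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in expression file")
    if pd.Index(raw.columns[1:]).duplicated().any():
        raise ValueError("duplicate sample ids in expression file")
    mat = raw.set_index("gene_id").T
    mat.index.name = "subject_id"
    values = mat.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression file contains missing or non-finite values")
    return mat.astype(float)


def write_expression(expr: pd.DataFrame, path) -> None:
    """Write a samples x genes DataFrame as a genes-as-rows TSV (10 sig digits)."""
    out = expr.T
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_phenotypes(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a phenotype CSV; split into (complete, incomplete) record tables."""
    tab = pd.read_csv(path)
    if tab.empty:
        raise ValueError("phenotype file has no records")
    required = {"subject_id", "age", "hba1c"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"phenotype file missing columns: {sorted(missing)}")
    tab = tab[["subject_id", "age", "hba1c"]].copy()
    tab["subject_id"] = tab["subject_id"].astype(str)
    incomplete_mask = tab[["age", "hba1c"]].isna().any(axis=1)
    complete = tab.loc[~incomplete_mask].reset_index(drop=True)
    incomplete = tab.loc[incomplete_mask].reset_index(drop=True)
    return complete, incomplete


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False, float_format="%.10g")


def write_cohort(cohort: Cohort, path) -> None:
    """Write ``subject_id,group,selection_prob``."""
    out = cohort.to_frame()[["subject_id", "group", "selection_prob"]]
    out.to_csv(path, index=False, float_format="%.10g")


def write_assignment(assignment: BatchAssignment, path, cohort: Cohort | None = None) -> None:
    """Write ``subject_id[,group],batch``."""
    assignment.to_frame(cohort).to_csv(path, index=False)


def read_assignment(path) -> BatchAssignment:
    tab = pd.read_csv(path)
    required = {"subject_id", "batch"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"assignment file missing columns: {sorted(missing)}")
    batches = pd.Series(tab["batch"].to_numpy(dtype=int),
                        index=pd.Index(tab["subject_id"].astype(str)))
    strategy = str(tab["strategy"].iloc[0]) if "strategy" in tab.columns else "unknown"
    return BatchAssignment(batches=batches.sort_index(), strategy=strategy)


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg
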