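"""Readers and writers for the pipeline's delimited-text dialect.

One dialect throughout: tab-separated, header row, UTF-8, "." decimal,
empty string for missing values.  Samples are rows and CpGs are columns in
the beta matrix; the first column is always ``sample_id``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .qc import VALID_STATUSES
from .synthetic import SyntheticCohort

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "read_evidence",
    "write_evidence",
    "write_cohort",
    "write_table",
]

SEP = "\t"


def write_table(df: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=SEP, index=index, na_rep="")
    return path


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a samples-by-CpGs beta matrix; empty cells become NaN (missing).

    Values must be numeric and in [0, 1]; the error for an out-of-range
    value names the offending sample and CpG.  Duplicate sample ids error.
    """
    df = pd.read_csv(path, sep=SEP, index_col=0)
    df.index.name = "sample_id"
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric beta value in {path}: {exc}") from exc
    bad = (df < 0) | (df > 1)
    if bad.any().any():
        stacked = bad.stack()
        sample, cpg = stacked[stacked].index[0]
        raise ValueError(
            f"beta value out of [0, 1] at sample {sample!r}, CpG {cpg!r}: "
            f"{df.loc[sample, cpg]}"
        )
    return df


def write_beta_matrix(betas: pd.DataFrame, path) -> Path:
    return write_table(betas, path)


_NUMERIC_PHENO = (
    "age",
    "age_started",
    "age_stopped",
    "cigs_per_day",
    "cotinine",
    "cell_gran",
    "cell_lymph",
    "cell_mono",
)


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate the phenotype table.

    Status must be current/former/never or missing (empty).  Rows violating
    ``age_stopped <= age`` or ``age_started <= age_stopped`` are reported
    together, by sample id.
    """
    df = pd.read_csv(path, sep=SEP, index_col=0)
    df.index.name = "sample_id"
    if df.index.duplicated().any():
        raise ValueError(
            f"duplicate sample ids: {df.index[df.index.duplicated()].unique().tolist()}"
        )
    if "status" not in df.columns:
        raise ValueError("phenotype table must have a 'status' column")
    status = df["status"].astype(object).where(df["status"].notna(), np.nan)
    known = status.isin(VALID_STATUSES) | status.isna() | (status == "missing")
    if not known.all():
        bad = sorted(set(status[~known]))
        raise ValueError(
            f"unknown status tokens {bad}; allowed: {list(VALID_STATUSES)} or empty"
        )
    df["status"] = status.where(status != "missing", np.nan)
    for col in _NUMERIC_PHENO:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    offenders = []
    if {"age", "age_stopped"} <= set(df.columns):
        bad = df["age_stopped"] > df["age"]
        offenders += [(i, "age_stopped > age") for i in df.index[bad.fillna(False)]]
    if {"age_started", "age_stopped"} <= set(df.columns):
        bad = df["age_started"] > df["age_stopped"]
        offenders += [(i, "age_started > age_stopped") for i in df.index[bad.fillna(False)]]
    if offenders:
        raise ValueError(f"invalid phenotype rows: {offenders}")
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path) -> Path:
    return write_table(phenotypes, path)


def read_evidence(path) -> pd.DataFrame:
    """Read an EWAS-evidence table (cpg_id, study_id, delta_beta)."""
    df = pd.read_csv(path, sep=SEP)
    required = {"cpg_id", "study_id", "delta_beta"}
    if not required <= set(df.columns):
        raise ValueError(
            f"evidence table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    df["delta_beta"] = pd.to_numeric(df["delta_beta"], errors="raise")
    return df


def write_evidence(evidence: pd.DataFrame, path) -> Path:
    return write_table(evidence, path, index=False)


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write a synthetic cohort as the three delimited-text pipeline inputs
    (plus the per-CpG truth)."""
    directory = Path(directory)
    return {
        "beta_matrix": write_table(cohort.betas, directory / "beta_matrix.tsv"),
        "phenotypes": write_table(cohort.phenotypes, directory / "phenotypes.tsv"),
        "truth": write_table(cohort.truth, directory / "truth.tsv"),
        "cpg_truth": write_table(cohort.cpg_truth, directory / "cpg_truth.tsv"),
    }
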