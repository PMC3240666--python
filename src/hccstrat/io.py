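"""Table I/O and cohort loading with schema validation.

All tables are tab-separated with a header row; expression and genotype
matrices store patients in columns, in the same order across files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import PlantedTruth, SimulationConfig, SyntheticCohort

__all__ = ["SchemaError", "read_clinical", "read_outcome", "read_matrix",
           "read_positions", "read_gene_list", "load_cohort",
           "load_tables"]

CLINICAL_COLUMNS = ("age", "sex", "tumor_size", "NOTN", "AFP", "ALBU",
                    "venous_infiltration", "pTNM", "AJCC")


class SchemaError(ValueError):
    """A table failed validation; the message names file and location."""


def _read_tsv(path, index_col=0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    return pd.read_csv(path, sep="\t", index_col=index_col,
                       float_precision="round_trip")


def read_clinical(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing clinical column(s) {missing}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][:5]
        raise SchemaError(f"{path}: duplicated patient id(s) {list(dup)}")
    return df[list(CLINICAL_COLUMNS) +
              [c for c in df.columns if c not in CLINICAL_COLUMNS]]


def read_outcome(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("time", "event"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
        if not np.issubdtype(df[col].dtype, np.number):
            raise SchemaError(f"{path}: column {col!r} is not numeric")
    if (df["time"] <= 0).any() or not np.isfinite(df["time"]).all():
        raise SchemaError(f"{path}: times must be positive and finite")
    if not df["event"].isin([0, 1]).all():
        raise SchemaError(f"{path}: event must be 0/1")
    return df[["time", "event"]]


def read_matrix(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.index.duplicated().any():
        raise SchemaError(f"{path}: duplicated row id(s)")
    bad = df.columns[~df.apply(
        lambda c: np.issubdtype(c.dtype, np.number))]
    if len(bad):
        raise SchemaError(f"{path}: non-numeric column(s) {list(bad)[:5]}")
    if not np.isfinite(df.to_numpy()).all():
        raise SchemaError(f"{path}: non-finite values present")
    return df


def read_positions(path, kind="snp") -> pd.DataFrame:
    df = _read_tsv(path)
    cols = ("chrom", "bp") if kind == "snp" else ("chrom", "tss")
    for col in cols:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    if df.index.duplicated().any():
        raise SchemaError(f"{path}: duplicated position id(s)")
    return df[list(cols)]


def read_gene_list(path) -> list:
    """Plain text, one gene symbol per line; blanks ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def load_tables(paths: dict) -> dict:
    """Load and cross-validate a set of tables.

    ``paths`` maps logical names (clinical, survival, dfs, expr_tumor,
    expr_normal, genotypes, snp_pos, gene_pos) to file paths; any subset
    may be given, but patient ids must align across every table present.
    """
    readers = {
        "clinical": read_clinical,
        "survival": read_outcome,
        "dfs": read_outcome,
        "expr_tumor": read_matrix,
        "expr_normal": read_matrix,
        "genotypes": read_matrix,
        "snp_pos": lambda p: read_positions(p, "snp"),
        "gene_pos": lambda p: read_positions(p, "gene"),
    }
    out = {}
    for name, path in paths.items():
        if name not in readers:
            raise SchemaError(f"unknown table name {name!r}")
        out[name] = readers[name](path)

    patient_axes = {
        "clinical": lambda df: df.index,
        "survival": lambda df: df.index,
        "dfs": lambda df: df.index,
        "expr_tumor": lambda df: df.columns,
        "expr_normal": lambda df: df.columns,
        "genotypes": lambda df: df.columns,
    }
    ref_name = next((n for n in patient_axes if n in out), None)
    if ref_name is not None:
        ref = set(patient_axes[ref_name](out[ref_name]))
        for name, axis in patient_axes.items():
            if name not in out or name == ref_name:
                continue
            ids = set(axis(out[name]))
            if ids != ref:
                diff = sorted(ids ^ ref)[:5]
                raise SchemaError(
                    f"patient ids of {name!r} do not match {ref_name!r}; "
                    f"e.g. {diff}")
    return out


def load_cohort(directory) -> SyntheticCohort:
    """Load the standard TSV layout written by ``SyntheticCohort.write``."""
    d = Path(directory)
    paths = {name: d / f"{name}.tsv" for name in
             ("clinical", "survival", "dfs", "expr_tumor", "expr_normal",
              "genotypes", "snp_pos", "gene_pos")}
    tables = load_tables({k: v for k, v in paths.items() if v.exists()})
    truth_file = d / "truth.json"
    truth = PlantedTruth.from_json(truth_file.read_text()) \
        if truth_file.exists() else PlantedTruth()
    return SyntheticCohort(
        clinical=tables["clinical"], survival=tables["survival"],
        dfs=tables.get("dfs"), expr_tumor=tables.get("expr_tumor"),
        expr_normal=tables.get("expr_normal"),
        genotypes=tables.get("genotypes"),
        snp_pos=tables.get("snp_pos"), gene_pos=tables.get("gene_pos"),
        truth=truth, config=SimulationConfig())
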