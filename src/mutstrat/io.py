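"""Readers and writers for the flat-file formats used by the pipeline.

All tables travel as TSV: the mutation matrix is samples x genes with 0/1
entries, the clinical table carries `sample_id`, `os_months`, `os_event`
plus optional covariates, and the interaction network is a three-column
edge list (gene1, gene2, combined score on the STRING 0-1000 scale).
Gene-set collections use the GMT dialect: name, description, then one gene
id per tab-separated field.
"""

from __future__ import annotations

import os

import pandas as pd

from .errors import DataError, ParseError

__all__ = [
    "read_mutation_matrix",
    "write_mutation_matrix",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "read_matrix",
    "write_matrix",
]


def read_mutation_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a binary sample x gene mutation matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise DataError(f"empty mutation matrix: {path}")
    values = df.to_numpy()
    if not ((values == 0) | (values == 1)).all():
        raise DataError("mutation matrix entries must be 0/1")
    return df.astype("int8")


def write_mutation_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_clinical(path: str | os.PathLike) -> pd.DataFrame:
    """Read the clinical table; requires sample_id, os_months, os_event."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "os_months", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"clinical table missing columns: {sorted(missing)}")
    return df.set_index("sample_id")


def write_clinical(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered {set name: gene list} mapping."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("GMT line needs name, description, >=1 gene", lineno)
            name = fields[0]
            if name in sets:
                raise ParseError(f"duplicate gene-set name {name!r}", lineno)
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ParseError(f"gene set {name!r} is empty", lineno)
            sets[name] = genes
    if not sets:
        raise DataError(f"no gene sets in {path}")
    return sets


def write_gmt(
    sets: dict[str, list[str]], path: str | os.PathLike, description: str = "na"
) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a generic samples-by-features TSV with a sample_id index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | os.PathLike, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", index_label="sample_id", float_format=float_format)
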