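"""Readers and writers for the pipeline's TSV/GMT dialects.

Abundance TSV: first column ``protein_id``, remaining columns sample ids,
``NA`` for missing, UTF-8, tab-separated.  Clinical TSV: columns
``sample_id, group, batch, os_months, os_event`` plus optional covariates.
GMT: one set per line — name, description, then tab-separated members.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, InputContractError
from .stats import GeneSetCollection

__all__ = [
    "read_abundance",
    "write_abundance",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_matrix_tsv",
]

REQUIRED_CLINICAL = ["sample_id", "os_months", "os_event"]


class ParseError(ValueError):
    pass


def read_abundance(path, clinical: pd.DataFrame | None = None) -> AbundanceMatrix:
    """Load an abundance TSV; attaches batch labels from `clinical` if given."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={0: str})
    if df.columns[0] != "protein_id":
        raise ParseError(f"{path}: first column must be 'protein_id', got {df.columns[0]!r}")
    df = df.set_index("protein_id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate protein ids {dups[:5]}")
    if df.columns.has_duplicates:
        raise ParseError(f"{path}: duplicate sample ids")
    bad_cols = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad_cols:
        for c in bad_cols:
            bad = df[c][pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()]
            if len(bad):
                line = df.index.get_loc(bad.index[0]) + 2  # header is line 1
                raise ParseError(f"{path}: non-numeric cell {bad.iloc[0]!r} "
                                 f"in column {c!r} (line {line})")
        df = df.apply(pd.to_numeric)
    batch = None
    if clinical is not None:
        missing = df.columns.difference(clinical["sample_id"])
        if len(missing):
            raise ParseError(f"samples without clinical rows: {list(missing)[:5]}")
        batch = clinical.set_index("sample_id")["batch"].reindex(df.columns)
    return AbundanceMatrix(df, batch)


def write_abundance(matrix: AbundanceMatrix, path, full_precision: bool = False) -> None:
    out = matrix.values.copy()
    out.index.name = "protein_id"
    fmt = None if full_precision else "%.6g"
    out.to_csv(path, sep="\t", na_rep="NA", float_format=fmt)


def read_clinical(path) -> pd.DataFrame:
    """Load a clinical annotation TSV and validate the survival columns."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in REQUIRED_CLINICAL if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    ev = df["os_event"].dropna()
    if not ev.isin([0, 1]).all():
        bad = sorted(ev[~ev.isin([0, 1])].unique().tolist())
        raise ParseError(f"{path}: os_event must be 0/1, found {bad}")
    if (df["os_months"].dropna() < 0).any():
        raise ParseError(f"{path}: negative os_months")
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index=False)


def write_matrix_tsv(df: pd.DataFrame, path, index_name: str,
                     full_precision: bool = False) -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", na_rep="NA",
               float_format=None if full_precision else "%.6g")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file into a GeneSetCollection."""
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{ln}: GMT line needs name, description, members")
        name, description, members = parts[0], parts[1], [m for m in parts[2:] if m]
        if name in sets:
            raise ParseError(f"{path}:{ln}: duplicate set name {name!r}")
        if not members:
            raise ParseError(f"{path}:{ln}: set {name!r} has no members")
        sets[name] = set(members)
        desc[name] = description
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=desc)
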