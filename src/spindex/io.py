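"""Readers and writers for the pipeline's tab-delimited file dialects.

All tables are UTF-8, tab-delimited, with a header row; missing values are
spelled ``NA``.  Count files carry entity ids in the first column (plus a
``gene_id`` column for exon files) and one integer column per sample.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrix import CountMatrix, Design, ExonCountMatrix

__all__ = [
    "read_sample_sheet",
    "read_counts",
    "write_table",
    "load_config_file",
    "ParseError",
]

NA_REP = "NA"


class ParseError(ValueError):
    pass


def read_sample_sheet(path, group_a: str | None = None, group_b: str | None = None) -> Design:
    """Read ``sample_id <TAB> group`` and build the two-group design.

    When the group labels are not given, the group of the first sample is
    the fold-change numerator (group A) and the other group the denominator.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise ParseError(f"{path}: expected columns 'sample_id', 'group'")
    groups = pd.Series(df["group"].to_numpy(), index=df["sample_id"], name="group")
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ParseError(f"{path}: need exactly two groups, found {labels}")
    if group_a is None:
        group_a = labels[0]
    if group_b is None:
        group_b = next(l for l in labels if l != group_a)
    return Design(groups=groups, group_a=group_a, group_b=group_b)


def _parse_int_block(df: pd.DataFrame, path, header_lines: int = 1) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals.fillna(0)))
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ParseError(
                f"{path}:{row + header_lines + 1}: non-integer count "
                f"{df[col].iloc[row]!r} in column {col!r}"
            )
        out[col] = vals.astype(np.int64)
    return pd.DataFrame(out, index=df.index)


def read_counts(path, design: Design) -> CountMatrix | ExonCountMatrix:
    """Read a count TSV; returns an exon matrix when a ``gene_id`` column
    follows the id column, a gene matrix otherwise.

    Errors (non-integer cells, duplicate ids, samples missing from the
    sample sheet) raise :class:`ParseError` with the offending line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need an id column plus sample columns")
    id_col = df.columns[0]
    df = df.set_index(id_col)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        row = int(np.nonzero(df.index.duplicated().astype(bool))[0][0])
        raise ParseError(f"{path}:{row + 2}: duplicate id {dup!r}")
    is_exon = df.columns[0] == "gene_id"
    gene_of = None
    if is_exon:
        gene_of = pd.Series(df["gene_id"].to_numpy(), index=df.index, name="gene_id")
        df = df.drop(columns="gene_id")
    missing = [c for c in df.columns if c not in design.groups.index]
    if missing:
        raise ParseError(f"{path}: samples not in sample sheet: {missing}")
    counts = _parse_int_block(df, path)
    if is_exon:
        return ExonCountMatrix(counts=counts, gene_of=gene_of, design=design)
    return CountMatrix(counts=counts, design=design)


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    """Write a results table: TSV, UTF-8, header, NA spelled ``NA``."""
    df.to_csv(path, sep="\t", na_rep=NA_REP, index=True, index_label=index_label)


def load_config_file(path) -> dict:
    """Read a YAML (or plain ``key: value``) configuration file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping of keys to values")
    return data
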