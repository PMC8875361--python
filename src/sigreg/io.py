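"""Tabular input/output with validation: count matrices, sample tables,
and gene-exclusion lists.

All files are plain TSV (tab separator, UTF-8, no quoting, '.' decimal).
The count-matrix header cell (0,0) is fixed to ``gene_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_SAMPLE_COLUMNS = ["strain", "condition", "replicate"]


@dataclass(frozen=True)
class ExclusionList:
    """Genes to drop before differential expression (e.g. the rRNA operons),
    with a free-text reason."""

    gene_ids: tuple
    reason: str = ""


def _check_duplicates(labels: pd.Index, what: str, path) -> None:
    dup = labels[labels.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate {what} id(s) in {path}: {', '.join(map(str, dup[:5]))}")


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples count matrix from TSV.

    The first column holds gene ids, the header row sample ids.  Every cell
    must be a nonnegative integer; violations raise with the offending gene
    and sample named.  Row and column order are preserved from the file.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    _check_duplicates(df.index, "gene", path)
    _check_duplicates(df.columns, "sample", path)

    values = np.empty(df.shape, dtype=np.int64)
    for j, sample in enumerate(df.columns):
        col = pd.to_numeric(df[sample], errors="coerce")
        bad = col.isna() | (col < 0) | (col != np.floor(col))
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: cell (gene {gene!r}, sample {sample!r}) is not a "
                f"nonnegative integer: {df.at[gene, sample]!r}"
            )
        values[:, j] = col.astype(np.int64)
    return pd.DataFrame(values, index=df.index, columns=df.columns)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_table(path) -> pd.DataFrame:
    """Read the sample design table (sample_id, strain, condition, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "strain": str,
                                            "condition": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df = df.set_index("sample_id")
    _check_duplicates(df.index, "sample", path)
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        raise ValueError(f"{path}: replicate numbers must be positive")
    return df


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def validate_design(counts: pd.DataFrame, samples: pd.DataFrame,
                    min_replicates: int = 2) -> None:
    """Check that every count column is described and every group is testable."""
    missing = set(counts.columns) - set(samples.index)
    if missing:
        raise ValueError(f"samples table lacks entries for: {sorted(missing)[:5]}")
    sizes = samples.loc[list(counts.columns)].groupby(
        ["strain", "condition"], observed=True
    ).size()
    thin = sizes[sizes < min_replicates]
    if len(thin):
        groups = ", ".join(f"{s}/{c}" for s, c in thin.index)
        raise ValueError(
            f"group(s) with fewer than {min_replicates} replicates: {groups}"
        )


def read_exclusions(path) -> ExclusionList:
    """Read an exclusion list: one gene id per line, optional second
    tab-separated column giving the reason (first reason found is kept)."""
    genes, reason = [], ""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            genes.append(parts[0])
            if len(parts) > 1 and not reason:
                reason = parts[1]
    return ExclusionList(tuple(genes), reason)


def apply_exclusions(counts: pd.DataFrame, *lists: ExclusionList) -> pd.DataFrame:
    """Drop listed genes from the matrix.

    Genes absent from the matrix are logged, not fatal; removing every gene
    is a hard error.  Idempotent: re-applying the same lists is a no-op.
    """
    to_drop: set = set()
    for lst in lists:
        present = set(lst.gene_ids) & set(counts.index)
        absent = set(lst.gene_ids) - set(counts.index)
        if absent:
            logger.warning(
                "exclusion list (%s): %d gene(s) not in matrix: %s",
                lst.reason or "no reason", len(absent),
                ", ".join(sorted(absent)[:5]),
            )
        to_drop |= present
    if to_drop:
        logger.info("excluding %d gene(s) before analysis", len(to_drop))
    kept = counts.drop(index=sorted(to_drop))
    if kept.shape[0] == 0:
        raise ValueError("exclusion lists would remove every gene")
    return kept
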