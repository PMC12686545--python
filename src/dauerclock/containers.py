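"""Tabular containers and TSV readers/writers shared across the toolkit.

Counts, sample metadata, gene annotation and simulation ground truth all
live in plain :class:`pandas.DataFrame` objects with fixed column
conventions, so every stage of the pipeline can be driven from files on
disk or from in-memory frames interchangeably.

Conventions
-----------
counts
    genes x samples, index ``gene_id``, non-negative integers.
metadata
    one row per sample: ``sample_id``, ``group``, ``timepoint_h``,
    ``median_lifespan_h``.
genes
    one row per gene: ``gene_id``, ``length_bp`` and optionally
    ``chrom``, ``start``, ``end`` (1-based inclusive coordinates).
truth
    one row per gene: ``gene_id``, ``program``, ``true_slope``,
    ``retention``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

METADATA_COLUMNS = ["sample_id", "group", "timepoint_h", "median_lifespan_h"]
TRUTH_COLUMNS = ["gene_id", "program", "true_slope", "retention"]


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a counts frame (genes x samples) for the expected shape.

    Raises ``ValueError`` on negative or non-finite entries or duplicated
    gene/sample identifiers; returns the (unmodified) frame for chaining.
    """
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene ids in counts: {dups[:5]}")
    if counts.columns.has_duplicates:
        dups = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample ids in counts: {dups[:5]}")
    values = counts.to_numpy()
    if not np.isfinite(values).all():
        raise ValueError("counts contain non-finite values")
    if (values < 0).any():
        raise ValueError("counts contain negative values")
    return counts


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene-by-sample count TSV (first column = gene id)."""
    path = _existing(path)
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    return validate_counts(counts)


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    frame = counts.copy()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    path = _existing(path)
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file {path} missing columns: {missing}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_genes(path: str | os.PathLike) -> pd.DataFrame:
    """Read gene annotation; derives ``length_bp`` from coordinates if absent."""
    path = _existing(path)
    genes = pd.read_csv(path, sep="\t")
    if "gene_id" not in genes.columns:
        raise ValueError(f"gene annotation {path} lacks a gene_id column")
    if "length_bp" not in genes.columns:
        if {"start", "end"} <= set(genes.columns):
            genes["length_bp"] = genes["end"] - genes["start"] + 1
        else:
            raise ValueError(
                f"gene annotation {path} needs length_bp or start/end columns"
            )
    if (genes["length_bp"] <= 0).any():
        bad = genes.loc[genes["length_bp"] <= 0, "gene_id"].tolist()
        raise ValueError(f"non-positive gene lengths for: {bad[:5]}")
    return genes


def write_genes(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    path = _existing(path)
    truth = pd.read_csv(path, sep="\t")
    missing = [c for c in TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise ValueError(f"truth file {path} missing columns: {missing}")
    return truth


def write_truth(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False)


def gene_lengths(genes: pd.DataFrame) -> dict[str, float]:
    """Map gene_id -> length in bp from an annotation frame."""
    return dict(zip(genes["gene_id"], genes["length_bp"].astype(float)))


def _existing(path: str | os.PathLike) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"required input file not found: {p}")
    return p
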