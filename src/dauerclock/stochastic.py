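"""Stochastic-drift aging clock.

Conceptually distinct from the regression clock: instead of learning a
weighted signature, this clock counts how many of a fixed panel of
"drift" genes — genes that are off in young animals and switch on with
increasing probability as random transcriptional changes accumulate —
are in the on state in a sample. The per-sample pipeline is

1. ``log10(count + 1)`` transform,
2. min-max normalization of the sample to [0, 1],
3. binarization against the median of the nonzero normalized values
   (strictly greater -> 1), and
4. summation over the clock gene panel.

Whether the published procedure sums the binarized states or the
min-max-normalized values is ambiguous; the default here sums binarized
states and ``mode="normalized"`` sums the normalized values instead for
sensitivity analysis.

Gene selection on training data is this package's own concretization:
candidate genes whose consensus state in the youngest age group is 0
are ranked by the slope of their mean binarized state against age, and
the top ``n_genes`` with positive slope form the panel (ties broken by
gene id).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class StochasticClockModel:
    """Ordered gene panel plus the fixed transform parameters."""

    clock_genes: list[str]
    meta: dict = field(default_factory=dict)
    pseudocount: float = 1.0
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if not self.clock_genes:
            raise ValueError("clock_genes must be non-empty")
        if len(set(self.clock_genes)) != len(self.clock_genes):
            raise ValueError("clock_genes must be unique")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"clock_genes": list(self.clock_genes), "meta": self.meta},
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StochasticClockModel":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            text = Path(source).read_text()
        else:
            text = source
        payload = json.loads(text)
        return cls(clock_genes=list(payload["clock_genes"]), meta=payload.get("meta", {}))


def normalize_sample(counts_column: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """log10(x + 1) then min-max scale one sample's counts into [0, 1]."""
    values = np.asarray(counts_column, dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    logged = np.log10(values + 1.0)
    lo, hi = logged.min(), logged.max()
    if hi == lo:
        raise ValueError("sample is constant; min-max normalization undefined")
    scaled = (logged - lo) / (hi - lo)
    if isinstance(counts_column, pd.Series):
        return pd.Series(scaled, index=counts_column.index)
    return scaled


def _binarize_normalized(normalized: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Strict-median binarization over the nonzero-count genes."""
    nonzero = counts > 0
    if not nonzero.any():
        raise ValueError("sample has all-zero counts; median undefined")
    threshold = np.median(normalized[nonzero])
    return ((normalized > threshold) & nonzero).astype(np.int8)


def stochastic_score(
    counts_column: pd.Series,
    model: StochasticClockModel,
    mode: str = "binarized",
) -> float:
    """Clock score of one sample: sum over the clock gene panel.

    ``mode="binarized"`` (default) sums the 0/1 states, giving a score
    in ``[0, len(clock_genes)]``; ``mode="normalized"`` sums the
    min-max-normalized values instead. Clock genes missing from the
    sample contribute 0 and are logged.
    """
    if mode not in ("binarized", "normalized"):
        raise ValueError("mode must be 'binarized' or 'normalized'")
    if not isinstance(counts_column, pd.Series):
        raise TypeError("counts_column must be a pandas Series indexed by gene id")
    normalized = normalize_sample(counts_column)
    genes = pd.Index(model.clock_genes)
    present = genes.intersection(counts_column.index)
    if len(present) < len(genes):
        logger.warning(
            "%d of %d clock genes absent from sample; treated as 0",
            len(genes) - len(present),
            len(genes),
        )
    if mode == "normalized":
        return float(normalized.loc[present].sum())
    states = _binarize_normalized(
        normalized.to_numpy(), counts_column.to_numpy(dtype=float)
    )
    state_series = pd.Series(states, index=counts_column.index)
    return float(state_series.loc[present].sum())


def score_matrix(
    counts: pd.DataFrame, model: StochasticClockModel, mode: str = "binarized"
) -> pd.Series:
    """Stochastic clock score for every sample (column) of a count matrix."""
    return pd.Series(
        {s: stochastic_score(counts[s], model, mode=mode) for s in counts.columns},
        name="stochastic_score",
    )


def select_clock_genes(
    training_counts: pd.DataFrame,
    ages: Sequence[float] | pd.Series,
    n_genes: int,
) -> StochasticClockModel:
    """Pick the genes that switch on most strongly with age.

    A gene is a candidate if the majority of samples in the youngest age
    group have it in state 0 after normalize-and-binarize. Candidates
    are ranked by the ordinary least-squares slope of their mean
    binarized state per age group against age; the ``n_genes`` largest
    positive slopes win, ties broken lexicographically by gene id.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be > 0")
    ages = np.asarray(
        ages.reindex(training_counts.columns) if isinstance(ages, pd.Series) else ages,
        dtype=float,
    )
    if ages.size != training_counts.shape[1]:
        raise ValueError("one age per training sample is required")
    unique_ages = np.unique(ages)
    if unique_ages.size < 2:
        raise ValueError("at least two distinct age groups are required")

    states = np.zeros(training_counts.shape, dtype=np.int8)
    raw = training_counts.to_numpy(dtype=float)
    for j in range(training_counts.shape[1]):
        normalized = np.log10(raw[:, j] + 1.0)
        lo, hi = normalized.min(), normalized.max()
        if hi == lo:
            raise ValueError(
                f"sample {training_counts.columns[j]!r} is constant; cannot normalize"
            )
        normalized = (normalized - lo) / (hi - lo)
        states[:, j] = _binarize_normalized(normalized, raw[:, j])

    group_means = np.column_stack(
        [states[:, ages == a].mean(axis=1) for a in unique_ages]
    )
    youngest_off = group_means[:, 0] < 0.5  # majority state 0 in youngest group

    t = unique_ages - unique_ages.mean()
    slopes = group_means @ t / (t @ t)

    candidates = pd.DataFrame(
        {"gene_id": training_counts.index, "slope": slopes, "off_young": youngest_off}
    )
    candidates = candidates[(candidates["off_young"]) & (candidates["slope"] > 0)]
    if n_genes > len(candidates):
        raise ValueError(
            f"n_genes={n_genes} exceeds the {len(candidates)} eligible candidates"
        )
    chosen = candidates.sort_values(
        ["slope", "gene_id"], ascending=[False, True], kind="mergesort"
    ).head(n_genes)
    return StochasticClockModel(
        clock_genes=chosen["gene_id"].tolist(),
        meta={
            "n_candidates": int(len(candidates)),
            "age_groups": unique_ages.tolist(),
            "selection": "max positive slope of mean binarized state vs age",
        },
    )
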