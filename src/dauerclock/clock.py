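"""Binarized-transcriptome biological age clock.

The clock operates on binarized expression: within each sample, genes
expressed strictly above the median of that sample's *nonzero* values
are set to 1, all others (including zero-count genes) to 0. Training is
an elastic-net linear regression of biological age — chronological age
rescaled by the ratio of a reference lifespan to the cohort's median
lifespan — on the binary gene states; prediction sums the coefficients
of the clock genes in state 1 and adds the intercept. The ratio of the
change in predicted biological age to the elapsed chronological time is
the (dimensionless) aging rate.

The modelling API follows the statsmodels convention: build a
:class:`BinarizedClock` from data, call :meth:`~BinarizedClock.fit` and
work with the returned :class:`ClockResults` (coefficients, predictions,
``summary()``, JSON round-trip). Thin functional wrappers
(:func:`train_clock`, :func:`predict_age`) cover script use.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV

logger = logging.getLogger(__name__)


def binarize(counts: pd.DataFrame) -> pd.DataFrame:
    """Binarize a genes-x-samples matrix per sample.

    For each sample the threshold is the median of its nonzero values;
    a gene maps to 1 iff its value is strictly greater than the
    threshold. Zero-count genes are excluded from the median and always
    map to 0. A sample with no nonzero gene has no defined median and
    raises ``ValueError`` naming the sample.
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    out = np.zeros_like(values, dtype=np.int8)
    for j, sample in enumerate(counts.columns):
        col = values[:, j]
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {sample!r} has all-zero counts; median undefined")
        threshold = np.median(nonzero)
        out[:, j] = (col > threshold).astype(np.int8)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def rescale_biological_age(
    chronological_age_h: float | np.ndarray,
    cohort_median_lifespan_h: float | np.ndarray,
    reference_lifespan_h: float,
) -> float | np.ndarray:
    """Map chronological age onto a common biological timescale.

    biological age = chronological age * reference_lifespan / cohort_lifespan,
    so a cohort living twice as long as the reference ages at half speed.
    """
    cohort = np.asarray(cohort_median_lifespan_h, dtype=float)
    if np.any(cohort <= 0) or reference_lifespan_h <= 0:
        raise ValueError("lifespans must be > 0")
    result = np.asarray(chronological_age_h, dtype=float) * (
        reference_lifespan_h / cohort
    )
    if np.isscalar(chronological_age_h) and result.ndim == 0:
        return float(result)
    return result


def aging_rate(
    pba_start_h: float,
    pba_end_h: float,
    chrono_start_h: float,
    chrono_end_h: float,
) -> float:
    """Biological hours aged per chronological hour between two timepoints."""
    span = chrono_end_h - chrono_start_h
    if span <= 0:
        raise ValueError("chronological span must be positive")
    return (pba_end_h - pba_start_h) / span


class BinarizedClock:
    """Elastic-net clock model on binarized expression states.

    Parameters
    ----------
    binarized
        genes x samples matrix of {0, 1} states (see :func:`binarize`).
    biological_ages_h
        per-sample biological age labels in hours, aligned with the
        matrix columns (a mapping, Series or array in column order).
    """

    def __init__(
        self,
        binarized: pd.DataFrame,
        biological_ages_h: Mapping[str, float] | pd.Series | np.ndarray,
    ) -> None:
        values = binarized.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("binarized matrix must contain only 0/1 values")
        if isinstance(biological_ages_h, pd.Series):
            ages = biological_ages_h.reindex(binarized.columns)
            if ages.isna().any():
                missing = ages.index[ages.isna()].tolist()
                raise ValueError(f"missing age labels for samples: {missing[:5]}")
            y = ages.to_numpy(dtype=float)
        elif isinstance(biological_ages_h, Mapping):
            try:
                y = np.array([biological_ages_h[s] for s in binarized.columns], float)
            except KeyError as exc:
                raise ValueError(f"missing age label for sample {exc}") from exc
        else:
            y = np.asarray(biological_ages_h, dtype=float)
            if y.size != binarized.shape[1]:
                raise ValueError("one age label per sample is required")
        if np.unique(y).size < 2:
            raise ValueError("age labels are constant; nothing to regress on")
        self.binarized = binarized
        self.ages_h = y

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        metadata: pd.DataFrame,
        reference_lifespan_h: float | None = None,
    ) -> "BinarizedClock":
        """Binarize counts and derive biological-age labels from metadata.

        ``metadata`` needs ``sample_id``, ``timepoint_h`` and
        ``median_lifespan_h`` columns; the reference lifespan defaults to
        the mean of the cohort median lifespans.
        """
        meta = metadata.set_index("sample_id").loc[list(counts.columns)]
        if reference_lifespan_h is None:
            reference_lifespan_h = float(meta["median_lifespan_h"].mean())
        ages = rescale_biological_age(
            meta["timepoint_h"].to_numpy(dtype=float),
            meta["median_lifespan_h"].to_numpy(dtype=float),
            reference_lifespan_h,
        )
        return cls(binarize(counts), pd.Series(ages, index=counts.columns))

    def fit(
        self,
        cv_folds: int = 5,
        seed: int = 0,
        l1_ratio: float = 0.5,
        max_iter: int = 10_000,
    ) -> "ClockResults":
        """Fit the elastic net with the penalty chosen by cross-validation.

        Cross-validation minimizes mean squared error over an automatic
        penalty path; only genes with nonzero coefficients are retained
        in the resulting clock. Deterministic for a fixed ``seed``.
        """
        n_samples = self.binarized.shape[1]
        if cv_folds > n_samples:
            raise ValueError(
                f"cv_folds={cv_folds} exceeds the {n_samples} available samples"
            )
        X = self.binarized.to_numpy(dtype=float).T
        model = ElasticNetCV(
            l1_ratio=l1_ratio,
            cv=cv_folds,
            random_state=seed,
            max_iter=max_iter,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter on tiny folds
            model.fit(X, self.ages_h)
        coef = pd.Series(model.coef_, index=self.binarized.index)
        coef = coef[coef != 0.0]
        meta = {
            "seed": seed,
            "cv_folds": cv_folds,
            "l1_ratio": l1_ratio,
            "alpha": float(model.alpha_),
            "n_training_samples": n_samples,
        }
        return ClockResults(
            coefficients=coef, intercept=float(model.intercept_), meta=meta
        )


@dataclass
class ClockResults:
    """A fitted (or loaded) clock: sparse gene coefficients + intercept.

    Prediction for a binarized sample is the sum of coefficients over
    clock genes in state 1, plus the intercept (hours).
    """

    coefficients: pd.Series
    intercept: float
    meta: dict

    @property
    def n_genes(self) -> int:
        return int((self.coefficients != 0).sum())

    def predict(self, binarized: pd.DataFrame) -> pd.Series:
        """Predicted biological age (h) for each column of a binarized matrix.

        Clock genes absent from the query matrix are treated as state 0;
        a warning is logged naming how many were missing.
        """
        genes = self.coefficients.index
        present = genes.intersection(binarized.index)
        missing = len(genes) - len(present)
        if missing:
            logger.warning(
                "%d of %d clock genes absent from query matrix; treated as state 0",
                missing,
                len(genes),
            )
        states = binarized.loc[present].to_numpy(dtype=float)
        pba = self.coefficients.loc[present].to_numpy() @ states + self.intercept
        return pd.Series(pba, index=binarized.columns, name="predicted_bio_age_h")

    def predict_sample(self, binarized_sample: Mapping[str, int] | pd.Series) -> float:
        if not isinstance(binarized_sample, pd.Series):
            binarized_sample = pd.Series(binarized_sample)
        frame = binarized_sample.to_frame(name="sample")
        return float(self.predict(frame).iloc[0])

    def summary(self) -> str:
        """Human-readable description of the fitted clock."""
        coefs = self.coefficients.sort_values()
        lines = [
            "Binarized transcriptome aging clock",
            "=" * 40,
            f"clock genes (nonzero coef) : {self.n_genes}",
            f"intercept (h)              : {self.intercept:.3f}",
        ]
        for key, val in self.meta.items():
            lines.append(f"{key:<27}: {val}")
        if len(coefs):
            lines.append("-" * 40)
            lines.append("largest-magnitude coefficients (h):")
            top = coefs.reindex(coefs.abs().sort_values(ascending=False).index[:10])
            for gene, c in top.items():
                lines.append(f"  {gene:<16} {c:+10.4f}")
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "intercept": self.intercept,
            "coefficients": {g: float(c) for g, c in self.coefficients.items()},
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ClockResults":
        """Load a clock from a JSON file path or JSON text."""
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            text = Path(source).read_text()
        else:
            text = source
        payload = json.loads(text)
        return cls(
            coefficients=pd.Series(payload["coefficients"], dtype=float),
            intercept=float(payload["intercept"]),
            meta=dict(payload.get("meta", {})),
        )


def train_clock(
    binarized: pd.DataFrame,
    biological_ages_h,
    cv_folds: int = 5,
    seed: int = 0,
) -> ClockResults:
    """Functional wrapper: fit a :class:`BinarizedClock` in one call."""
    return BinarizedClock(binarized, biological_ages_h).fit(cv_folds=cv_folds, seed=seed)


def predict_age(binarized_sample, model: ClockResults) -> float:
    """Predicted biological age (h) of a single binarized sample."""
    return model.predict_sample(binarized_sample)
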