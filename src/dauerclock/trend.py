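"""Time-course differential expression and trajectory structure.

Genes are prefiltered (counts >= 10 in >= 3 samples by default),
depth-normalized with median-of-ratios size factors, and tested for a
linear trend: for each gene, ordinary least squares of
``log2(normalized + 0.5)`` on the continuous time covariate (dauer day
or exit hour). The slope is the log2 fold change per unit time; its
t-test p-value is adjusted with Benjamini-Hochberg across genes and a
direction (up / down / ns) assigned at the chosen FDR.

The Gaussian trend model on log-normalized counts is a deliberate,
self-contained replacement for a negative-binomial GLM likelihood-ratio
machinery; slopes have a closed form and are directly checkable, at the
cost of ignoring count-level mean-variance structure. Results on real
data are not expected to match an NB GLM gene-for-gene.

The module also provides k-means trajectory clustering with an explicit
elbow rule, a signed-overlap concordance matrix between DEG sets, and a
PCA embedding of the samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests


def prefilter(
    counts: pd.DataFrame, min_count: int = 10, min_samples: int = 3
) -> pd.DataFrame:
    """Keep genes with at least ``min_count`` counts in >= ``min_samples`` samples."""
    keep = (counts >= min_count).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("prefilter removed every gene", stacklevel=2)
    return counts.loc[keep]


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size-factor normalization.

    For each sample the size factor is the median over genes of
    count / geometric-mean-across-samples, computed over genes with no
    zero count in any sample; factors are rescaled to geometric mean 1
    for identifiability. Returns ``(normalized, factors)``.
    """
    values = counts.to_numpy(dtype=float)
    all_nonzero = (values > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; size factors undefined"
        )
    ref = values[all_nonzero]
    log_geo_mean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.log(ref) - log_geo_mean
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    factors_s = pd.Series(factors, index=counts.columns, name="size_factor")
    normalized = counts / factors_s
    return normalized, factors_s


class TrendModel:
    """Per-gene linear trend model of log2 expression on time.

    Parameters
    ----------
    norm_counts
        genes x samples size-factor-normalized matrix.
    times
        the continuous design variable (e.g. dauer day or exit hour),
        one value per sample in column order; needs >= 3 distinct
        values for a slope t-test.
    pseudocount
        offset added before the log2 transform (default 0.5).
    """

    def __init__(
        self,
        norm_counts: pd.DataFrame,
        times: Sequence[float] | pd.Series,
        pseudocount: float = 0.5,
    ) -> None:
        t = np.asarray(
            times.reindex(norm_counts.columns)
            if isinstance(times, pd.Series)
            else times,
            dtype=float,
        )
        if t.size != norm_counts.shape[1]:
            raise ValueError("one time value per sample is required")
        if np.unique(t).size < 3:
            raise ValueError("trend test needs >= 3 distinct time values")
        self.norm_counts = norm_counts
        self.times = t
        self.pseudocount = pseudocount

    def fit(self, alpha: float = 0.05) -> "TrendResults":
        """OLS slope, t-test and BH adjustment for every gene (vectorized)."""
        y = np.log2(self.norm_counts.to_numpy(dtype=float) + self.pseudocount)
        t = self.times
        n = t.size
        tc = t - t.mean()
        sxx = float(tc @ tc)
        yc = y - y.mean(axis=1, keepdims=True)
        slope = yc @ tc / sxx
        intercept = y.mean(axis=1) - slope * t.mean()
        resid = yc - np.outer(slope, tc)
        dof = n - 2
        sigma2 = (resid**2).sum(axis=1) / dof
        se = np.sqrt(sigma2 / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(se > 0, slope / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(stat), dof)
        p = np.clip(p, 0.0, 1.0)
        q = multipletests(p, method="fdr_bh")[1]
        direction = np.where(
            (q <= alpha) & (slope > 0),
            "up",
            np.where((q <= alpha) & (slope < 0), "down", "ns"),
        )
        frame = pd.DataFrame(
            {
                "gene_id": self.norm_counts.index,
                "slope": slope,
                "intercept": intercept,
                "se": se,
                "stat": stat,
                "p": p,
                "q": q,
                "direction": direction,
            }
        ).set_index("gene_id")
        return TrendResults(frame=frame, alpha=alpha, times=t)


@dataclass
class TrendResults:
    """Per-gene trend statistics with convenience views."""

    frame: pd.DataFrame
    alpha: float
    times: np.ndarray

    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["direction"] != "ns"]

    def signed_set(self) -> dict[str, int]:
        """gene -> +1/-1 for significant genes (input to overlap analysis)."""
        sig = self.significant()
        return {g: (1 if s > 0 else -1) for g, s in sig["slope"].items()}

    def summary(self) -> str:
        sig = self.significant()
        lines = [
            "Per-gene linear trend (log2 expression vs time)",
            "=" * 48,
            f"genes tested          : {len(self.frame)}",
            f"distinct time values  : {np.unique(self.times).size}",
            f"FDR level (BH)        : {self.alpha}",
            f"significant genes     : {len(sig)}"
            f" ({(sig['direction'] == 'up').sum()} up,"
            f" {(sig['direction'] == 'down').sum()} down)",
        ]
        if len(sig):
            top = sig.reindex(sig["q"].sort_values().index[:5])
            lines.append("-" * 48)
            lines.append("top genes by q:")
            for g, row in top.iterrows():
                lines.append(
                    f"  {g:<16} slope={row['slope']:+.3f}  q={row['q']:.2e}"
                    f"  {row['direction']}"
                )
        return "\n".join(lines)


def trend_test(
    norm_counts: pd.DataFrame,
    times: Sequence[float] | pd.Series,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Functional wrapper: fit a :class:`TrendModel` and return its frame."""
    return TrendModel(norm_counts, times, pseudocount=pseudocount).fit(alpha).frame


def two_group_test(
    norm_counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Welch t-test of log2(normalized + pseudocount), group B minus group A.

    Companion to the trend test for two-condition contrasts (e.g. UV vs
    untreated) where a time trend is not defined. Positive ``lfc`` means
    higher expression in group B.
    """
    a = np.log2(norm_counts[list(group_a)].to_numpy(dtype=float) + pseudocount)
    b = np.log2(norm_counts[list(group_b)].to_numpy(dtype=float) + pseudocount)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    lfc = b.mean(axis=1) - a.mean(axis=1)
    with warnings.catch_warnings():
        # near-constant genes trigger a precision warning inside the
        # t-statistic; their p ends up ~1 either way
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    direction = np.where(
        (q <= alpha) & (lfc > 0), "up", np.where((q <= alpha) & (lfc < 0), "down", "ns")
    )
    return pd.DataFrame(
        {"lfc": lfc, "stat": stat, "p": p, "q": q, "direction": direction},
        index=norm_counts.index,
    )


@dataclass
class ClusterAssignment:
    """k-means trajectory clustering output."""

    labels: pd.Series  # gene -> cluster label in 1..k
    centers: pd.DataFrame  # cluster x timepoint mean scaled profile
    wcss: pd.Series  # k -> within-cluster sum of squares
    chosen_k: int

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _scaled_profiles(
    norm_counts: pd.DataFrame, times: np.ndarray, pseudocount: float
) -> pd.DataFrame:
    """Replicate-averaged, per-gene z-scaled log2 profiles over timepoints."""
    log_expr = np.log2(norm_counts.to_numpy(dtype=float) + pseudocount)
    unique_times = np.unique(times)
    profile = np.column_stack(
        [log_expr[:, times == t].mean(axis=1) for t in unique_times]
    )
    mean = profile.mean(axis=1, keepdims=True)
    sd = profile.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} genes have zero variance across timepoints; excluded",
            stacklevel=3,
        )
    scaled = (profile[~flat] - mean[~flat]) / sd[~flat]
    return pd.DataFrame(scaled, index=norm_counts.index[~flat], columns=unique_times)


def choose_elbow(wcss: pd.Series) -> int:
    """Elbow k: maximize the second difference of WCSS over the scanned k.

    With fewer than three scanned values no curvature is defined and the
    largest k is returned.
    """
    ks = np.asarray(sorted(wcss.index))
    if ks.size < 3:
        return int(ks.max())
    w = wcss.loc[ks].to_numpy(dtype=float)
    curvature = w[:-2] - 2 * w[1:-1] + w[2:]  # indexed by interior ks
    return int(ks[1:-1][int(np.argmax(curvature))])


def cluster_profiles(
    norm_counts: pd.DataFrame,
    times: Sequence[float] | pd.Series,
    k_range: Sequence[int] = range(1, 11),
    seed: int = 0,
    n_init: int = 100,
    max_iter: int = 1000,
    k: int | None = None,
    pseudocount: float = 0.5,
) -> ClusterAssignment:
    """k-means clustering of per-gene scaled time profiles.

    Profiles are replicate means per timepoint, z-scaled per gene
    (zero-variance genes excluded with a warning). WCSS is recorded for
    every k in ``k_range``; the reported assignment uses ``k`` if given,
    otherwise the elbow k (max second difference of WCSS).
    """
    t = np.asarray(
        times.reindex(norm_counts.columns) if isinstance(times, pd.Series) else times,
        dtype=float,
    )
    profiles = _scaled_profiles(norm_counts, t, pseudocount)
    k_range = sorted(set(int(x) for x in k_range))
    if not k_range or k_range[0] < 1:
        raise ValueError("k_range must contain integers >= 1")
    if len(profiles) < max(k_range):
        raise ValueError(
            f"only {len(profiles)} usable genes for k up to {max(k_range)}"
        )
    X = profiles.to_numpy()
    fits: dict[int, KMeans] = {}
    wcss = {}
    for kk in k_range:
        km = KMeans(
            n_clusters=kk, n_init=n_init, max_iter=max_iter, random_state=seed
        ).fit(X)
        fits[kk] = km
        wcss[kk] = float(km.inertia_)
    wcss_s = pd.Series(wcss, name="wcss").sort_index()
    chosen = int(k) if k is not None else choose_elbow(wcss_s)
    if chosen not in fits:
        km = KMeans(
            n_clusters=chosen, n_init=n_init, max_iter=max_iter, random_state=seed
        ).fit(X)
    else:
        km = fits[chosen]
    labels = pd.Series(km.labels_ + 1, index=profiles.index, name="cluster")
    centers = pd.DataFrame(
        km.cluster_centers_,
        index=pd.RangeIndex(1, chosen + 1, name="cluster"),
        columns=profiles.columns,
    )
    return ClusterAssignment(labels=labels, centers=centers, wcss=wcss_s, chosen_k=chosen)


def exit_overlap(deg_sets: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Pairwise signed overlap between DEG sets.

    ``deg_sets`` maps a label (e.g. "D1") to ``{gene: +1/-1}``. For each
    pair the number of shared genes and the fraction of shared genes
    with the same sign are reported; the fraction is NA when the sets
    are disjoint. The result is a long-format symmetric table with
    columns ``set_a``, ``set_b``, ``n_shared``, ``frac_same_direction``.
    """
    labels = list(deg_sets)
    rows = []
    for a in labels:
        for b in labels:
            genes_a, genes_b = deg_sets[a], deg_sets[b]
            shared = set(genes_a) & set(genes_b)
            n = len(shared)
            frac = (
                sum(genes_a[g] == genes_b[g] for g in shared) / n if n else np.nan
            )
            rows.append(
                {"set_a": a, "set_b": b, "n_shared": n, "frac_same_direction": frac}
            )
    return pd.DataFrame(rows)


@dataclass
class PcaEmbedding:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    explained_variance_ratio: pd.Series


def pca_embed(
    norm_counts: pd.DataFrame,
    n_components: int = 2,
    pseudocount: float = 0.5,
) -> PcaEmbedding:
    """PCA of samples on gene-centered log2(normalized + pseudocount).

    Components beyond what the sample count supports are truncated with
    a warning. Orientation is fixed by forcing the largest-magnitude
    gene loading of each component positive.
    """
    if norm_counts.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    max_comp = min(norm_counts.shape[1], norm_counts.shape[0])
    if n_components > max_comp:
        warnings.warn(
            f"n_components truncated from {n_components} to {max_comp}", stacklevel=2
        )
        n_components = max_comp
    X = np.log2(norm_counts.to_numpy(dtype=float) + pseudocount).T  # samples x genes
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x components
    # deterministic orientation
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaEmbedding(
        scores=pd.DataFrame(scores, index=norm_counts.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=norm_counts.index, columns=comp_names),
        explained_variance_ratio=pd.Series(
            pca.explained_variance_ratio_, index=comp_names, name="evr"
        ),
    )
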