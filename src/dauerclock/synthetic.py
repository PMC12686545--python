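"""Synthetic bulk RNA-seq count generator for dauer-style time courses.

The generator emulates the structure of a dauer diapause aging
experiment: a handful of chronological timepoints (e.g. dauer day 1, 4,
15, 30 expressed in hours), a few biological replicates per timepoint,
and ~10^3-10^4 genes whose expression follows one of several programs:

``up`` / ``down``
    log-linear change of ``effect_size_log2_per_day`` log2 units per day
    of (biological) age, centred on the middle of the time course.
``transient``
    a Gaussian bump in log2 space peaking at an interior timepoint.
``oscillatory``
    a sinusoid with a short developmental period (default 8 h).
``drift``
    stochastic activation: a lowly expressed gene jumps to a high state
    per-sample with probability increasing in age, mimicking the
    accumulation of random transcriptional changes that stochastic
    aging clocks read out.
``flat``
    no age dependence (the remainder of the gene panel).

Counts are drawn from a negative binomial (gamma-Poisson) with
``var = mu + dispersion * mu**2`` and log-normal library sizes, the
standard bulk RNA-seq noise model. A UV-irradiation effect can be
layered on top: each gene's expected count is multiplied by a
length-dependent retention factor ``exp(-lesion_rate * dose * kb)``,
emulating transcription-blocking lesions that preferentially silence
long genes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import containers
from .enrichment import GeneSetCollection, read_gmt, write_gmt

PROGRAMS = ("up", "down", "transient", "oscillatory", "drift", "flat")

#: default reference lifespan (h) attached to single-cohort simulations;
#: roughly a daf-2 median lifespan at 15 C scaled to hours.
DEFAULT_LIFESPAN_H = 480.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the count simulator.

    Fractions refer to the share of the gene panel assigned to each
    expression program; whatever is left over is flat. Timepoints are
    chronological ages in hours and must be strictly increasing.
    """

    n_genes: int = 2000
    n_samples_per_timepoint: int = 3
    timepoints_h: tuple[float, ...] = (24.0, 96.0, 360.0, 720.0)
    seed: int = 0
    library_size_mean: float = 1_000_000.0
    library_size_cv: float = 0.15
    frac_age_up: float = 0.05
    frac_age_down: float = 0.05
    frac_transient: float = 0.05
    frac_oscillatory: float = 0.05
    frac_drift: float = 0.05
    effect_size_log2_per_day: float = 0.1
    nb_dispersion: float = 0.1
    uv_dose: float = 0.0
    lesion_rate_per_kb_per_dose: float = 0.1
    gene_length_range_bp: tuple[float, float] = (200.0, 100_000.0)
    oscillation_period_h: float = 8.0
    oscillation_amplitude_log2: float = 1.0
    transient_amplitude_log2: float = 2.0
    drift_rate_per_day: float = 0.03
    drift_shift_log2: float = 4.0
    baseline_log2_sd: float = 2.0

    def validate(self) -> None:
        fracs = (
            self.frac_age_up,
            self.frac_age_down,
            self.frac_transient,
            self.frac_oscillatory,
            self.frac_drift,
        )
        if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
            raise ValueError("program fractions must be >= 0 and sum to <= 1")
        times = np.asarray(self.timepoints_h, dtype=float)
        if times.size < 1 or np.any(np.diff(times) <= 0):
            raise ValueError("timepoints_h must be strictly increasing")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.uv_dose < 0:
            raise ValueError("uv_dose must be >= 0")
        if self.lesion_rate_per_kb_per_dose < 0:
            raise ValueError("lesion_rate_per_kb_per_dose must be >= 0")
        lo, hi = self.gene_length_range_bp
        if lo <= 0 or hi <= lo:
            raise ValueError("gene_length_range_bp must satisfy 0 < min < max")
        if self.n_genes < 1 or self.n_samples_per_timepoint < 1:
            raise ValueError("n_genes and n_samples_per_timepoint must be >= 1")


@dataclass
class GroundTruth:
    """Per-gene and per-sample ground truth of a simulation run.

    ``table`` has one row per gene (program, true slope in log2/day,
    length in bp, UV retention factor); ``sample_bio_age_h`` maps each
    sample to the biological age its expression was generated at;
    ``expected_means`` holds the noise-free expected counts used for the
    negative-binomial draw (before UV), which is what ``apply_uv_effect``
    rescales.
    """

    table: pd.DataFrame
    sample_bio_age_h: pd.Series
    expected_means: pd.DataFrame
    nb_dispersion: float
    seed: int

    def genes_in(self, program: str) -> list[str]:
        sel = self.table.loc[self.table["program"] == program, "gene_id"]
        return sel.tolist()


def _assign_programs(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    n = cfg.n_genes
    counts = {
        "up": int(round(cfg.frac_age_up * n)),
        "down": int(round(cfg.frac_age_down * n)),
        "transient": int(round(cfg.frac_transient * n)),
        "oscillatory": int(round(cfg.frac_oscillatory * n)),
        "drift": int(round(cfg.frac_drift * n)),
    }
    total = sum(counts.values())
    if total > n:  # rounding pushed us over; trim the largest program
        for name in sorted(counts, key=counts.get, reverse=True):
            if total <= n:
                break
            counts[name] -= total - n
            total = sum(counts.values())
    labels = np.array(
        sum(([name] * k for name, k in counts.items()), [])
        + ["flat"] * (n - total),
        dtype=object,
    )
    rng.shuffle(labels)
    return labels


def _expected_log2_offsets(
    cfg: SimulationConfig,
    programs: np.ndarray,
    bio_age_h: np.ndarray,
    chrono_age_h: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic log2 offsets (genes x samples) plus per-gene slopes.

    Offsets are centred so the panel-wide expression level stays stable
    across the time course; drift is handled separately because it is a
    per-sample stochastic event, not a deterministic offset.
    """
    n_genes = len(programs)
    n_samples = len(bio_age_h)
    bio_days = bio_age_h / 24.0
    mid_day = (bio_days.min() + bio_days.max()) / 2.0
    span_days = max(bio_days.max() - bio_days.min(), 1e-9)

    offsets = np.zeros((n_genes, n_samples))
    slopes = np.zeros(n_genes)

    up = programs == "up"
    down = programs == "down"
    slopes[up] = cfg.effect_size_log2_per_day
    slopes[down] = -cfg.effect_size_log2_per_day
    offsets[up | down] = np.outer(slopes[up | down], bio_days - mid_day)

    transient = np.flatnonzero(programs == "transient")
    if transient.size:
        uniq = np.unique(bio_days)
        interior = uniq[1:-1] if uniq.size > 2 else uniq
        peaks = rng.choice(interior, size=transient.size)
        width = span_days / 6.0 if span_days > 0 else 1.0
        bumps = np.exp(-((bio_days[None, :] - peaks[:, None]) ** 2) / (2 * width**2))
        offsets[transient] = cfg.transient_amplitude_log2 * (bumps - bumps.mean(axis=1, keepdims=True))

    osc = np.flatnonzero(programs == "oscillatory")
    if osc.size:
        phases = rng.uniform(0, 2 * np.pi, size=osc.size)
        wave = np.sin(
            2 * np.pi * chrono_age_h[None, :] / cfg.oscillation_period_h
            + phases[:, None]
        )
        offsets[osc] = cfg.oscillation_amplitude_log2 * wave

    return offsets, slopes


def _simulate(
    cfg: SimulationConfig,
    metadata: pd.DataFrame,
    bio_age_h: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Shared core: build expected means for given samples and draw counts."""
    rng = np.random.default_rng(cfg.seed)
    gene_ids = np.array([f"g{i:05d}" for i in range(cfg.n_genes)])
    sample_ids = metadata["sample_id"].to_numpy()
    chrono_age_h = metadata["timepoint_h"].to_numpy(dtype=float)

    programs = _assign_programs(rng, cfg)
    lo, hi = cfg.gene_length_range_bp
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_genes))
    lengths = np.round(lengths).astype(int)

    # baseline relative abundances, log-normal across genes
    base = np.exp(rng.normal(0.0, cfg.baseline_log2_sd * np.log(2), size=cfg.n_genes))
    drift_mask = programs == "drift"
    base[drift_mask] *= 0.25  # drift genes start lowly expressed (state 0)

    offsets, slopes = _expected_log2_offsets(
        cfg, programs, bio_age_h, chrono_age_h, rng
    )

    # per-sample stochastic drift activation
    if drift_mask.any():
        bio_days = bio_age_h / 24.0
        p_flip = np.clip(cfg.drift_rate_per_day * bio_days, 0.0, 0.95)
        flips = rng.random((drift_mask.sum(), len(bio_age_h))) < p_flip[None, :]
        offsets[drift_mask] += cfg.drift_shift_log2 * flips

    rel = base[:, None] * np.exp2(offsets)
    lib_sizes = _lognormal_library_sizes(rng, cfg, len(sample_ids))
    mu = rel / rel.sum(axis=0, keepdims=True) * lib_sizes[None, :]

    counts = _draw_nb(rng, mu, cfg.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=sample_ids)
    truth_table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "program": programs,
            "true_slope": slopes,
            "retention": np.ones(cfg.n_genes),
            "length_bp": lengths,
        }
    )
    truth = GroundTruth(
        table=truth_table,
        sample_bio_age_h=pd.Series(bio_age_h, index=sample_ids, name="bio_age_h"),
        expected_means=pd.DataFrame(mu, index=counts_df.index, columns=sample_ids),
        nb_dispersion=cfg.nb_dispersion,
        seed=cfg.seed,
    )
    return counts_df, metadata, truth


def _lognormal_library_sizes(
    rng: np.random.Generator, cfg: SimulationConfig, n: int
) -> np.ndarray:
    cv = max(cfg.library_size_cv, 0.0)
    sigma2 = np.log1p(cv**2)
    mu_log = np.log(cfg.library_size_mean) - sigma2 / 2.0
    return rng.lognormal(mu_log, np.sqrt(sigma2), size=n)


def _draw_nb(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw with var = mu + dispersion * mu^2 (gamma-Poisson)."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_timecourse(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a single-cohort dauer aging time course.

    Biological age equals chronological age (one cohort, one lifespan).
    Returns ``(counts, metadata, truth)``; deterministic for a fixed
    ``config.seed``.
    """
    config.validate()
    rows = []
    for tp in config.timepoints_h:
        for rep in range(1, config.n_samples_per_timepoint + 1):
            rows.append(
                {
                    "sample_id": f"t{int(round(tp))}h_r{rep}",
                    "group": f"t{int(round(tp))}h",
                    "timepoint_h": float(tp),
                    "median_lifespan_h": DEFAULT_LIFESPAN_H,
                }
            )
    metadata = pd.DataFrame(rows)
    bio_age = metadata["timepoint_h"].to_numpy(dtype=float)
    return _simulate(config, metadata, bio_age)


def simulate_lifespan_cohorts(
    config: SimulationConfig,
    n_cohorts: int,
    lifespan_range_h: tuple[float, float],
    lifespans_h: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate several cohorts whose aging rate scales with lifespan.

    Each cohort receives a median lifespan (uniform over
    ``lifespan_range_h`` unless ``lifespans_h`` fixes them) and gene
    expression is generated as a function of *biological* age —
    chronological age rescaled by ``reference_lifespan / cohort_lifespan``
    with the reference set to the mean of the cohort lifespans. A clock
    trained on such cohorts must therefore learn lifespan-invariant
    signal to generalize across cohorts.
    """
    config.validate()
    if n_cohorts < 2:
        raise ValueError("n_cohorts must be >= 2")
    lo, hi = lifespan_range_h
    if lo <= 0 or hi <= lo:
        raise ValueError("lifespan_range_h must satisfy 0 < low < high")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    if lifespans_h is None:
        lifespans = rng.uniform(lo, hi, size=n_cohorts)
    else:
        lifespans = np.asarray(lifespans_h, dtype=float)
        if lifespans.size != n_cohorts or (lifespans <= 0).any():
            raise ValueError("lifespans_h must give one positive value per cohort")
    reference = float(lifespans.mean())

    rows = []
    for c, ls in enumerate(lifespans, start=1):
        for tp in config.timepoints_h:
            for rep in range(1, config.n_samples_per_timepoint + 1):
                rows.append(
                    {
                        "sample_id": f"c{c}_t{int(round(tp))}h_r{rep}",
                        "group": f"cohort{c}",
                        "timepoint_h": float(tp),
                        "median_lifespan_h": float(ls),
                    }
                )
    metadata = pd.DataFrame(rows)
    bio_age = (
        metadata["timepoint_h"].to_numpy(dtype=float)
        * reference
        / metadata["median_lifespan_h"].to_numpy(dtype=float)
    )
    return _simulate(config, metadata, bio_age)


def apply_uv_effect(
    counts: pd.DataFrame,
    truth: GroundTruth,
    dose: float,
    lesion_rate_per_kb_per_dose: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Redraw counts after UV exposure with length-dependent retention.

    Each gene's expected count is multiplied by
    ``retention = exp(-lesion_rate * dose * length_kb)`` and counts are
    redrawn from the same negative-binomial model; ``truth.table`` is
    updated in place with the retention factors. Dose 0 returns data
    distributionally identical to the input (retention 1 everywhere).
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if lesion_rate_per_kb_per_dose < 0:
        raise ValueError("lesion_rate_per_kb_per_dose must be >= 0")
    lengths_kb = truth.table["length_bp"].to_numpy(dtype=float) / 1000.0
    retention = np.exp(-lesion_rate_per_kb_per_dose * dose * lengths_kb)
    truth.table["retention"] = retention

    mu = truth.expected_means.loc[counts.index, counts.columns].to_numpy()
    mu_uv = mu * retention[:, None]
    rng_seed = truth.seed + 104729 if seed is None else seed
    rng = np.random.default_rng(rng_seed)
    uv_counts = _draw_nb(rng, mu_uv, truth.nb_dispersion)
    return pd.DataFrame(uv_counts, index=counts.index, columns=counts.columns)


def program_gene_sets(truth: GroundTruth) -> GeneSetCollection:
    """Gene sets named after the simulation programs (for enrichment demos)."""
    sets: dict[str, list[str]] = {}
    for program in PROGRAMS:
        members = truth.genes_in(program)
        if members:
            sets[f"PROGRAM_{program.upper()}"] = members
    return GeneSetCollection(
        sets=sets,
        descriptions={k: "simulated expression program" for k in sets},
    )


def write_fixture(
    directory: str | Path,
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write counts/metadata/genes/truth TSVs and a program GMT to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "metadata": directory / "metadata.tsv",
        "genes": directory / "genes.tsv",
        "truth": directory / "truth.tsv",
        "genesets": directory / "genesets.gmt",
    }
    containers.write_counts(counts, paths["counts"])
    containers.write_metadata(metadata, paths["metadata"])
    genes = truth.table[["gene_id", "length_bp"]]
    containers.write_genes(genes, paths["genes"])
    containers.write_truth(truth.table[list(containers.TRUTH_COLUMNS)], paths["truth"])
    write_gmt(program_gene_sets(truth), paths["genesets"])
    return paths


def read_fixture(
    directory: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GeneSetCollection]:
    """Read back a fixture directory written by :func:`write_fixture`.

    Returns ``(counts, metadata, genes, truth_table, gene_sets)``; raises
    ``FileNotFoundError`` naming the first missing file.
    """
    directory = Path(directory)
    counts = containers.read_counts(directory / "counts.tsv")
    metadata = containers.read_metadata(directory / "metadata.tsv")
    genes = containers.read_genes(directory / "genes.tsv")
    truth_table = containers.read_truth(directory / "truth.tsv")
    gene_sets = read_gmt(directory / "genesets.gmt")
    return counts, metadata, genes, truth_table, gene_sets


def config_with(config: SimulationConfig, **overrides) -> SimulationConfig:
    """Return a copy of ``config`` with the given fields replaced."""
    return dataclasses.replace(config, **overrides)
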