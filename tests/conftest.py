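import numpy as np
import pandas as pd
import pytest

import dauerclock as dc


@pytest.fixture(scope="session")
def timecourse():
    """Small mixed-program dauer-style time course with ground truth."""
    cfg = dc.SimulationConfig(
        n_genes=600,
        n_samples_per_timepoint=3,
        timepoints_h=(24.0, 96.0, 360.0, 720.0),
        frac_age_up=0.1,
        frac_age_down=0.1,
        frac_transient=0.05,
        frac_oscillatory=0.05,
        frac_drift=0.1,
        effect_size_log2_per_day=0.2,
        seed=42,
    )
    return cfg, *dc.simulate_timecourse(cfg)


@pytest.fixture(scope="session")
def trend_fixture():
    """Planted up/down trends, 4 timepoints x 3 reps, effect 1 log2/day."""
    cfg = dc.SimulationConfig(
        n_genes=1000,
        n_samples_per_timepoint=3,
        timepoints_h=(24.0, 48.0, 72.0, 96.0),
        frac_age_up=0.1,
        frac_age_down=0.1,
        frac_transient=0.0,
        frac_oscillatory=0.0,
        frac_drift=0.0,
        effect_size_log2_per_day=1.0,
        nb_dispersion=0.1,
        seed=3,
    )
    counts, meta, truth = dc.simulate_timecourse(cfg)
    filtered = dc.prefilter(counts)
    norm, _ = dc.normalize_counts(filtered)
    days = meta.set_index("sample_id").loc[list(norm.columns), "timepoint_h"] / 24.0
    return norm, days, truth


@pytest.fixture(scope="session")
def null_fixture():
    """All-flat simulation for false-positive-rate checks."""
    cfg = dc.SimulationConfig(
        n_genes=600,
        n_samples_per_timepoint=3,
        timepoints_h=(24.0, 48.0, 72.0, 96.0),
        frac_age_up=0.0,
        frac_age_down=0.0,
        frac_transient=0.0,
        frac_oscillatory=0.0,
        frac_drift=0.0,
        seed=4,
    )
    counts, meta, truth = dc.simulate_timecourse(cfg)
    filtered = dc.prefilter(counts)
    norm, _ = dc.normalize_counts(filtered)
    days = meta.set_index("sample_id").loc[list(norm.columns), "timepoint_h"] / 24.0
    return norm, days


@pytest.fixture(scope="session")
def cohort_fixture():
    """Four lifespan-labelled cohorts (60 samples, 500 genes) for clock tests."""
    cfg = dc.SimulationConfig(
        n_genes=500,
        n_samples_per_timepoint=3,
        timepoints_h=(24.0, 48.0, 72.0, 96.0, 120.0),
        frac_age_up=0.15,
        frac_age_down=0.15,
        frac_transient=0.0,
        frac_oscillatory=0.0,
        frac_drift=0.0,
        effect_size_log2_per_day=1.0,
        nb_dispersion=0.1,
        seed=11,
    )
    counts, meta, truth = dc.simulate_lifespan_cohorts(cfg, 4, (300.0, 900.0))
    return counts, meta, truth


@pytest.fixture(scope="session")
def archetype_profiles():
    """Four planted trajectory archetypes on a positive expression scale."""
    rng = np.random.default_rng(0)
    times = np.repeat([1.0, 4.0, 15.0, 30.0], 3)
    shapes = {
        "up": lambda t: (t - t.mean()) / t.std(),
        "down": lambda t: -(t - t.mean()) / t.std(),
        "early": lambda t: np.exp(-((t - 4.0) ** 2) / 18.0),
        "late": lambda t: np.exp(-((t - 15.0) ** 2) / 50.0),
    }
    rows, labels, genes = [], [], []
    for label, (name, shape) in enumerate(shapes.items()):
        profile = shape(times)
        for i in range(50):
            base = rng.uniform(6.0, 10.0)
            log_expr = base + 2.0 * profile + rng.normal(0.0, 0.15, size=times.size)
            rows.append(2.0**log_expr)
            labels.append(label)
            genes.append(f"{name}{i}")
    norm = pd.DataFrame(
        rows, index=genes, columns=[f"s{i}" for i in range(times.size)]
    )
    return norm, times, np.array(labels)
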