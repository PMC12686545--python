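# dauerclock

Transcriptomic aging analysis for *C. elegans* dauer diapause RNA-seq:
biological-age clocks, time-course differential expression, trajectory
clustering, pathway over-representation and the gene-length-dependent
transcription-decline statistic — with a negative-binomial count
simulator so the whole stack can be exercised and validated without any
external data.

## Who this is for

The dauer larva is a stress-resistant, developmentally arrested stage
that can outlive a normal *C. elegans* lifespan several times over and
still resume development into a normal adult. Quantifying how
"biologically old" dauers get, and how fast they rejuvenate upon exit,
requires transcriptome-level age estimates and trend statistics rather
than pairwise contrasts. This package implements that toolchain for
anyone analysing dauer-style (or any bulk RNA-seq) time courses.

## The methods

**Binarized aging clock.** Within each sample, a gene is set to 1 iff
its expression is strictly above the median of the sample's nonzero
values (zero-count genes are excluded from the median and always 0).
Training is an elastic-net regression (mixing 0.5, penalty by k-fold CV)
of *biological age* on these binary states, where biological age is
chronological age rescaled by lifespan:

    b = t · ℓ_ref / ℓ_cohort

Prediction for a sample is Σ β_g·x_g + β₀ over the clock genes with
state x_g = 1. The **aging rate** between two timepoints is
(PBA₂ − PBA₁)/(t₂ − t₁), biological hours aged per chronological hour.

**Stochastic-drift clock.** Per sample: log10(x+1), min-max to [0, 1],
binarize as above, and count how many of a fixed panel of drift genes —
genes off in the young consensus that switch on with age — are active.

**Trend differential expression.** After prefiltering (counts ≥ 10 in
≥ 3 samples) and median-of-ratios size-factor normalization, each gene
gets an OLS fit of log2(normalized + 0.5) on the continuous time
covariate; the slope is the log2 fold change per unit time, tested with
a t-test and BH-adjusted. Trajectories are k-means clustered (scaled
replicate-mean profiles; elbow rule on WCSS), and signed DEG sets are
compared by shared-gene direction concordance.

**Enrichment.** Hypergeometric upper-tail over-representation against
GMT gene sets, with gene-ratio (k/n) and rich-factor (k/m) summaries.

**GLTD.** Two-sided Mann-Whitney U comparison of the gene-length
distributions of up- vs down-regulated sets — the signature of
transcription-blocking lesions is that down-regulated genes are longer.

## Worked example

Simulate four lifespan-labelled cohorts (60 samples, 500 genes), train
the binarized clock on three of them and predict the held-out cohort:

```python
import dauerclock as dc
from scipy.stats import pearsonr

cfg = dc.SimulationConfig(
    n_genes=500, n_samples_per_timepoint=3,
    timepoints_h=(24, 48, 72, 96, 120),
    frac_age_up=0.15, frac_age_down=0.15,
    effect_size_log2_per_day=1.0, seed=1,
)
counts, meta, truth = dc.simulate_lifespan_cohorts(
    cfg, n_cohorts=4, lifespan_range_h=(300, 900))
held = meta["group"].unique()[-1]
train = meta.loc[meta["group"] != held, "sample_id"].tolist()
test = meta.loc[meta["group"] == held, "sample_id"].tolist()

binarized = dc.binarize(counts)
fit = dc.train_clock(binarized[train], truth.sample_bio_age_h.loc[train], seed=1)
print(fit.summary())
pred = fit.predict(binarized[test])
r, _ = pearsonr(truth.sample_bio_age_h.loc[test], pred)
print(f"held-out cohort: r = {r:.3f}")
print(f"aging rate D1->D4: {dc.aging_rate(123.0, 180.0, 24.0, 96.0):.2f}")
```

prints

```
Binarized transcriptome aging clock
========================================
clock genes (nonzero coef) : 154
intercept (h)              : 80.836
...
held-out cohort: r = 0.995
aging rate D1->D4: 0.79
```

The clock kept 154 informative genes; its held-out predictions track
the true biological age almost perfectly (r = 0.995) because the
simulated cohorts age at lifespan-rescaled speed, exactly what the
rescaled training labels encode. The final line is the worked
aging-rate arithmetic for real dauers: predicted biological age rises
123 h → 180 h while 72 chronological hours pass, i.e. dauers age at
0.79× speed over days 1–4 (and only ~0.12× over days 4–30).

A full pipeline run (simulate → filter → normalize → both clocks →
trend → clustering → overlap → enrichment → UV/GLTD, with a hashed
manifest) is one command:

```sh
dauerclock run-all --config config.yaml
```

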