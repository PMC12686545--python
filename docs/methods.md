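# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical conventions, and the open design choices made
in `dauerclock`, in the order a pipeline run visits them.

## Synthetic count model

The generator produces gene-by-sample integer counts with the design of
a dauer aging experiment: a strictly increasing set of chronological
timepoints (default 24, 96, 360, 720 h ≈ dauer days 1/4/15/30), three
replicates per timepoint, and a gene panel partitioned into expression
programs.

Counts are gamma-Poisson (negative binomial) with

    var = μ + φ·μ²,   φ = `nb_dispersion` (default 0.1),

the standard bulk RNA-seq noise model. Expected counts are
`μ_gs = L_s · q_g · 2^{δ_g(s)} / Σ_g' q_g' 2^{δ}`, where `L_s` is a
log-normal library size (mean 10⁶ counts, CV 0.15 by default — enough
depth variation to exercise normalization), `q_g` a log-normal baseline
abundance (SD 2 log2 units, giving the wide dynamic range binarization
needs), and `δ_g(s)` the program offset in log2:

- **up / down**: ±`effect_size_log2_per_day` × (biological age in
  days), centred on the mid-course so overall depth stays stable. The
  default of 0.1 log2/day yields ~3 log2 over a 30-day course, a
  moderate, plausible magnitude; the recovery fixtures use 1.0 log2/day
  over a 4-day course, chosen for statistical power (no empirical
  effect-size scale exists for dauer expression drift, so power, not
  fidelity, drives the choice).
- **transient**: a Gaussian bump (width = span/6) peaking at a random
  interior timepoint, amplitude 2 log2 by default.
- **oscillatory**: a sinusoid with an 8 h period mimicking the
  developmental expression oscillations of larval stages; amplitude
  1 log2.
- **drift**: genes start at 25% of their baseline (so their young
  consensus binarized state is 0) and jump by 4 log2 per-sample with
  probability `drift_rate_per_day × age` (capped at 0.95) — a
  stochastic activation model of accumulating random transcriptional
  change, which is what the stochastic clock reads out.
- **flat**: the remainder; no age dependence.

Gene lengths are log-uniform over 200 bp–100 kb, spanning the dynamic
range the gene-length test needs.

**Lifespan cohorts.** `simulate_lifespan_cohorts` draws one median
lifespan per cohort (uniform over the given range) and generates
expression as a function of *biological* age
`b = t · ℓ_ref / ℓ_cohort` with `ℓ_ref` the mean cohort lifespan. By
construction a cohort living twice as long shows, at chronological age
`t`, the expression of a reference cohort at `t/2`; a clock can only
generalize across held-out cohorts by learning this lifespan-invariant
signal.

**UV effect.** `apply_uv_effect` multiplies each gene's expected count
by `exp(−lesion_rate · dose · length_kb)` — a single-hit Poisson model
of transcription-blocking lesions, under which the probability that a
transcript escapes a block decays exponentially in gene length — and
redraws counts from the same NB model. Dose 0 is distributionally
identical to the input.

**What the generator does not emulate:** GC/length biases in counting,
replicate-level batch effects, correlated gene modules beyond the
shared programs, developmental stage mixtures within a sample, and any
real dauer regulon structure. Passing recovery tests therefore show
that the estimators are correct and well calibrated under their own
assumptions, not that real dauer data will behave this cleanly.

## Binarized clock

Binarization is per sample: threshold = median of the sample's nonzero
values; state 1 iff strictly greater. "Strictly" is a deliberate fixed
convention (values equal to the median, and all zero-count genes, map
to 0); with an even number of nonzero genes at most half can be active.
A sample with no nonzero count has no median and is an error naming the
sample.

Training regresses biological age on the binary states with an elastic
net (mixing 0.5, penalty path chosen by 5-fold CV minimizing MSE,
`random_state` recorded in the model). Only nonzero-coefficient genes
are kept. The reference lifespan for the age labels defaults to the
mean of the training cohorts' median lifespans — any fixed choice only
rescales the label axis. Prediction is the coefficient sum over active
clock genes plus the intercept; clock genes missing from a query matrix
count as state 0 with a logged warning, since the summation form
extends naturally across annotation versions. Published external
coefficient tables can be loaded through the JSON model schema
(`ClockResults.from_json`); none are bundled.

## Stochastic clock

Per sample: log10(x+1), min-max to [0, 1], then the same strict-median
binarization restricted to nonzero-count genes, then a sum over the
clock panel. The underlying description of this clock is ambiguous
about whether the binarized states or the min-max-normalized values are
summed; the default sums binarized states (giving an interpretable
count in [0, panel size]), and `mode="normalized"` sums normalized
values for sensitivity analysis. Neither is asserted to be the original
computation.

Panel selection is this package's own concretization: genes whose
majority state in the youngest age group is 0 are ranked by the OLS
slope of their mean binarized state against age; the top `n_genes`
positive slopes form the panel, ties broken lexicographically by gene
id for determinism.

## Trend differential expression

Prefilter: counts ≥ 10 in ≥ 3 samples (the smallest group size).
Normalization: median-of-ratios size factors over genes with no zero
in any sample, rescaled to geometric mean 1 for identifiability.

The per-gene model is OLS of `log2(normalized + 0.5)` on the continuous
time covariate; the slope is the log2 fold change per unit time, tested
by its t statistic (n−2 df) and BH-adjusted across genes. This Gaussian
model is a deliberate replacement for a negative-binomial GLM with a
likelihood-ratio test: it is self-contained, has a closed-form slope
checkable against an independent OLS oracle to 1e-9, and behaves well
on log-normalized counts — but it does not model count-level
mean-variance structure, so results on real data will not match an NB
GLM gene-for-gene. The 0.5 pseudocount is the usual log-CPM-style
offset and is configurable; at counts ≥ 100 it biases slopes by < 0.5%.

A Welch t-test companion (`two_group_test`) covers two-condition
contrasts (UV vs control) where no time axis exists.

## Trajectory clustering

Profiles are replicate means per timepoint, z-scaled per gene
(zero-variance genes excluded with a warning). k-means runs with 100
restarts and up to 1000 iterations per k, seeded. Because the visual
"elbow" of a WCSS curve is not an algorithm, the rule here is explicit:
the elbow k maximizes the second difference of WCSS over the scanned
range (with fewer than three scanned k, the largest is returned). On
curves whose early drops dwarf the true elbow this rule can pick a
smaller k than the eye would; the chosen k can always be overridden
with the `k` argument, and WCSS per k is reported for inspection.

## Signed overlap

For each pair of signed DEG sets: number of shared genes, and fraction
of shared genes with equal sign. Genes must be significant in *both*
sets to count as shared (intersection semantics). Disjoint sets report
NA rather than 0 for the fraction — 0 would mean "perfect discordance",
which is not what an empty intersection shows.

## Over-representation

Hypergeometric upper tail `P(X ≥ k)` per set, after intersecting each
set with the universe (default universe: genes passing the prefilter, a
proxy for post-filtering test universes); sets with fewer than
`min_set_size` (default 3) members in the universe are skipped with a
warning. Only over-representation is tested. BH across tested sets,
significance at q ≤ 0.05 by default.

## Gene-length comparison

Two-sided Mann-Whitney U with midrank ties; the exact null distribution
when `n_up·n_down ≤ 10,000` and no ties are present, otherwise the
normal approximation with tie correction. Sidedness of the original
analysis is not stated anywhere authoritative, so the test is two-sided
and the direction (which set is longer, by median) is reported
separately. Gene length is `end − start + 1` (1-based inclusive) when
coordinates are given, else the `length_bp` column directly.

## Pipeline

`run_all` executes simulate → prefilter → normalize → clocks → trend →
cluster → overlap → enrichment → UV/GLTD from a single YAML config, all
randomness funnelled through named seeds, and writes a manifest with a
SHA-256 hash per output; two runs with the same config produce
identical hashes. The overlap stage, which on real exit data would
compare per-day exit signatures, is demonstrated on synthetic runs by
comparing the full-course trend signature with the signature of the
course without its final timepoint. Stage failures abort with the stage
name; partial outputs are retained.

## Problem sizes

Test and acceptance fixtures use 400–2000 genes, 9–60 samples, and 500
resampling iterations — sizes at which every recovery statistic in the
suite is stable across seeds (held-out clock r ≈ 0.97–0.99, trend
sensitivity ≈ 1.0 at observed FDR < 0.1, clustering ARI 1.0, UV length
test p < 1e-100) while the full suite runs in seconds.

## Known limitations

- The Gaussian trend test loses power relative to an NB GLM at very low
  counts and does not shrink fold changes.
- The clocks are validated on synthetic data only; no published
  coefficient sets or real accessions are bundled, so no claim of
  numeric equality with any published clock is made (or needed for the
  package's correctness).
- The elbow rule is one fixed operationalization of a visual criterion.
- Enrichment requires user-supplied GMT collections; there is no
  pathway-database client or identifier mapping.
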