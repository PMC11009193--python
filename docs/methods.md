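# Methods

This note documents the models, algorithms and design choices behind
`cheekclock`: what each stage assumes, which parameters matter, and what the
synthetic cohorts do and do not establish.

## Data model

Methylation is carried as probes-in-rows, samples-in-columns matrices on
either the beta scale (methylated fraction, `[0,1]`) or the M scale
(`M = log2(β/(1−β))`). All modelling happens on M values, which are
approximately homoscedastic where betas compress near 0 and 1. The beta→M
map clips betas to `[ε, 1−ε]` with `ε = 1e-3` by default so the transform is
finite; the clip is a recorded configuration value because it touches every
downstream number. Missing entries are `NaN` throughout; a cluster average
ignores missing members and is itself missing only when every member is.

Survey data follow the convention of scaling every lifestyle/health response
to `[0,1]` and coding binary demographics as −1/+1. Replicate samples (two
swabs from one person) share a `replicate_group` id; groups are atomic in
every train/test split.

## Synthetic cohorts

The generator emulates an adult buccal methylation study at desk scale. Per
probe, the M value is

```
baseline + cell-mixture term + cluster latent + age term + lifestyle term + noise
```

* **Baseline** — bimodal (`N(−2.5,1)` or `N(+2.5,1)` per probe), as array
  M-value distributions are.
* **Cell mixture** — two pseudo cell types with Dirichlet(8,4) proportions
  per sample; 10% of probes differ between the types by `N(0, 0.5)` M. These
  delta probes double as the deconvolution reference.
* **Cluster latent** — every true cluster shares a per-sample `N(0, 0.1²)`
  component. This is what makes a cluster a recoverable object: member
  probes are correlated beyond their planted signal, and unlike probe noise
  the latent does not average out within a cluster, so it sets the accuracy
  floor of cluster-level models.
* **Age term** — planted clusters drift linearly at `sign · |N(0.02, 0.005²)|`
  M per year (sign fair), centred mid-range. Over a 75-year span this is a
  1–2 M-unit excursion, the size of a strong aging CpG.
* **Lifestyle term** — selected clusters additionally respond to a survey
  factor at 0.5 M per unit response, *directed along the cluster's age
  slope*: a less healthy response pushes the methylome toward its older
  state, so delta-age associations have a coherent sign across clusters (the
  directionality the phenomenon itself has — health effects accelerate, not
  randomly scramble, the aging trajectory). By default lifestyle clusters
  also carry their own age slope; a lifestyle signal can only surface in
  delta age if it rides on inputs that predict age at all.
* **Noise** — i.i.d. `N(0, 0.3²)` M per probe, a typical residual scale for
  buccal EPIC data.
* **Survey** — responses are Gaussian-copula transforms of latents
  correlated with age (uniform marginals on `[0,1]`); default sign pattern
  has smoking and reported stress declining with age and self-perceived
  aging rising. Ages are uniform on 18–93 to keep bias checks unconfounded
  by cohort shape.
* **Sex signal** — X probes hemimethylated (M ≈ 0) in XX-like samples and
  shifted off zero in XY-like ones; Y probes carry signal only in XY-like
  samples.
* **Replicates** — chosen samples are duplicated with `N(0, 0.1²)` M
  technical noise, mirroring a paired-swab test-retest design (the
  production-scale analogue used 190 pairs).

All randomness flows from one integer seed through a single generator, so
identical seeds give byte-identical cohorts on any platform — this is part
of the test contract, not a convenience.

**What the generator does not emulate:** array chemistry (intensities, dye
bias, probe types), batch effects, non-uniform age structure, correlated
probe noise beyond the cluster latent, non-linear age trajectories, and
missingness patterns. Passing tests therefore show that the machinery
recovers planted linear structure under Gaussian noise at these effect
sizes — not that a real cohort of this size would yield a clock of equal
accuracy.

## Preprocessing

Probe filtering applies rules in a fixed, reported order — exclusion list →
detection-p failures → missingness → sex chromosomes → variance — and the
report is a partition: every input probe is accounted for exactly once.
Auditability substitutes for any particular published recipe; thresholds are
explicit configuration.

Sex calling summarises each sample by the fraction of Y-chromosome probes
with M above a signal floor and splits the scores by exact two-class 1-D
clustering (the split minimising within-class sum of squares — deterministic,
unlike seeded k-means); calls within 20% of the class gap of the boundary
are `undetermined`.

Cell-type proportions solve nonnegative least squares against reference
M-value profiles with a sum-to-one constraint, implemented as NNLS on a
penalty-augmented system followed by exact renormalisation; the penalty
weight (100× the reference scale) makes the augmented solution agree with
the exactly constrained one to well below the reported precision.

The PCA diagnostic (default 18 components) correlates every survey and
technical variable with the leading PCs of the cluster-averaged inputs — the
pre-training check that age and lifestyle structure actually reached the
model inputs.

## Clustering

Probes are clustered by profile similarity: correlation distance
(`1 − Pearson r` across samples), average linkage, dendrogram cut so merges
stop at `r < 0.7` by default. "Top" clusters are ranked by size descending
(averaging more probes suppresses measurement noise, the stated purpose of
cluster inputs), ties by mean member variance, then id — the ranking rule is
a logged choice, since no canonical definition exists. Production-scale runs
keep the top 10,000 clusters; synthetic cohorts are built small enough that
all clusters are kept. Clustering is single-path (scipy `pdist`/`linkage`);
cohorts beyond ~50k filtered probes would need a chunked distance
computation that is not implemented.

## The annealing objective

The score of a cluster subset with OLS-fitted weights is

```
S = w_rmse · RMSE(pred, age) + w_sig · Σ_f log10 max(p_f, sig_floor) + w_cplx · k
```

with defaults `w_rmse = 1.0`, `w_sig = 1.0`, `w_cplx = 0.5`,
`sig_floor = 1e-10`, `k` the subset size. Two refinements proved necessary
in implementation, both configurable:

* **Age-partialled significance.** `p_f` is the two-sided test of the
  *partial* correlation between delta age and factor `f`, controlling for
  chronological age. With plain correlations the objective is degenerate: a
  badly fitting model's delta is approximately `−age`, which correlates with
  every age-linked survey factor, so the search is rewarded for predicting
  badly. Partialling out age removes exactly and only that channel. (The
  public `delta_age_pvalues` also offers the unadjusted form, which is what
  the final multivariate association analysis builds on.)
* **Evidence saturation.** p-values are clipped at `sig_floor` inside the
  objective, so one factor's evidence is worth at most 10 orders of
  magnitude. Without the cap the significance term spans ~100 log units at
  cohort sizes of a few hundred and the accuracy/significance balance
  becomes a knife edge — any `w_sig` large enough to matter drowns the RMSE
  term entirely. With the cap, one extra cluster must buy half a year of
  RMSE or a few orders of magnitude of association evidence, which is the
  trade-off the method is meant to make. The weights were calibrated on
  synthetic cohorts and logged; they are configuration, not constants.

The search itself: start from a random 3-subset; propose add/drop/swap of
one cluster (probabilities 0.3/0.3/0.4, size capped at 15 by default); refit
OLS weights for every proposal; accept by the Metropolis rule
`P = min(1, exp(−ΔS/T))`; cool geometrically (`c = 0.995` per iteration,
2000 iterations default); return the best subset ever visited. The starting
temperature is auto-calibrated so that ~80% of worsening moves would be
accepted over a 100-move warm-up walk — a standard schedule, recorded in the
trace. Fixed seed ⇒ identical trajectory; the per-iteration trace
(temperature, current score, best score) is available for audit. Production
scale repeats the search 1098 times; ensembles combine the top 100. On
synthetic cohorts the suite verifies the annealer against exhaustive subset
enumeration on universes of ≤ 15 clusters.

## Ensemble, rotation, cross-validation

The top-k models by score are combined with worst-anchored linear weights,
`w_i ∝ S_worst − S_i + ε` (`ε = 1e-9·|S_worst|`), normalised to sum to one:
parameter-free, and a strictly lower score gives a strictly higher weight;
identical scores fall back to uniform. A softmax alternative would introduce
a temperature parameter with no principled default. The ensemble stores the
training mean of every cluster it uses, so prediction on matrices missing a
cluster imputes from the clock itself — serialized clocks are
self-contained.

The age-bias rotation fits `raw = a·age + b` on training data and applies
`(raw − b)/a` at predict time, so the corrected-vs-age regression has slope
1 and intercept 0 on the training set (and the MAB metric is 0 there by
construction). It is fitted strictly on training folds — applying it must
never peek at test labels.

Cross-validation (default tenfold, 12 models per fold) assigns whole
replicate groups to folds, trains a fold ensemble plus rotation on each
training split, and gives every sample exactly one out-of-fold prediction.

## Evaluation

* `RMSE`, `MAE` — standard; `R²` is the squared Pearson correlation.
* `MAB` (mean absolute bias) — fit prediction on age by least squares and
  average |fitted − identity| over observed ages; zero exactly when the
  clock has no systematic age compression or expansion.
* `MRE` (mean replicate error) — average over all replicate *samples* of
  |prediction − group mean prediction|; for a pair this is half the
  within-pair gap. The per-sample convention is documented because the
  per-pair one differs by bookkeeping only.
* The delta-age association model regresses delta on all lifestyle,
  demographic, technical and (optionally) cell-proportion covariates at
  once; categorical covariates are one-hot encoded against a first-level
  reference; aliased columns are dropped greedily with a warning;
  Benjamini–Hochberg adjusts across covariates. BH is the field-default FDR
  procedure; the suite checks it against a definition-based step-up oracle.
* The first-generation comparator is an elastic net (`l1_ratio = 0.5`,
  penalty by inner 5-fold CV) under the same replicate-aware outer folds,
  returning the same metric report and per-factor delta-age tests for
  head-to-head comparison.

The contrast the multi-objective clock exists for is demonstrated on a
cohort where the planted lifestyle factor is orthogonal to age, its clusters
are weak age markers (half-scale slopes), and the age-informative universe
is rich (60 clusters): an accuracy-only elastic net spreads weight across
the many clean age clusters and dilutes the lifestyle leak below
significance, while the annealed objective actively concentrates on the
lifestyle-responsive inputs and recovers the association out of fold. With
strong-slope lifestyle clusters both methods detect the effect; with
zero-slope clusters neither can (an OLS weight of zero carries no leak) —
the contrast regime is where the phenomenon lives, and the experiment is
configured there deliberately.

## Insight analyses

Age trajectories use equal-width bins (default 15 over the observed range,
~5-year steps on an adult cohort; equal-count binning is a config option)
and summarise each CpG by the Pearson r of its per-bin mean or variance
against bin midpoints. Selection windows default to `|r| ∈ [0.45, 0.55]`
and `[0.95, 1.0]` for means and `|r| > 0.5` for variances. Factor overlap
takes each factor's top-100 features by |r| and counts pairwise
intersections. Genomic-context enrichment uses Fisher's exact test per
island/shore/shelf/open-sea category (exact at the small counts these sets
produce, and checkable against a brute-force hypergeometric oracle) with BH
across the four categories; the array's six positional labels are collapsed
to four. Differential variability between delta-age extremes (default
cut-offs −5/+5 years) uses a two-sided F-test per CpG with BH across CpGs —
the simplest two-group variance test, exact under the generator's Gaussian
noise; on real, heavier-tailed data a robust alternative (Levene) should be
swapped in via the pluggable statistic.

## Numerical and degenerate-input policy

OLS uses `lstsq` (minimum-norm under rank deficiency, with a warning);
p-values are floored at `1e-300` before logs everywhere; zero-variance
factors test at p = 1 with a warning rather than NaN; zero-variance
predictions make R² missing rather than crash; an all-missing cluster
proposal is rejected and resampled; an empty filter result raises rather
than returning an empty matrix. Serialization uses shortest round-trip
float encoding, so save/load is bit-exact and checked byte-for-byte.

## Problem sizes

The suite's end-to-end runs use the standard synthetic cohort: 500 samples,
300 clusters (~1,200 probes), 20 age + 5 lifestyle clusters, tenfold CV
with 12 models per fold at 2,000 annealing iterations each; the
oracle-equivalence check enumerates all ≤3-subsets of 12-cluster universes
over 40 seeded repeats; null calibrations use 500 simulated association
models and 10,000 CpGs. These sizes preserve every qualitative regime of
the production-scale protocol (8,045 samples, ~200,000 CpGs, 10,000
clusters, 1098 annealing repeats) while keeping any single run in minutes
on one core.

## Known limitations

Cluster counts beyond ~50k probes need a chunked correlation path that is
not implemented; the annealer refits OLS per proposal (a weight-perturbation
move mode would search weight space as well); the F-test's normality
assumption is exact only for synthetic data; the elastic-net baseline's
`l1_ratio` is fixed rather than tuned; and the synthetic generator's
independence assumptions listed above mean real-data performance claims are
out of scope for this package's tests.
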