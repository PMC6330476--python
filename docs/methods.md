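# Methods

## Model and perturbation scheme

Counts are modelled as Y_gi ~ NB(mu_gi, sigma2_gi) with the quadratic
variance function sigma2 = mu + phi_g * mu^2; phi_g is the per-feature
dispersion. Stability is probed by resampling from the two-component
mixture f = alpha0*f0 + alpha1*f1, where f0 is the (unobservable) true
density and f1 the NB density with parameters estimated from the data.
Operationally each cell keeps its observed count with probability
alpha0 = 1 - alpha1 and is otherwise replaced by a draw from
NB(mu_hat_gi, phi_hat_g). The perturbation size alpha1 runs over an even
grid in (0, alpha_max]; alpha_max defaults to 0.1, small enough that the
perturbed data remain distributionally close to the original (the
changed-cell fraction is bounded by alpha1, and in expectation falls
below it because resampled counts can coincide with the observed ones).
AUCOR is empirically insensitive to alpha_max choices near 0.1 (tested at
0.08 vs 0.12).

The NB density is fitted once, on the original matrix, and reused for
every perturbed replicate; re-estimating per replicate would convolve the
metric with estimator noise and is not what the resampling scheme
describes.

### Mean estimation

mu_hat_gi = q_hat_{g,c(i)} * s_i, where q_hat_{g,c} is the mean of
size-factor-normalized counts over the samples of condition c. Means are
condition-specific: pooling across conditions would erase the
differential signal that the perturbation is supposed to preserve, making
every DE method look maximally unstable by construction. Means are
floored at 1e-8 so the sampler is defined for all-zero features, which
then resample to zero almost surely.

Size factors use median-of-ratios by default (per-sample median of count
ratios to the geometric-mean pseudo-reference over features with
all-positive counts), because resampling happens on the raw-count scale
and must respect library-size differences. Total-count normalization is
the documented fallback (automatic, with a warning, when no feature has
all-positive counts); both are exposed.

### Dispersion estimation

A deliberately transparent three-step estimator (not a re-implementation
of any published weighting scheme):

1. Method-of-moments: phi_tilde_g = max(0, (s2_g - m_g) / m_g^2), with
   m_g the overall mean of normalized counts and s2_g the pooled
   within-condition variance (conditions with >= 2 replicates contribute,
   weighted by their degrees of freedom).
2. Trend: lowess (frac 0.4, no robustness iterations) of
   log(phi_tilde + 1e-4) on log(m), fitted over features with mean > 1 —
   low-count MoM values are too unstable to inform the trend. The fitted
   knots are kept in `NBParams.trend` for audit.
3. Shrinkage: phi_hat = max(0.5*phi_tilde + 0.5*trend(m), 1e-8). The
   50/50 blend keeps feature-specific signal while taming the heavy right
   tail of small-sample MoM estimates.

With `robust=True` (the default when fitting the resampling density),
counts are first winsorized at the 95th percentile of a per-cell NB fit
whose dispersion is the cross-feature trend value — using each feature's
own MoM value would let an outlier inflate its own cap and escape the
clip. Because one-sided capping at the 95th percentile also clips ~5% of
clean probability mass, the winsorized pooled variance is divided by the
normal-theory consistency factor Var(min(Z, z_0.95)) ~= 0.915, which
makes the robust estimator nearly unbiased on clean data (median shift
under 8% across seeds) while removing roughly a third of the
dispersion inflation caused by 10% single-cell outliers. The lowess
smoother itself runs without robustness iterations so that outlier
resistance is attributable entirely to the winsorization flag.

## Similarity and AUCOR

The truncated phi coefficient is computed in the integer-exact form
(k*G - k1*k2) / sqrt(k1*(G-k1)*k2*(G-k2)), algebraically identical to the
normalized-covariance definition but exact for identical sets (returns
1.0, not 1 - epsilon). It is defined as 0 when either set is empty or
full: a method that selects nothing is maximally unstable by convention,
which is also the behavior observed for permutation-based methods that
cannot reach adjusted p < 0.05 at small sample sizes.

The curve anchors at (0, 1) rather than spending M runs on the identity
perturbation — Ave(alpha1) -> 1 as alpha1 -> 0 for any deterministic
method. When s0 is empty the whole curve, anchor included, is 0, so AUCOR
is exactly 0 in the degenerate regime. Integration is trapezoidal (exact
for piecewise-linear curves, no tuning), divided by alpha_max.

Defaults: alpha_max 0.1, 10 grid points, M = 10 replicates per grid
point. Scaled-down runs in the test suite and acceptance script use M = 5
with G = 2000 at 3-vs-3; these sizes keep a full four-method comparison
under a minute while leaving Monte-Carlo noise in AUCOR at the third
decimal (per-replicate rho values are stored in the curve for inspection).

RNG discipline: a master seed spawns one `SeedSequence` substream per
(grid index, replicate), so results are bit-reproducible and refining the
grid never changes already-computed replicates.

### Stratified AUCOR

Features are binned at the three quartiles of average log2-CPM
(prior 0.5). The DE method always runs on the full matrix; selection sets
and the phi universe are restricted to each stratum afterwards. Running
DE within strata would change the multiple-testing universe and conflate
stratification with re-analysis.

## Built-in DE methods

All methods implement one contract: `(counts, design, rng) -> p-values`
(NaN = not tested), followed by Benjamini-Hochberg adjustment and
selection at padj <= threshold (default 0.05; the boundary is included —
ties at the threshold have probability zero for continuous p-values).
Features with zero counts in every sample are never tested. BH is the
standard step-up, implemented directly so that NaN masking defines m
correctly; tests verify it against both a brute-force adjustment and
statsmodels.

- `nb_wald` — per-feature NB Wald z-test: effect = log-ratio of
  normalized condition means (floored at 0.125 counts so all-zero groups
  stay finite), SE from the NB Fisher information with working weights
  mu/(1 + phi*mu), dispersion fixed at the trend-shrunk estimate above.
  Algebraically a two-group NB GLM Wald test with known dispersion,
  vectorized across features. Null false-positive rate at p < 0.05 on
  5-vs-5 null data measures ~0.065-0.08 — slightly anticonservative, as
  Wald tests with plug-in dispersions are.
- `logcpm_welch` — Welch t-test on log2-CPM (prior 0.5), a deliberately
  simple stand-in for precision-weighted linear modelling. Zero-variance
  features get p = 1. Note: at 3 replicates per group its ~4 degrees of
  freedom cannot produce p-values small enough to clear BH at G in the
  thousands, so it selects nothing there — the empty-selection regime,
  AUCOR 0 — and becomes useful from about 5 replicates per group.
- `oracle(true_lfc, noise_sd)` — ranks |true log fold change| + Gaussian
  noise and selects the top decile; noise_sd tunes its stability
  continuously between the two references below.
- `constant_set(k)` / `random_k(k)` — the perfectly stable
  (data-ignoring) and maximally unstable (uniform random) references.
  Any user callable honoring the contract can be passed instead.

## Synthetic data generator

The generator emulates bulk RNA-seq at the study's default design:
(mean, dispersion) pairs with log-means ~ N(log 50, 1.5^2) truncated to
[0.5, 1e5] and dispersions (0.1 + 2/mu) * lognormal(0, 0.4) — a
decreasing mean-dispersion trend typical of bulk data; a packaged
~1000-pair table (generated once from this model; it is a synthetic
stand-in for pairs estimated from a large real dataset) supports
resampling-based generation. 10% of 10,000 features are DE, half
up-regulated; fold changes ~ N(3, 0.5^2) truncated below at 1 (so
direction labels stay meaningful); down-regulation divides the mean
(symmetric on the log scale). Library sizes are equal by construction.
Counts after outlier multiplication are rounded to the nearest integer to
stay on the NB support.

Outlier mechanisms (factors ~ U(1.5, 10)): S multiplies exactly one
uniformly chosen cell per selected feature (features selected with the
given probability, so at most one outlier per feature); R multiplies each
cell independently; M resamples each selected cell from NB with the true
mean inflated by the factor (and therefore requires the truth
parameters).

What the generator does *not* emulate: unequal library sizes (a config
hook exists but defaults off), GC/length biases, isoform structure,
correlated features, multi-factor designs. Passing tests on this
generator therefore demonstrate correctness of the machinery and
qualitative factor effects, not performance claims about any real
dataset.

## Evaluation harness

Proxy ground truth: R independent datasets (default 20; 10 in
scaled-down runs) are drawn from one truth draw with fresh NB noise; the
mean pairwise phi among the R selections estimates the method's true
stability. Rank agreement between AUCOR and the proxy uses tie-corrected
Kendall tau (Spearman optional). Sensitivity = TP/(TP+FN),
precision = TP/(TP+FP) with precision defined as 1 for an empty
selection.

Factor sweeps cover nSamp, gFeatures, pDE, mFoldChange, rDisp, pUp,
threshold, pOutlier and outlierMech. Each (level, replicate) simulates a
fresh dataset with a derived seed; the threshold sweep computes the DE
results once per dataset and repeats only the selection step. Summaries
report the mean AUCOR per level with its standard error; trend checks in
the tests tolerate one monotonicity violation to absorb Monte-Carlo noise
at desk scale. Sweep-style checks use `nb_wald` as the representative
built-in: it is the only built-in with realistic power at the default
3-vs-3 design.

## Numerical conventions and edge cases

- Counts are strictly integers; decimal "expected counts" are rejected,
  never rounded.
- Mean floor 1e-8, dispersion floor 1e-8; trend fitted only where
  mean > 1; the trend interpolates linearly in log-mean and clamps at its
  end knots.
- phi = 0 degenerates the sampler to Poisson.
- A median-ratio request on data with no all-positive feature falls back
  to total-count with a logged warning rather than failing.
- `select` never includes untested (NaN) features; selection sets are
  nested across thresholds.
- Curves must contain the (0, anchor) point and strictly increasing
  alphas; AUCOR raises otherwise.

## Known limitations

- The perturbation assumes the NB model; strong model violations would
  call for a nonparametric resampling scheme, which is out of scope.
- The dispersion estimator is a transparent MoM/trend/winsorization
  stand-in, not an adjusted-profile-likelihood or empirical-Bayes
  estimator; absolute AUCOR values shift slightly with the estimator,
  though method rankings are robust to it.
- Only two-condition designs are supported.
- The similarity is set-based; rank-weighted similarity of the full
  ordering is not implemented.
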