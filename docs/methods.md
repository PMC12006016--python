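# Methods

`trajgex` analyzes longitudinal expression data from repeated-measures
cohorts — the motivating design is PBMC profiling of young children sampled
every 3 months from age 3 to 36 months — and answers four questions per
dataset: which genes change with age, what shape those changes take, how
much of each gene's variance each covariate explains, and whether gene
categories of interest are over-represented among the changing genes.

## Temporal differential expression

### Model

For gene *g* and sample *s* of subject *i*,

    y_gis = beta_0 + f_g(age_is) + gamma_sex + gamma_season + b_gi + e_gis

on the log2 scale, where `f_g` is a natural cubic spline in age with 3
degrees of freedom, sex enters as one indicator, season as three indicators
(4-level categorical), `b_gi ~ N(0, sigma_b^2)` is a subject random
intercept and `e_gis ~ N(0, sigma_g^2)` is residual noise.

The spline basis uses the truncated-power natural-spline construction with
boundary knots at the minimum/maximum observed age and interior knots at
the 33.3%/66.7% quantiles of the distinct ages. Three degrees of freedom
are deliberately few: they span monotone, U-shaped and late-rise curves on
quarterly sampling without chasing noise, and they keep the tested
hypothesis a 3-dimensional contrast.

### Two-stage random intercept

A subject random intercept is equivalent to compound-symmetric
within-subject correlation `rho = sigma_b^2 / (sigma_b^2 + sigma_e^2)`.
Rather than fitting a full mixed model per gene, the pipeline uses the
two-stage strategy standard for repeated-measures microarray designs:

1. **Per-gene REML for rho.** For each gene the REML criterion (profiled
   over the residual scale) is evaluated on a 121-point grid of rho from
   just above the identifiability bound `-1/(m_max - 1)` to 0.99, where
   `m_max` is the largest number of samples per subject. The grid is
   vectorized across genes: for each rho, whitening each subject block
   costs one pass over the data, and the per-gene residual sums of squares
   come from one QR decomposition. Grid resolution (~0.01) is an order of
   magnitude below the precision the pooled estimate needs. Negative
   estimates are retained (truncated at the bound); genes with numerically
   zero variance are dropped from the pool and counted.
2. **Consensus pooling.** The consensus is `tanh(trimmed mean of
   atanh(rho_g))` with 10% trimming in each tail — per-gene estimates are
   noisy but share a common target, and the atanh scale symmetrizes their
   distribution.
3. **GLS per gene.** Every gene is refit by generalized least squares
   under the common block covariance `V = (1 - rho) I + rho J` within
   subject, via the closed-form whitening
   `W y = (y - ybar)/sqrt(1-rho) + ybar/sqrt(1+(m-1) rho)` per block.
   At `rho = 0` this is exactly OLS (tested to machine precision). The
   residual degrees of freedom `d_g = n - p` are the same for all genes.

### Moderated F test

Residual variances are shrunk by empirical Bayes: a scaled inverse
chi-square prior `(d0, s0^2)` is fitted by matching the mean and variance
of `log s_g^2` to their theoretical values under the hierarchical model
(digamma/trigamma moment equations, with the trigamma inverse solved by
Newton iteration). When the observed log-variances are underdispersed
relative to pure chi-square sampling noise, `d0` is infinite and every
posterior variance equals the prior scale `exp(mean(e))` — note this is
the moment-matched scale, which exceeds a degenerate common variance by
the factor `exp(log(d/2) - digamma(d/2))` (~5% at d = 20, vanishing with
d); this is the behaviour of the published estimator, kept deliberately.

The three spline coefficients are tested jointly:

    F_g = [(RSS_reduced - RSS_full) / 3] / s2_post_g  ~  F(3, d0 + d_g)

with the chi-square(3)/3 limit when `d0` is infinite. P-values are BH
adjusted in one family across all genes.

### The differential-expression flag

A gene is flagged when its adjusted p-value is below `alpha` (default
0.05) **and** the peak-to-trough fold change of its fitted marginal
trajectory is at least `fc_threshold` (default 1.10, i.e. a 10% change).
The marginal trajectory is the fitted curve on a 0.5-month age grid with
sex/season columns fixed at their sample means (effect-averaged), and
`FC_t = 2^(max - min)` of that curve. Since the filter operates on the
*fitted* fold change, a gene whose true amplitude sits just under the
threshold can occasionally be flagged when estimation noise pushes the
fitted range over it; the flag's contract is `p_adj < alpha AND
FC_t >= threshold`, which tests enforce exactly.

### Interaction tests

Whether trajectories differ by sex or HLA genotype is tested by adding
`spline(age) x factor` columns (3 per non-reference level) plus factor
main effects to the design and applying the same moderated F machinery to
the interaction columns, BH-adjusted as a separate family. The factor may
be constant within subject — it is a fixed effect, so between-subject
contrasts identify it.

## Variance partitioning

Each gene is decomposed with a variance-components model: random
intercepts for individual, season, sex and HLA genotype, plus the fixed
3-df age spline. All categoricals — even two-level sex — enter as random
intercepts so every term lands on the variance scale. REML estimation
uses Henderson's mixed-model equations: with `W = [X Z]` and the
crossproducts `W'W`, `W'y`, `y'y` precomputed, each evaluation of the
criterion

    (n - p) log S(gamma) + sum_k q_k log gamma_k
        + log|Z'Z + Gamma^-1| + log|X' V~^-1 X|

(`gamma_k` the variance ratios, `S` the generalized RSS, `V~ = I + Z
Gamma Z'`) involves only matrices of the total random-effect dimension
(tens), so a gene fits in ~25 ms. Optimization is L-BFGS-B over
`log gamma_k` bounded to [-20, 10]; failures are reported as all-NaN rows
and counted. statsmodels' general-purpose mixed-model optimizer was
evaluated for this step and converged unreliably on crossed variance
components, which motivated the dedicated estimator.

Reported fractions: each variance component over the total, where the age
contribution is the sample variance of the fitted fixed spline component
across samples (the convention for continuous covariates) and the total
is the sum of all components plus the age term and residual. Fractions
are non-negative and sum to one by construction.

## Trajectory clustering and shape archetypes

Fitted trajectories of flagged genes are Z-scored per gene across the age
grid (population SD), pairwise distances are `d = 1 - tau` with
tie-corrected Kendall tau-b, and average-linkage agglomerative clustering
is cut into k = 24 fine clusters. Average linkage was chosen for its
robustness with correlation-type distances; complete and Ward linkage are
exposed as options. k = 24 is a convention of the motivating analysis,
taken as a parameter rather than re-derived.

Each fine cluster's mean Z trajectory is classified by a deterministic
cascade replacing manual shape curation (first match wins):

1. peak-to-trough amplitude < 0.25 x the largest cluster-mean amplitude
   -> STABLE;
2. |Spearman(z, age)| >= 0.9 -> INCREASING or DECREASING by sign;
3. interior minimum with both endpoints >= min + 0.5 x amplitude -> U;
   mirrored -> INVERTED_U;
4. no net change over the first two thirds and a final-third net rise
   >= 0.25 x amplitude -> LATE_RISE;
5. otherwise nearest shaped canonical curve by Kendall tau.

Cluster labels propagate to member genes. All thresholds are in
`ShapeThresholds`. The main known confusion is late-rise curves smoothed
by the 3-df spline into near-monotone fits, which rule 2 then takes as
INCREASING; at the default settings this affects a minority of late-rise
genes and overall archetype recovery on simulated data is ~95%.

## Enrichment statistics

2x2 enrichment (e.g. disease-susceptibility genes, genes in the MHC
region chr6:28,510,120-33,480,577, Hg38, 1-based inclusive) uses the
two-sided Fisher exact test with the minimum-likelihood rule (sum of
hypergeometric point probabilities <= that of the observed table). The
reported effect is the sample odds ratio `ad/bc`, with the
Haldane-Anscombe +0.5 applied to all cells only when some cell is zero,
and a Woolf (log-OR +/- 1.96 SE) 95% interval; the conditional-MLE odds
ratio and exact conditional interval are reported alongside, since the
two conventions differ in the tails. Gene lists are intersected with the
analyzed universe first (dropped members are counted), and cells are
derived by subtraction so the table always conserves the universe.

Gene-set over-representation against user-supplied GMT collections is the
upper-tail hypergeometric `P(X >= a)`, reported unadjusted — an
exploratory convention; callers needing FDR control can feed the p-values
to `bh_adjust`. Per-gene importance counts (how many significant sets
contain each flagged gene) support word-cloud-style summaries.

## Synthetic data generator

The generator emulates the longitudinal design the analysis assumes:
subjects scheduled every 3 months from 3 to 36 months with independent
Bernoulli visit retention (a subject losing all visits keeps one so the
random intercept stays identifiable), per-subject sex, HLA genotype and
birth month, season derived from birth month + visit age (4 calendar
categories; winter raises expression by `season_amplitude`, summer lowers
it, spring/autumn are neutral — the simplest additive encoding). Each
gene draws a baseline in [6, 12] log2 units (a typical microarray range;
downstream models include intercepts, so this is cosmetic), an archetype
(default: 10% dynamic spread evenly over six shapes, 90% null) and its own
vector of subject offsets `N(0, subject_sd^2)` — per-gene draws, not one
shared vector, because inter-individual variation is gene-specific in real
data and a shared vector would make the pooled intra-subject correlation
track a single random realization.

Default condition (the "desk-scale" design): 40 subjects, 12 scheduled
visits, retention 0.5 (~240 samples), 2000 genes, amplitude 1.0 log2,
`subject_sd = residual_sd = 0.5` (intraclass correlation 0.5),
`sex_effect = season_amplitude = 0.1`. A `study_scale_config()` helper
reproduces the real cohort's scale (108 subjects, retention ~0.305,
expected ~395 samples). Realistic effect sizes for sex and season in
early-childhood PBMC are not well established; 0.1 log2 keeps them
detectable but minor, matching the small variance shares such covariates
show in cohort expression data.

Ground truth: the "dynamic" flag is amplitude-based (`amplitude x curve
range >= log2(1.10)`), not label-based — STABLE genes are planted shapes
with zero amplitude and therefore truth-negative for the
differential-expression task, mirroring the amplitude-defined flag rule.

What the generator does *not* emulate: probe-level structure and array
batch effects, gene-gene correlation, heteroscedastic per-gene residual
variances (all genes share `residual_sd`, which is why the moderation
prior typically estimates `d0 = inf` on simulated data — the prior
recovery test uses explicit scaled-chi-square draws instead), and any
outcome process (autoantibodies, disease progression). Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to real-array artefacts.

## Numerical and design choices

- Whitening-based GLS is exact, not iterative; the only tolerance is the
  rho grid (~0.01).
- Posterior variances are floored at 1e-12; an exact-fit gene (zero
  residual variance) thus yields a huge but finite F with a warning-level
  log rather than a crash.
- Quantile normalization assigns ties the mean of the tied reference
  quantiles; it is idempotent and preserves the grand mean to 1e-9.
- Probe summarization defaults to the median (robust to a single bad
  probe); normalization runs after summarization, at gene level.
- BH adjustment delegates to `statsmodels.stats.multitest`; Fisher's
  exact p and the conditional-MLE odds ratio delegate to scipy. Both are
  cross-checked in tests against independently written oracles
  (step-up formula; full hypergeometric enumeration).
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configuration implies
  byte-identical outputs, which the pipeline test verifies.

## Problem sizes used in validation

End-to-end statistical checks run at 40 subjects / 2000 genes (null
calibration, FDR/sensitivity, archetype recovery), 1000 genes for
consensus-correlation recovery, and 3 x 500 genes for variance-fraction
recovery — sizes at which the Monte-Carlo error of each checked quantity
is comfortably below its tolerance. The Fisher implementation is swept
against the enumeration oracle on 10^4 random tables with universe up to
200.
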