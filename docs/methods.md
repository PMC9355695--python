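# Methods

## Statistical model

### Directed partial-correlation scan

For a gap variable g and a criterion y, the analysis restricts to the
rows where both are observed, regresses each on an intercept plus the
covariates (sex, age, age², total intracranial volume by default; age²
is derived internally by squaring the age column), and correlates the
residuals. With n pairwise-complete rows and k non-intercept covariates,

  df = n − 2 − k,  t = r·√df / √(1 − r²),

and the one-tailed p-value is the upper-tail t probability of s·t, where
s ∈ {+1, −1} is the pre-specified hypothesized direction of the
criterion (so p < 0.5 exactly when the observed sign matches the
hypothesis). The two-tailed p is 2·min(p₁, 1 − p₁). Residualize-then-
correlate is algebraically identical to the textbook recursive and
precision-matrix partial-correlation formulas on complete-case data;
the test suite verifies both equivalences to 1e−10 and cross-checks
against an independent implementation (pingouin).

Missing data are handled pairwise: each (gap, criterion) pair is
analyzed on its own complete rows, with residualization refit there.
This preserves each variable's full information and reproduces the
per-variable N reporting convention of such scans. A variant that
residualizes every variable once on its own observed rows
(`scan_residualized`) exists for exchangeability with the permutation
null (below); the two differ only when criteria have missing entries,
and then only marginally. An r of exactly 0 counts as
hypothesis-inconsistent in all direction counts (conservative).

### Multiple-testing correction

The effective number of independent tests among m correlated variables
is estimated from the eigenvalues λᵢ of their correlation matrix:

  m_eff = Σᵢ [ 1(|λᵢ| ≥ 1) + (|λᵢ| − ⌊|λᵢ|⌋) ].

The study-wise threshold is α / (m_eff,gaps × m_eff,criteria). The raw
(fractional) m_eff is retained in outputs; the rounded integer is used
for the threshold. With 3 gap variables intercorrelated near 0.7 and 27
partly correlated criteria, this yields thresholds near 0.05/44 ≈ 0.001.

### Grouped-permutation aggregate evidence

Single associations in this regime are underpowered, so the package
tests the *pattern* of the whole scan. All variables are residualized on
the covariates first; then, B times, one random permutation of the
subject rows is applied jointly to all gap columns while the criterion
block stays fixed. Because an identical row reordering is applied to the
entire block, the within-gap correlation matrix of every replicate
equals the original exactly (and the criterion block is untouched),
while gap–criterion dependence is destroyed in expectation. Criterion
missingness stays attached to criterion rows, so every permuted pair is
recomputed on its own pairwise-complete rows and per-variable N is
preserved under the null.

Each replicate's rescan is summarized by four aggregates, compared with
the observed scan:

- n_consistent — count of sign-consistent effects (null expectation:
  50% of tests);
- n_nominal — count of one-tailed p < 0.05 (null expectation: 5%);
- mean_r — tanh of the mean of atanh(sᵢ·rᵢ): Fisher-z averaging after
  aligning each correlation with its hypothesized direction;
- λ — the median of χ²₁ quantiles of the one-tailed p-values divided by
  0.4549364 (the χ²₁ median); λ ≈ 1 under the null and grows with
  widespread weak signal. λ is computed from one-tailed p-values to
  match the directed testing; medians of even-length sets are midpoint
  averages.

The permutation p-value of each aggregate is the proportion of null
replicates with an equal-or-larger value (ties count). This convention
can return exactly 0; the add-one convention (count+1)/(B+1) is
available and recommended when p-values feed downstream computations.
QQ envelopes plot the observed p-values sorted from largest to smallest
against the rank-wise mean and 5th/95th percentiles of the null order
statistics, on raw and −log10 scales. The empirical family-wise error
rate at a threshold is the fraction of replicates whose minimum p falls
below it.

Defaults: B = 10,000 with per-replicate p/r matrices retained (about
13 MB at the default scan size); an aggregates-only retention mode
supports much larger B. All randomness flows from a single integer seed
recorded in every output.

### Sensitivity power analysis

Power for the Pearson correlation test uses the Cohen-style
approximation mirrored by standard correlation power calculators: the
critical correlation r_c = √(t²/(t² + n − 2)) with t the upper-α (α/2
two-sided) quantile of t(n − 2); z_r = atanh(r) + r/(2(n − 1));
power = Φ((z_r − atanh(r_c))·√(n − 3)), plus the opposite-tail term for
two-sided tests. One-tailed α = 0.05 is the default throughout the
package, matching the directed hypotheses; at that setting the
detectable effect sizes at n = 335 are r = 0.044 / 0.090 / 0.135 for
20 / 50 / 80% power, and r = 0.064 / 0.130 / 0.195 at n = 160 (the
smallest per-variable N of the default cohort template). `detectable_r`
inverts the power function by bracketed root finding (power is strictly
increasing in r). A pure large-sample Fisher-z variant is available
under `method="fisher"` and agrees within 0.01 for n ≥ 100.

### Stacked age-prediction scaffold

The age model is a desk-scale version of the cross-validated stacking
design used to train brain-age models on large imaging cohorts. Within
each of R repeats of a balanced k-fold split, every base learner is fit
on the training folds and predicts the held-out fold, so base
predictions are strictly out-of-fold (verified by a poisoning test:
perturbing a held-out subject's age does not change its base
prediction). Stacking weights are then fit by least squares of
chronological age on the pooled out-of-fold prediction matrix — one fit
per repeat on all n subjects, rather than per fold — and stacked
predictions are averaged across repeats (configurable to first-repeat
only). Collinear base predictions are resolved by the pseudo-inverse
(minimum-norm least squares), so duplicated learners reproduce the
single-learner fitted values. Desk-scale defaults are k = 10, 5 repeats,
~300 subjects and tens of PCA components with two linear-family base
learners; the full-scale setting this mirrors (100 repeats, 500
components, >30k subjects, relevance vector machines and gradient
boosting) is intentionally out of scope, and learners are a pluggable
fit/predict contract so any scikit-learn regressor (optionally wrapped
in a PCA pipeline) can stand in.

## Synthetic cohort generator

The generator emulates the data structure of an older-adult aging-cohort
study, not any real joint distribution. Covariates: age from a truncated
normal (mean 70.5, SD 3.8) on 61–82 years; sex Bernoulli (37.9% female);
TIV normal (1475 ± 130 ml). The gap block is drawn multivariate normal
with configurable SDs (default 2.99 / 3.71 / 3.17 years) and pairwise
intercorrelation (default 0.7, an assumption — phenotypic gap
intercorrelations are rarely reported; configurable), then residualized
in-sample against the covariate design and rescaled, so gap columns are
exactly mean-zero, exactly orthogonal to the covariates (i.e. already
bias-corrected), and hit their target SDs exactly.

Each criterion is built from a latent normal score: planted_r/w times
the standardized equal-weight composite of the gap block (w is the
population correlation between the composite and each equicorrelated
member, √((1 + (k−1)c)/k)) plus independent noise, plus an optional age
loading (default 0.2) that residualization removes. The latent partial
correlation with each gap variable given the covariates therefore equals
planted_r in the population. Shapes are produced by monotone transforms
of the latent score: linear for normal criteria; shifted lognormal
matched to a target mean and SD for skewed ones; thresholding at normal
quantiles for ordinal (category probabilities configurable) and binary
(prevalence) criteria. Discretization and nonlinear transforms attenuate
the realized Pearson correlation relative to planted_r; this is
documented, not corrected — planted_r is a latent-scale parameter. The
infeasible case (composite loading outside (−1, 1)) raises an error
naming the offending variable.

Missingness is applied separately and completely at random, masking each
criterion column to exactly its specified observed count (the real
study's missingness mechanism is unknown; MCAR is the neutral choice).
The default template mirrors a published older-adult battery: 27
criteria spanning socioeconomic, lifestyle (ordinal alcohol/smoking
items), affect, metabolic/laboratory (heavily skewed, e.g. TNF-α),
cognitive and time-horizon domains, with per-variable N from 160 to 335
and a binary diabetes diagnosis at ~10% prevalence.

What passing tests on these cohorts do show: the scan, permutation and
power machinery are calibrated (null rates 50%/5%, uniform permutation
p-values for continuous aggregates, correct planted-effect recovery) and
exact where exactness is claimed. What they do not show: robustness to
informative missingness, non-monotone gap–criterion relations,
heteroscedasticity, or real covariate–criterion confounding structure —
none of which the generator models.

The feature-matrix generator (for the age model) draws ages uniformly,
builds one age-loaded component whose correlation with age equals the
requested signal plus independent structured components, and mixes them
through random loadings with small i.i.d. noise, so the best linear
predictor of age attains approximately the requested correlation.

## Numerical choices and conventions

- Residualization solves least squares via `numpy.linalg.lstsq`; rank
  deficiency raises an error naming the collinear columns.
- |r| is clipped to 1 before the t transform; |r| = 1 maps to t = ±∞
  and exact p ∈ {0, 1} rather than NaN. Fisher averaging refuses
  |r| = 1.
- χ²₁ quantiles of p = 0 (possible for permutation p-values under the
  plain proportion convention) must be capped explicitly (use 1/(2B));
  a warning is emitted.
- Descriptive quartiles use linear interpolation between order
  statistics (type-7); skewness and excess kurtosis are the standardized
  third and fourth central moments (kurtosis minus 3), undefined for
  constant columns.
- Fold assignment balances sizes to within one subject; permutations
  come from `numpy.random.default_rng(seed).permuted`, so a seed fully
  determines every replicate.
- Pairs with fewer than k + 4 complete rows are excluded from scans
  with an explicit warning, never silently.
- The pipeline embeds the master seed and a SHA-256 config hash in every
  output file; reruns with the same config are byte-identical up to that
  stamp.

## Known limitations

- Count-based aggregate statistics (n_consistent, n_nominal) are
  discrete; with ties counted, their permutation p-values are
  conservative (super-uniform) under the null. This is inherent to the
  "proportion with same or larger" definition and is most visible for
  n_nominal, whose null distribution concentrates on few values; the
  continuous aggregates (mean_r, λ) are exactly calibrated. Use the
  add-one convention, or treat count p-values as upper bounds.
- Planted effects are latent-scale; realized Pearson correlations for
  ordinal/binary criteria are attenuated by design.
- Power calculations apply to simple Pearson correlations; for partial
  correlations with k covariates, substituting an effective n (n − k) is
  a documented approximation only.
- Desk-scale defaults (B = 10⁴ permutations, hundreds of subjects,
  dozens of components) are chosen for interactive use; the statistics
  are unchanged at larger B, only their Monte-Carlo resolution improves.
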