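# Methods

This note records the statistical models the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot tell you about real breeding data.

## The GBLUP mixed model

The phenotype of line *i* (a BLUE across environments — one value per line,
no environment structure) is modeled as `y_i = μ + g_i + ε_i` with
`g ~ N(0, σ²_g G)` and i.i.d. Gaussian residuals. `G` is the VanRaden
method-1 relationship matrix from SNP dosages (0/1/2): dosages are
mean-imputed per marker, monomorphic markers dropped by default, columns
centered at twice the allele frequency, and the cross-product scaled by
`2 Σ p_j(1−p_j)`. Allele frequencies come from the full dataset, so `G` is
fixed across cross-validation folds (the common practice when the genotype
panel is known in advance; only phenotypes are masked). A ridge `εI` with
`ε = 1e-6` guarantees the invertibility the predictor needs; it is omitted
only where a test exploits the exact GBLUP/ridge-regression identity.

Two estimation paths:

* **REML** (default, deterministic). One eigendecomposition of the
  training block `G_tt = U D U'` turns the restricted likelihood into a
  1-D function of the variance ratio `δ = σ²_ε/σ²_g`, optimized by bounded
  scalar minimization of `(n−1)·log σ̂²_g(δ) + Σ log(d_i+δ) + log(1'V⁻¹1)`
  on `log δ ∈ [log 1e-6, log 1e6]`. Test lines are predicted by the
  conditional mean. Constant training phenotypes short-circuit to an
  intercept-only fit (`σ²_g = 0`).
* **Gibbs**. Scaled-inverse-chi-square priors on both variances with
  df = 5 and scale set so each prior mode is half the training phenotypic
  variance (the usual R2 = 0.5 default rule). Sampling is done in the
  eigenbasis of the full `G`, where the conditional of the spectral
  coefficients is diagonal (O(n²) per sweep); missing (test) phenotypes
  are re-imputed each sweep, so test predictions are posterior means of
  `μ + g_i` under the standard missing-value-augmentation convention.
  Defaults: 12,000 iterations, 2,000 burn-in, thinning 5. On seeded
  simulations the Gibbs and REML predictions correlate > 0.99; the grid
  uses REML for exact reproducibility.

A fixed-variance path (`method="fixed"`) predicts at a caller-supplied δ.
With `G = WW'/c` it reproduces ridge regression on markers with penalty
`λ = δ·c` exactly (push-through identity); the test suite uses an
independent primal-ridge implementation as the oracle for this identity.

## Quantile mapping

Non-parametric empirical QM: knots are type-7 empirical quantiles of the
training predictions and training observations at `n_knots` equally spaced
probabilities in [0, 1] (`n_knots = min(100, n_train)` by default), with
monotone piecewise-linear interpolation between knot pairs. Outside the
calibrated range the default `constant_offset` policy adds the boundary
offset `y_knot − x_knot` (QUANT/RQUANT-style), which keeps the map
continuous and monotone and avoids wild linear extrapolation on small
folds; `clamp` is available. Ties enter the quantiles as-is — no
jittering, so the fit is deterministic. By construction the map is
non-decreasing, reduces the KS distance between calibration samples, and
is idempotent in distribution up to interpolation error.

Note one structural consequence: an affine transfer cannot change Pearson
correlation, so on clean, well-calibrated fits QM moves NRMSE (through
variance re-inflation of the shrunken predictions) much more than COR.

## Outlier detection

Each training observation gets K = 3 two-sided p-values from residual
diagnostics of an inner 5-fold cross-validated GBLUP fit (shrinkage pinned
by one REML fit on the whole training fold):

1. out-of-fold residual standardized by median/MAD, referred to N(0,1);
2. the same residual studentized by its leave-one-out standard deviation,
   referred to t with (inner training size − 2) df;
3. squared Mahalanobis distance of the (observed, predicted) pair after a
   rank-to-normal-scores transform of each coordinate, referred to χ²₂.

P-values are floored at 1e-300 and clipped below 1 − 1e-16 before logit or
probit transforms. The four combiners follow their closed-form nulls —
Fisher `L = Σ −2 ln p_k ~ χ²_2K`; Mudholkar–George
`T = −Σ logit(p_k)/C ~ t_{5K+4}` with
`C = sqrt(K π² (5K+2) / (3(5K+4)))` (the normalizer the t null requires);
Edgington `W = (0.5 − p̄)√(12K) ~ N(0,1)`; Stouffer
`Z = Σ w_k Φ⁻¹(1−p_k)/√(Σ w_k²) ~ N(0,1)`, unit weights by default. All
four are oriented so small base p-values give large positive statistics,
and all are monotone in each p_k. Lines with combined p < α (default 0.01,
unadjusted; Bonferroni/BH available) are removed from the training set by
the evaluation layer; if fewer than 10 training lines survive, the fold is
marked failed and excluded from averages.

A caveat stated openly: the three diagnostics are computed from the same
observation and are therefore positively correlated (the two residual
tests strongly so), while the combiners' nulls assume independence. On
clean data this inflates the flagged fraction above the nominal α —
roughly 5–8% per method at α = 0.01 in our simulations, mean ≈ 6.5%
across the four methods — an inherent property of combining marginal
diagnostics of a single observation, shared by the meta-analytic approach
this follows. The combiners themselves are exactly calibrated under
independent uniform p-values (verified by simulation), so the base-test
construction, which is pluggable behind the `PValueMatrix` interface, is
the only source of this inflation.

## Evaluation protocol

Cross-validation is Monte Carlo: `n_reps = 10` independent seeded random
80/20 train/test splits (an exhaustive k-fold switch exists; note that
"10-fold" with 80/20 folds is not standard k-fold, which would use 90/10 —
the repeated-split reading is implemented as the default). Within a fold
all ten variants share the split and the GRM; the four filters share one
base p-value matrix, and variants with identical post-filter training sets
share the GBLUP fit. Metrics: sample Pearson correlation (COR; recorded as
missing with a warning when either vector is constant, and excluded from
averages) and RMSE normalized by the mean of the observed test values
(NRMSE; `sd` and `range` normalizers available, since the conventional
normalizer is ambiguous and trait-scale dependent). Percent differences
between variants use two conventions matching how such results are usually
narrated: for COR the comparison method is the denominator
(`100·(ref − other)/other`); for NRMSE the reference (lower-error) method
is (`100·(other − ref)/ref`). Across-dataset summaries are unweighted
means of per-dataset per-variant averages.

## Synthetic data

`simulate_genotypes` draws each marker independently: allele frequency
uniform on `maf_range` (default 0.05–0.5), dosages Binomial(2, p) under
Hardy–Weinberg. `simulate_phenotypes` places `n_qtl` additive QTL (default
min(300, n_markers)) with Gaussian effects on centered dosages, rescales
the genetic values so realized `var(g) = h²·trait_sd²`, and adds noise
with variance `(1−h²)·trait_sd²` — Gaussian, or standardized
shifted-gamma when `skew ≠ 0` (gamma shape `(2/skew)²` reproduces the
requested skewness coefficient exactly). Defaults: heritability 0.5, trait
mean 5 and SD 1 (a yield-like scale keeping mean-normalized NRMSE
well-defined). Contamination adds `±outlier_magnitude` residual SD
(random sign) to `round(outlier_fraction·n)` randomly chosen lines and
records them in `true_outlier_flags`. Everything is bit-reproducible from
`config.seed`; named profiles reproduce the line counts of real breeding
panels (Indica 327, EYT_1 776, Wheat_1 1301, ...) with marker counts
capped at 5,000 (`MARKER_CAP`) — prediction accuracy from a relationship
matrix saturates in markers well below real array sizes, and the cap keeps
single-CPU runs fast.

**What this generator does not emulate.** Lines are unrelated and loci
unlinked, so the GRM has no family or population structure and prediction
accuracy is capped near `r(g, ĝ) ≈ sqrt(n h² / (n h² + M))` — e.g. ≈ 0.3
for 320 training lines, h² = 0.5, 2,000 markers — well below the 0.4–0.65
typical of real panels, where relatedness and LD carry most of the signal.
Absolute COR/NRMSE levels from these simulations are therefore not
comparable to results on real data; the simulations support *relative*
comparisons among the ten variants, calibration checks, and recovery of
known truth (heritability, planted outliers). Likewise, a single
homoscedastic trait is simulated: no genotype-by-environment structure,
no non-additive effects, and the contamination mechanism is a pure
location shift — the canonical detectable outlier, chosen because real
datasets' outlier mechanisms are unobservable.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the package's
own study conditions: 10-variant × 10-fold grids at 400 lines × 2,000
markers; combiner calibration on 10,000 uniform p-value rows (K = 5); REML
recovery over 20 seeds at n = 300; outlier precision/recall and clean
calibration over 20 seeds at n = 400. REML optimization uses `xatol = 1e-8`
on `log δ`; eigenvalues are clipped at zero; the GRM ridge is `1e-6`;
fold-level and sampler seeds all derive deterministically from a master
seed, and no code path draws from global random state.

## Known limitations

* Clean-data flagging rates exceed the nominal α (see above); thresholds
  should be interpreted as ranking cutoffs, not calibrated error rates.
* The Gibbs path reports posterior means only — no convergence statistics
  beyond counts, and no credible intervals.
* Relative-efficiency percentages are point summaries; no uncertainty is
  attached to variant comparisons (fold correlations make naive standard
  errors misleading).
* VCF ingestion is read-only and biallelic-SNP-only; no PLINK formats.
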