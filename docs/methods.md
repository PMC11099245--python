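# Methods

`mrscreen` implements a genome-wide two-sample Mendelian randomization
(MR) screen from summary statistics: many molecular exposures (the
motivating application is circulating miRNA expression, instrumented by
cis-eQTLs) tested against a handful of disease outcomes (Parkinson's
disease risk and its clinical sub-phenotypes). This note records the
models, the numerical choices, and what the synthetic-data studies do
and do not demonstrate.

## The causal model

For instrument (SNP) j, let `bx_j` (SE `sx_j`) be its estimated effect
on the exposure and `by_j` (SE `sy_j`) its estimated effect on the
outcome, both per copy of a common effect allele. Under the
instrumental-variable assumptions (association with the exposure,
independence from confounders, no direct path to the outcome), each SNP
identifies the causal effect `theta` through its Wald ratio
`by_j / bx_j`, and the estimators differ in how they pool J ratios and
which violations they tolerate:

- **IVW** — zero-intercept regression of `by` on `bx` with weights
  `1/sy^2`. Unbiased only if every instrument is valid. The reported SE
  is the fixed-effect SE times `max(1, sqrt(Q/(J-1)))` (multiplicative
  random effects; over-dispersion inflates, under-dispersion never
  deflates). Normal reference for CI and p.
- **MR-Egger** — the same regression with a free intercept, after
  orienting instruments so `bx_j >= 0`. The intercept absorbs
  directional pleiotropy provided direct effects are independent of
  instrument strength (InSIDE). Inference uses t with J-2 df and the
  same floored multiplicative scale.
- **Weighted median** — per-SNP ratios weighted by the inverse
  first-order ratio variance `(sy_j/|bx_j|)^2`; the estimate
  interpolates the weighted empirical ratio distribution at probability
  1/2 and is consistent while valid instruments carry more than half
  the weight. SE by parametric bootstrap (default 1000 draws, seeded).
- **cML-MA** — constrained maximum likelihood: minimize
  `sum_j [(by_j - theta*g_j - r_j)^2/sy_j^2 + (bx_j - g_j)^2/sx_j^2]`
  with at most K direct effects `r_j` nonzero, for K = 0..J-2. For
  fixed `theta`, each valid SNP's `g_j` profiles out in closed form and
  a SNP's inclusion among the K invalid removes exactly its profile
  contribution `(by_j - theta*bx_j)^2 / (sy_j^2 + theta^2 sx_j^2)`, so
  the block-coordinate iteration alternates a top-K selection with
  closed-form `theta`/`gamma` updates, restarted from five perturbed
  starts (perturbation scale proportional to the IVW slope plus the
  ratio spread, which keeps the optimizer equivariant under rescaling
  of the outcome). Models are combined with weights
  `exp(-(BIC(K)-min BIC)/2)`, `BIC(K) = nll(K) + K log J` on the
  2x-negative-log-likelihood scale; per-K SEs come from the profile
  Fisher information over `(theta, gamma_valid)` and the model-averaged
  SE uses Buckland's formula (per-K variance plus between-model
  dispersion). This is the BIC model-averaging variant; the
  data-perturbation variant is out of scope.

With a single instrument only the Wald ratio is reported (SE
`sy/|bx|`); with two, only IVW (Egger with two points is saturated and
inference-free — the line solver is still exposed for algebra checks).

## Instrument selection

Filters run in a fixed, logged order per exposure:

1. keep p < 5e-8; if fewer than `min_snps` (default 1) survive, retry
   at the relaxed tier p < 1e-5 (the tier used is recorded);
2. greedy LD clumping: rank by ascending p (ties by variant ID), keep
   the best, discard same-chromosome variants within 10 Mb with
   r^2 >= 0.001 against it, repeat. Without an LD table clumping is a
   logged no-op — the synthetic scenarios generate unlinked SNPs, and
   LD is an input here, never computed from genotypes;
3. drop variants on the user-supplied confounder exclusion list (a
   reproducible stand-in for live variant-lookup services);
4. drop variants associated with the outcome at p < 5e-8 (the
   threshold is configurable; "associated with the outcome" has no
   canonical cutoff);
5. drop weak instruments: per-SNP `F = R^2 (N-2) / (1-R^2)` must exceed
   10, with `R^2 = 2 eaf (1-eaf) beta^2` (standardized traits) or
   `t^2/(t^2+N-2)` when frequency is missing. The set-level F (total
   R^2, K = set size) is reported for information.

An empty set is a valid outcome: the pair is reported untestable and
never aborts the screen.

## Harmonization

Per variant present on both sides: identical allele pair is kept;
swapped orientation negates the outcome beta and mirrors its frequency;
a pair matching only after A<->T/C<->G complementation is strand-flipped
then resolved the same way (configurable off); palindromic (A/T, C/G)
variants are dropped outright — frequency-based rescue exists but is
off by default because strand is genuinely unresolvable near
frequency 0.5; anything else (including indels) is a mismatch drop.
Magnitudes and SEs are never altered, only signs and frequencies, which
makes harmonization idempotent.

## Sensitivity battery

- **Cochran's Q** on the per-SNP ratios with weights `(bx_j/sy_j)^2`;
  chi-square with J-1 df. Q also drives the IVW random-effects scale,
  so the two are internally consistent.
- **Egger intercept test**: intercept p < 0.05 flags possible
  directional pleiotropy.
- **MR-PRESSO** (J >= 4): the observed residual sum of squares uses
  leave-one-out slopes (each SNP's residual is taken against the IVW
  slope fitted without it, weighted by `1/sy^2`); the null distribution
  re-simulates `by_j ~ N(slope_-j * bx_j, sy_j^2)` (default 1000 draws)
  and recomputes the RSS including its leave-one-out slopes. Empirical
  p-values carry the (+1)/(+1) correction and are therefore never zero.
  Per-SNP outlier p-values are Bonferroni-corrected across J. The
  distortion test runs only when outliers are flagged: the relative
  change in slope after removing them is compared against removing
  random subsets of the same size. Instruments are processed in sorted
  variant order so results are invariant to input order at a fixed
  seed. Note the null model treats instrument effects as known: the
  global test is calibrated when `theta^2 sx^2 << sy^2` and grows
  anti-conservative as exposure-side noise becomes comparable to
  outcome noise — the calibration study below is run in the regime the
  method assumes.
- **Leave-one-out** IVW per excluded SNP plus an all-SNP reference row.

## Multiple testing and classification

The IVW (or Wald) p-value is primary. Storey q-values are computed per
outcome across exposures (the family choice is configurable to pooled):
`pi0(lambda) = #{p > lambda}/(m(1-lambda))` on lambda = 0.05..0.95,
smoothed with a natural cubic smoothing spline and evaluated at
lambda = 0.95, clipped to (0,1]; `q_(i) = min_{j>=i} pi0*m*p_(j)/j`.
With pi0 = 1 this is exactly Benjamini-Hochberg, and families smaller
than 20 fall back to pi0 = 1 because the spline is unstable there.
A pair is *significant* at q < 0.1, *nominal* at p < 0.05 with
q >= 0.1, otherwise *null*; pairs with no surviving instruments are
*untestable*. Cross-outcome summaries count nominal-or-better outcomes
per exposure and select those reaching `min_outcomes` (default 4,
i.e. "more than three").

## Target-gene enrichment

Screen hits map to target genes through a user-supplied two-column
table (a static stand-in for validated-interaction databases, whose
live contents are version-dependent); the pooled target set is tested
per GMT gene set with the hypergeometric upper tail
`P(X >= k | M, K, n)` and BH adjustment across sets. The universe
defaults to the union of set members; supplying an explicit background
is recommended whenever one is available.

## Synthetic data generator

Per SNP: `eaf ~ U(0.05, 0.5)` (avoids degenerate variance),
`gamma_j ~ N(mean, sd)` (defaults 0.35/0.05 — a few strong cis
signals), standardized-trait SEs `1/sqrt(2 eaf (1-eaf) n)` with
defaults `n_exp = 710` (a realistic miRNA-eQTL discovery cohort) and
`n_out = 50000`; `bx_j ~ N(gamma_j, sx_j^2)`,
`by_j ~ N(theta*gamma_j + alpha_j, sy_j^2)`. Direct effects `alpha_j`
are zero for valid instruments; invalid fractions draw them centred at
zero (balanced), off-centre (directional), or proportional to `gamma_j`
plus noise (correlated — violating InSIDE). Outcome rows randomly swap
allele orientation (beta negated, frequency mirrored) so harmonization
is always exercised, and a requested fraction of SNPs receives
palindromic allele pairs. Optional LD blocks share a common noise
factor achieving a chosen within-block r^2 and emit the matching LD
table; block positions are 20 Mb apart so only within-block pairs fall
inside a clump window. One root seed spawns a deterministic substream
per exposure.

What the generator does **not** emulate: realistic genome-wide LD
structure, allele-frequency spectra or polygenic outcome architecture;
sample overlap between the two GWAS; population stratification; indels
or multi-allelic sites. Passing simulation tests therefore demonstrates
correctness of the statistical machinery under its own assumptions, not
robustness to those real-data complications.

## Validation studies and problem sizes

`scripts/acceptance.py` (and the mirrored tests) recomputes, per run
seed:

- exact algebra fixtures (3-SNP IVW, two-point Egger line, equal-weight
  weighted median, the F formula at R^2 = 0.05, N = 710, K = 1);
- oracle agreement: the cML constrained optimum per K against
  exhaustive invalid-subset enumeration with dense-grid profiling at
  J = 8 (best-of-5 starts, since a single start of a coordinate
  descent can land in a local optimum), and hypergeometric ORA
  p-values against full combinatorial enumeration at M = 15;
- calibration at 500 replicates: IVW null rejection at the 0.05 level
  (J = 20, strong instruments); Egger intercept size under balanced
  pleiotropy; and a Kolmogorov-Smirnov uniformity check of 100
  MR-PRESSO global p-values at 200 simulations each, in the
  precise-instrument regime discussed above;
- recovery at 500 replicates: mean IVW at theta = 0.5; weighted-median
  versus IVW absolute bias under 40% balanced-invalid instruments;
  cML-MA versus IVW absolute bias and the modal selected invalid count
  under 30% directional-invalid instruments at J = 10;
- pipeline rules: the harmonization action fixtures, the clumping
  fixture, the BH hand-check, and an end-to-end screen of 50 null plus
  5 causal exposures (theta = 0.5, J = 10, outcome cohort of 1000 so
  instruments predict the exposure strongly but the outcome only
  weakly — large outcome cohorts would push signal SNPs past
  genome-wide significance on the outcome and the overlap filter would
  correctly strip them).

Replicate counts (500 for calibration/recovery, 200 simulations for
the per-replicate PRESSO check, reduced bootstrap/simulation counts
inside the screen study) keep the whole battery within a couple of
minutes on one CPU while leaving Monte-Carlo error well inside the
asserted bands.

## Known limitations

- No proxy-variant substitution, genome-build liftover, or LD
  computation from reference genotypes; LD is always an input.
- The Egger intercept test has low power when instrument strengths are
  homogeneous (the intercept is then nearly collinear with the slope).
- cML-MA model-averaged SEs can understate uncertainty when two K
  models with very different estimates share weight; the BIC-minimizing
  K and full weight vector are exposed in `extras` for inspection.
- MR-PRESSO's outlier test can cascade (flag neighbours of a gross
  outlier) because the contaminated leave-one-out slopes bias every
  residual; this mirrors the method's reference behaviour.
- The q-value smoother needs a reasonably large p-value family;
  per-outcome families smaller than 20 silently become BH (logged).
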