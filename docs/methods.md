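# Methods

## Model and assumptions

The package implements two-sample summary-data Mendelian randomization.
For SNP j, let (b_Xj, se_Xj) be its association with the exposure and
(b_Yj, se_Yj) with the outcome, estimated in non-overlapping samples. Under
the instrumental-variable assumptions (relevance, independence from
confounders, and exclusion restriction), each Wald ratio b_Yj/b_Xj
estimates the causal effect of X on Y; for a binary outcome the betas are
log-odds and estimates exponentiate to odds ratios.

Estimators:

- **IVW** — weighted least squares of b_Y on b_X through the origin with
  weights 1/se_Y^2, algebraically the inverse-variance-weighted mean of the
  Wald ratios with first-order weights (se_X is ignored in the weights,
  matching the ratio SE convention used throughout). Cochran's
  Q = sum_j (b_Xj/se_Yj)^2 (ratio_j − beta_IVW)^2 against chi-square(n−1)
  decides the error model: when Q rejects at alpha = 0.05 the SE is
  inflated by sqrt(Q/df) floored at 1 (multiplicative random effects),
  otherwise the fixed-effect SE stands. IVW p-values are two-sided normal.
  One SNP degenerates to the Wald ratio.
- **MR-Egger** — the same regression with a free intercept, after orienting
  every pair so b_Xj ≥ 0. The slope is consistent under InSIDE (instrument
  strength independent of direct effects) even with directional pleiotropy;
  the intercept estimates the mean direct effect and serves as the
  pleiotropy screen. The residual variance is floored at 1 so the SEs never
  undercut fixed effects; p-values are two-sided t with df = n − 2. The t
  convention (not normal) reproduces the intercept p-values printed in the
  packaged fixtures — e.g. intercept 1.31e-4, SE 2.60e-3 at 68 SNPs gives
  p = 0.960 under t(66).
- **Weighted median** — the ratio at cumulative normalized weight 0.5
  (weights 1/se_ratio^2, linear interpolation), consistent when valid
  instruments carry a majority of the weight. Its SE comes from a seeded
  parametric bootstrap (default 1000 resamples of b_X and b_Y from normals
  with their reported SEs).
- **MR-PRESSO** — per-SNP residuals against leave-one-out IVW fits,
  weighted by 1/se_Y^2 and summed into the global RSS. Parametric
  simulation (default 1000 draws) under the no-pleiotropy expectation gives
  plus-one empirical p-values: global (RSS tail), per-SNP outlier
  (Bonferroni-corrected by the SNP count; note flagging is only possible
  when n_sim exceeds n_snp/alpha), and a distortion test comparing the
  with/without-outlier IVW contrast against random pseudo-outlier sets of
  the same size. Flagged outliers are removed and IVW is recomputed rather
  than silently substituted.

Multiplicity is controlled per screen family with Benjamini–Hochberg
(statsmodels' step-up implementation behind `bh_adjust`); a trait is a
mediator when both of its steps have q < 0.05 and neither Egger intercept
has p < 0.05. The mediated effect is the product of coefficients
beta1·beta2 with a Sobel delta-method SE
sqrt(beta2^2 se1^2 + beta1^2 se2^2) attached as an extension (published
mediation tables of this design report no uncertainty). Proportions
mediated, 100·beta1·beta2/total, are signed and untruncated: a mediator
working against the total effect yields a negative percentage.

## Harmonization and instrument selection

Defaults: instrument p < 5e-8; greedy clumping keeps the smallest p-value
and discards same-chromosome neighbours within 10,000 kb with r^2 ≥ 0.001
(ties broken by chromosome, position, then identifier, for determinism);
instruments with outcome association p < 5e-8 are excluded. LD is consumed
as an explicit matrix (long-format TSV or identity); when absent, SNPs are
treated as independent and a warning is logged — the package never
downloads a reference panel.

Harmonization aligns outcome records to the exposure's effect allele:
swapped alleles negate the outcome beta and complement its allele
frequency; strand flips (A<->T, C<->G on both alleles) are matched after
complementing. Palindromic SNPs are inherently ambiguous and are kept only
when both allele frequencies are present, both fall outside 0.5 ± 0.08,
and they agree in orientation; otherwise dropped. Duplicate SNP rows keep
the smallest p-value. Missing allele frequencies are written as the
explicit marker `NA`, never imputed as 0 or 0.5.

## The synthetic-data generator

`simulate_three_trait_gwas` emulates the summary-statistics geometry of a
two-sample mediation study. Per-SNP instrument effects on the exposure are
half-normal with scale `gamma_sd` (default 0.15) — effect alleles oriented
to the trait-increasing direction, as instrument lists conventionally
report them; with symmetric effects a planted *directional* pleiotropy
would be indistinguishable from balanced pleiotropy after Egger's
orientation rule. Observed betas add homoscedastic study noise (defaults
se 0.003 / 0.02 / 0.03 for exposure, mediator and outcome, chosen so the
instrument strength ratio gamma_sd/se_exp = 50 makes essentially all 30
exposure instruments genome-wide significant, like the strong BMI
instruments of large consortia). The mediator inherits theta1 times the
exposure effects and additionally carries `n_snp_mediator` (default 30)
instruments of its own, whose effects reach the outcome only through
theta2. The mediator-own block is a deliberate design choice: SNPs acting
on the mediator solely through the exposure are invalid instruments for
the mediator→outcome step (the exposure's direct path is open), so without
that block the two-step design is unidentifiable. The outcome combines the
direct effect tau_direct and the mediated paths sum(theta1·theta2) on the
exposure block. Defaults theta1 = 0.2, theta2 = 0.3, tau_direct = 0.3
give a total effect of 0.36 and a true proportion mediated of 16.7%.

Optional pleiotropy adds per-SNP direct outcome effects alpha on the
exposure block: balanced (mean 0) or directional (mean `pleiotropy_mean`),
independent of instrument strength, so InSIDE holds. Allele frequencies
are uniform on (0.05, 0.40), away from the palindrome ambiguity band, and
SNPs sit 20 Mb apart so default clumping windows never interact (a supplied
block LD matrix exercises clumping explicitly). Binary outcomes are
generated directly on the log-odds scale; there is no individual-level
liability simulation, no LD by default, no sample-overlap correlation, and
no eaf-dependent heteroscedasticity (an SE proportional to
1/sqrt(2·eaf·(1−eaf)·n) would be the natural extension). Passing tests on
this generator therefore demonstrate correctness of the estimators and the
screening logic under idealized sampling, not robustness to weak
instruments, overlapping samples, or misspecified LD.

## Packaged fixtures and verification

The fixtures are machine-readable copies of a published screen: 176
BMI-associated metabolic traits, 85 gallstone-disease-associated traits
(with odds ratios), and the 49 mediators in their intersection, keyed by
study accession, with all values at the three significant figures of the
source tables. `verify_fixtures` recomputes each derivable cell — OR and
CI from (beta, se), Egger intercept p from (intercept, se, n_snp) under
t(n−2), mediation effects as beta1·beta2, and the intersection count — and
flags a cell only when the printed value (± half a unit in its last
significant figure) is disjoint from the interval obtained by propagating
the same half-unit rounding through the inputs (corner evaluation; all the
recomputed functions are monotone in each input). Naive one-unit
comparison would false-flag dozens of p-value cells whose inputs round
with 0.5% relative error. The shipped tables pass with zero discrepancies
across 664 cells. The total effect used for the printed proportions is not
itself printed in the source tables; the fixture audit uses the value
implied by mediation_effect/proportion, which is constant across all 49
rows to within 1% relative spread (mean 0.428 on the log-odds scale).

## Problem sizes and numerical choices

The calibration studies use 30-instrument systems: 1000 replicates for
Cochran's Q null calibration, 500 for IVW coverage, 200 each for Egger
pleiotropy recovery and mediation-proportion recovery, and 40 for
MR-PRESSO planted-outlier detection at n_sim = 1000 — sizes at which every
Monte-Carlo band in the tests is computed from the binomial at the 99%
level. Empirical p-values use the plus-one convention, so none can be
exactly zero. All simulation and bootstrap randomness flows through
numpy's `default_rng` from explicit seeds; reruns with the same seed are
byte-identical. The weighted median interpolates linearly in cumulative
weight and clamps to the extreme ratios when 0.5 falls outside the centred
cumulative weights. Wald ratios use the first-order SE se_Y/|b_X|;
second-order (se_X-aware) weights are out of scope.

## Known limitations

Multivariable MR, MR-RAPS, mode-based estimators, Steiger filtering,
proxy-SNP lookup, and multi-allelic variants are not implemented. The
cross-source consistency check compares only effect signs, as the source
design did. FDR family definitions follow the screen structure (one family
per exposure-direction screen); whether the total-effect tests belong to
any family is a design choice left to the caller.
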