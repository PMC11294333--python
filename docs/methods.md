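# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data tests
do and do not demonstrate.

## Data model and harmonization

Summary statistics are per-SNP records (alleles, effect-allele frequency,
beta, SE, p, N) validated on read: SE > 0, p ∈ (0, 1], eaf ∈ (0, 1) when
present, single-nucleotide alleles only. Rows violating an invariant are
rejected with a per-row reason list, never silently dropped. Missing eaf
is allowed; any operation that needs it (R², palindrome frequency
inference) fails loudly per SNP rather than imputing. Positions are
1-based; missing positions disable window clumping. The canonical text
sentinel for missing values is `NA`, and floats are written with 17
significant digits so that a write/read round trip is exact.

Harmonization re-expresses the outcome association on the exposure's
effect allele. A swapped allele pair negates the outcome beta and
reflects its frequency; strand-complement and swapped-complement pairs
are complemented first. Palindromic SNPs (A/T, C/G) are strand-ambiguous:
the default policy drops them, which matches conservative practice for
well-powered exposures; the alternative `infer_by_eaf` aligns by
frequency and drops any SNP whose exposure or outcome frequency lies in
0.5 ± 0.08 (inclusive) or is missing. The 0.08 half-band is the common
convention in summary-data MR software; nothing in the method pins it,
so it is a policy parameter. Indels and multi-allelic sites are out of
scope.

## Instrument selection

Defaults: significance threshold p < 5×10⁻⁸ (strict inequality), greedy
clumping with a 10,000 kb window and r² > 0.001 exclusion, and removal of
instruments whose *outcome* p-value is itself below 5×10⁻⁸ (such SNPs are
genome-wide outcome hits in their own right and violate the exclusion
restriction). Without an LD matrix, clumping is window-only — every SNP
within the window of a better hit is removed, i.e. unknown r² is treated
as 1. This is deliberately conservative: reference-panel LD is
unavailable offline, and keeping a possibly-correlated neighbour would
understate the IVW standard error. A user-supplied symmetric r² matrix
(3-column TSV) switches to true r²-based clumping. p-value ties are
broken by (chrom, pos, snp_id), making selection deterministic without a
seed.

Instrument strength: per-SNP F = β²/σ² (the squared Wald z); aggregate
R² = Σ 2·eaf(1−eaf)β² and F = ((N−K−1)/K)·R²/(1−R²). F > 10 is the
conventional weak-instrument bar.

## Estimators

All estimators consume harmonized pairs (β̂_X, σ_X, β̂_Y, σ_Y) and are
exposed both as scikit-learn-style estimator classes (`fit`,
trailing-underscore attributes) and as plain functions.

* **Wald ratio**: β̂_Y/β̂_X with first-order delta SE σ_Y/|β̂_X|. The
  second-order term is omitted; at F > 10 its contribution is below the
  Monte-Carlo resolution of the tests.
* **IVW**: weights w = β̂_X²/σ_Y² (first-order ratio variances, matching
  the Wald SE above). Fixed SE = (Σw)^(−1/2); the random-effects model is
  multiplicative with the scale floored at 1, SE_random =
  SE_fixed·max(1, √(Q/(k−1))) — the variant used by the dominant
  summary-data MR software lineage; additive DerSimonian–Laird is not
  implemented. The point estimate is identical under both models. `auto`
  applies the Q rule: fixed iff the Q p-value is strictly greater than
  0.05 (p = 0.05 therefore selects random effects). IVW p-values are
  normal; the CI multiplier is 1.959964 everywhere.
* **MR-Egger**: SNPs oriented so β̂_X ≥ 0, then WLS of β̂_Y on β̂_X with
  intercept and weights 1/σ_Y². Coefficient variances are scaled by
  max(1, RSS_w/(k−2)); p-values use t(k−2) because k is typically small.
  A design with no variation in |β̂_X| is singular and rejected.
* **Weighted median**: ratios sorted ascending, standardized cumulative
  weights s_j = (Σ_{i≤j} w_i − w_j/2)/Σw, linear interpolation at
  s = 0.5. Weights are inverse first-order ratio variances (or equal, for
  the simple median). SE = sd of the estimate over n_boot = 1000 seeded
  parametric-bootstrap resamples of (β̂_X, β̂_Y).
* **Modes**: normal-kernel density over the ratios, bandwidth
  h = φ·0.9·min(sd, MAD/0.6745)·k^(−1/5) with φ = 1. When MAD = 0 but the
  sd is positive (a majority of exactly-equal ratios), the sd alone sets
  the bandwidth — the literal min() would degenerate to h = 0 even though
  a mode is well defined. Only fully identical ratios are degenerate: the
  common ratio is returned with SE 0 and a flag. The mode is located by a
  2048-point grid scan refined with bounded scalar minimisation; the
  weighted variant weights kernels by inverse ratio variance. Bootstrap
  SE as for the median.

Equivariance (negating all betas leaves estimates unchanged; negating
only outcome betas negates them) is enforced by property tests.

## Heterogeneity, pleiotropy, leave-one-out

Cochran's Q for IVW is Σ w_j(ratio_j − β_IVW)² on k−1 df; the Egger
version is the weighted residual sum of squares of the intercept
regression on k−2 df (Rücker's Q′). p-values come from the upper chi-square
tail with no small-sample correction. The Egger intercept t-test yields
the pleiotropy verdict (no evidence iff p > 0.05). Leave-one-out refits
IVW k times with the SE model resolved once on the full set — re-choosing
the model per subset would make the k curves incomparable — and flags any
omission that exits the full-set CI or flips the sign.

## MR-PRESSO

Observed statistic: RSS = Σ_j (β̂_Yj − β̂_(−j)·β̂_Xj)²/σ²_Yj where β̂_(−j)
is the IVW slope on the other k−1 SNPs. The null distribution redraws
both β̂*_X ~ N(β̂_X, σ_X) and β̂*_Y ~ N(β̂_(−j)·β̂_X, σ_Y) (the full
parametric scheme — exposure betas are perturbed too) in each of
`nb_distribution` replicates (default 3000, as configured in the
motivating analysis; significance threshold 0.05) and recomputes the RSS
identically, including the within-replicate leave-one-out slopes. All
p-values use the add-one form (1+#exceedances)/(nb+1), so they are never
exactly 0 — this includes the distortion p-value, keeping it in (0, 1].
Outliers are SNPs whose per-residual p falls below threshold/k
(Bonferroni). Note the resolution limit: with nb replicates the smallest
achievable p is 1/(nb+1), so Bonferroni flagging is only possible when
k < threshold·(nb+1); at nb = 500 and threshold 0.05 that means k ≤ 25.
The distortion test compares the percent shift of the IVW estimate after
outlier removal against shifts from excluding random same-size inlier
subsets. With the seed fixed the entire result is bit-reproducible.

## Multivariable MR

Outcome betas are regressed on the k×p exposure-beta matrix with weights
1/σ_Y², without intercept (IVW) or with one (Egger, after orienting each
SNP so the first exposure's beta is non-negative). Q is the weighted RSS
on k−p (or k−p−1) df; SE scaling is multiplicative with floor 1; IVW
p-values are normal, Egger's use t. Rank-deficient designs raise a
collinearity error naming the exposures. Cross-exposure sampling
covariance is taken as zero — the exposures come from separate GWAS
samples and no covariance inputs exist in the data model; requesting the
non-zero-covariance variant raises rather than silently assuming.

Conditional instrument strength residualises each exposure's betas on the
other exposures' (WLS, weights 1/σ_Y², no intercept) and applies the
R²/total-F formula to the residuals with that exposure's eaf and sample
size. With one exposure this reduces exactly to the univariable total F;
an exposure that duplicates another collapses toward 0. Conditional F
below 10 triggers a weak-instrument warning in reports. Exact numerical
agreement with any particular published conditional-F variant is not
claimed; the statistic is validated by its reduction, orthogonality and
collapse properties.

The joint instrument set is the union of each exposure's genome-wide
hits, re-clumped on the smallest per-SNP p-value, restricted to SNPs
present in every dataset, and aligned onto the first exposure's effect
alleles.

## Analytic power

For a binary outcome, power = Φ(z_alt − z_{1−α/2}) with
z_alt = |ln OR|·√(N·R²·K·(1−K)) — N the outcome sample size, R² the
instrument-explained exposure variance, K the case fraction. This is the
non-centrality approximation used by the popular web calculator for this
design; it is validated against its analytic limits (OR = 1 gives
Φ(−z_{1−α/2}) ≈ 0.025 at α = 0.05, symmetry in OR ↔ 1/OR, monotonicity
in every argument). The second tail term Φ(−z_alt − z_{1−α/2}) is
omitted, consistent with that approximation; at any realistic power
level it is negligible.

## Synthetic data

The generator emulates two-sample summary statistics for independent
SNPs: maf ~ Uniform(0.05, 0.5); SEs from the binomial-variance formula
σ = (2·maf(1−maf)·N)^(−1/2), so the instrument-strength formulas are
exactly exercisable; true exposure effects b ~ N(0, 0.05²) truncated by
batched rejection sampling (capped at 500 rounds) so that the *observed*
beta passes genome-wide significance with probability ≈ 1 (threshold
z₅ₑ₋₈ + 4 margin); pleiotropy α_j (zero with probability
1 − pleiotropy_fraction, else N(mean, sd²)) acting on the
exposure-increasing allele, so a non-zero mean is directional in exactly
the sense the Egger intercept measures; optional outliers displaced by a
fixed number of outcome SEs with random sign; palindromic allele pairs at
a configurable fraction; and random swapping/strand-complementing of the
outcome table's alleles so harmonization is genuinely exercised. All
latent labels are returned in a truth frame.

Defaults are the motivating study's conditions: 80 instruments, true
causal log-OR ln(1.41), exposure N = 602,604, outcome N = 97,173,
palindromic fraction 14/80 = 0.175, no pleiotropy and no outliers
(consistent with that study's null Egger intercept and the outliers
being removed by its filters).

What the generator does **not** emulate: LD between SNPs (simulated SNPs
are independent, so clumping is exercised via constructed fixtures
rather than the generator), sample overlap between the two GWAS,
case-control ascertainment effects on SEs, population stratification, and
winner's-curse bias in the exposure betas. Passing simulation tests
therefore demonstrate correctness of the estimators and pipeline under
the stated two-sample model, not robustness to those real-data
complications.

One interaction worth knowing: with a strong simulated causal effect,
many valid instruments are genome-wide significant for the *outcome*
through the causal path, so the outcome-association filter removes the
strongest instruments and biases the pipeline estimate slightly toward
the null. This mirrors what the filter would do to real data under a
strong causal effect; parameter-recovery tests therefore evaluate the
estimators on the harmonized set directly, and the end-to-end report
exposes both numbers.

## Pipeline and reproducibility

Filter order: significance → clumping → harmonization (palindromes) →
outcome-association exclusion → MR-PRESSO outlier removal → estimation.
Every SNP entering the analysis receives exactly one filter-ledger entry
with a machine-readable reason (a partition, enforced by test). All
randomness (PRESSO, bootstraps, simulation) derives from one config seed
via numpy `SeedSequence` splitting, and report bundles are written with
fixed float formatting so a rerun with the same seed is byte-identical.
Problem sizes in the test suite (50-SNP instances, 100–500 replicate
studies, nb_distribution 200–1000) were chosen so the full suite
completes in well under a minute while keeping Monte-Carlo error small
relative to the asserted bands.

## Known limitations

No Steiger directionality filtering, MR-RAPS, or SIMEX-corrected Egger;
no additive random-effects IVW; no proxy-SNP lookup or reference-panel
LD; no genome-build liftover; binary GWAS-VCF is not parsed (a tabular
export dialect is provided). Reverse-direction analyses inherit the
classic caveat that instruments of a strongly affected outcome can be
downstream of the exposure; the bidirectional runner selects instruments
per direction but does not apply directionality tests.
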