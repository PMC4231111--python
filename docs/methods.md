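# Methods

## Problem

A GWAS meta-analysis reports, per SNP, only marginal association statistics:
effect allele, effect-allele frequency, a log odds ratio `b`, its standard
error `se`, a p-value and a sample size `n`. When several variants at one
locus carry independent effects (allelic heterogeneity), single-SNP
statistics misstate each variant's contribution — most strikingly when two
risk alleles are negatively correlated, which attenuates ("masks") both
marginal effects. `cojopred` re-estimates joint and conditional SNP effects
from the marginal statistics plus an LD correlation matrix measured in a
reference panel of the same ancestry, selects SNPs stepwise, and quantifies
how much the resulting multi-SNP risk scores improve case-control
prediction.

## Joint estimation from summary statistics

For SNP `j` let `p_j` be its effect-allele frequency, `v_j = 2 p_j (1 − p_j)`
the Hardy–Weinberg dosage variance, and `D_jj = n_j v_j`. The cross-products
of the (unavailable) individual-level regression are approximated by

    (X'X)_jj = D_jj
    (X'X)_jk = r_jk · sqrt(v_j v_k) · min(n_j, n_k)      (j ≠ k)
    (X'y)_j  = D_jj · b_j
    (y'y)_j  = D_jj b_j² + D_jj se_j² (n_j − 1)

where `r_jk` is the effect-allele-oriented LD correlation. Joint estimates
solve `X'X β = X'y`; standard errors use
`σ² = (y'y − β'X'y) / (df − |S|)` with `y'y` the median of the per-SNP
reconstructions (robust to SNPs with mis-specified `n`) and `df` the median
`n` over the selected set. P-values are two-sided normal Wald tests.
Conditional statistics for a candidate SNP are its coefficient in the joint
fit over {current model ∪ candidate}.

Design choices in this block, made where the construction is genuinely
open:

- **Off-diagonal sample size** `min(n_j, n_k)`: the overlap of two
  meta-analysis subsamples is at most the smaller of the two; conservative.
- **`y'y` aggregation by median** over the region's SNPs.
- **Degrees of freedom**: per-SNP `n` varies widely in meta-analyses
  (roughly 54,000–132,000 in the motivating application), and a single
  scalar is needed; the median over selected SNPs is used.
- **σ² floor**: with approximated inputs the residual variance can come out
  non-positive; it then falls back to `y'y / df` with a warning flag on the
  results object.
- **Exactness option**: `v_j = 2p(1−p)` assumes HWE. When the per-SNP
  dosage variance measured on the *same* sample as the marginal statistics
  is supplied (`JointGwas(..., var=...)`), the reconstruction is
  algebraically identical to individual-level least squares for a
  quantitative trait; the test suite asserts equality to 1e-6 relative.
  With the HWE default the difference is O(n^−1/2).
- **Collinearity**: `X'X` is Cholesky-factorized and additionally guarded
  against numerically-singular success (smallest pivot² ≤ 1e-8 × largest
  diagonal); failures raise an error naming the most collinear SNP pair.

## Stepwise selection

Selection seeds with the region's minimum-marginal-p SNP if it passes the
threshold; then, repeatedly: (1) every non-model SNP whose maximum r² with
the model is ≤ 0.9 (collinearity guard) is scored by its conditional
p-value, and the best one enters if below threshold; (2) the model is
refitted jointly and SNPs whose joint p exceeds the threshold are removed
one at a time, worst first, refitting after each removal. Iteration stops
when no change occurs (or at `max_iter=100`, flagged as non-converged). All
ties break deterministically by (p, position, SNP id). Regions are analyzed
independently (cross-region LD treated as zero); the default threshold
sweep is 5e-8, 5e-7, 5e-6, 5e-5, 5e-4. Models at stricter thresholds need
not nest in looser ones.

## Reference panel QC

Imputed dosages are hard-called for LD estimation: dosages strictly inside
(0.33, 0.66) or (1.33, 1.66) are set missing, all others rounded (band
endpoints are kept — "between" is read strictly; the alternative SNP-level
exclusion is available as an option). Variant QC applies, in order:
imputation info < 0.6 (when an info column is supplied), missingness > 10%,
MAF < 0.5%, and Hardy–Weinberg 1-df chi-square p < 0.005 (the chi-square
test, not the exact test, is the historical default at this cutoff).
Relatedness pruning computes the standard genomic relationship matrix and
greedily removes, from each pair at A ≥ 0.025, the member with more
over-threshold partners. LD is computed pairwise-complete on hard calls,
oriented to each SNP's effect allele; validation scoring, by contrast, uses
raw dosages (matching how validation cohorts are conventionally handled).

## Harmonization

Summary SNPs are matched to panel variants by id; allele pairs are resolved
directly, swapped, or strand-complemented, yielding an orientation flag of
±1 that reflects whether the effect allele is the panel's counted allele.
`b`, `se`, `p`, `n` are never altered. Strand-ambiguous SNPs (A/T, C/G)
with effect-allele frequency in [0.35, 0.65] are excluded by default; outside
that band they are resolved by frequency matching. Both behaviors are
switchable.

## Risk scores and evaluation

A weighted GRS is `score_i = Σ_j w_j d_ij` over effect-allele dosages, with
weights either marginal lead-SNP log-ORs or C/J joint coefficients; in
combined ("lead + C/J") sets a SNP present in both keeps its joint weight.
Missing dosages are mean-imputed as 2 × panel frequency.

Prediction models are logistic regressions (hand-rolled IRLS; convergence
when the maximum coefficient step < 1e-8; a coefficient exceeding 15 on the
standardized scale raises a perfect-separation error advising
penalization): a baseline with age and sex, then baseline + each GRS.
Reported per model: Mann–Whitney AUC (ties ½), Nagelkerke R² against the
intercept-only null, and AIC with the intercept counted. Model pairs are
compared by the paired DeLong test via placement values (two-sided normal
reference; identical rankings give p = 1 with a logged flag).

Liability-scale variance explained per SNP assumes HWE genotype
frequencies and multiplicative genotype odds (1, OR, OR²): the baseline
odds solve a bracketed root-find (10^−12, 10^12) so the population
prevalence equals K (default 0.10); penetrances map to liability means
μ_g = T − Φ⁻¹(1 − π_g) with threshold T = Φ⁻¹(1−K), and the reported
fraction is Var(μ)/(1 + Var(μ)). Odds (not risk) scaling is used. A SNP
collection reports the sum of per-SNP fractions (independence assumption),
capped at 1 with a warning. This construction is validated against a
10⁶-sample liability Monte Carlo in the test suite, not against any
published table.

## Synthetic data

The generator emulates the statistical structure the pipeline consumes,
with direct control of the quantity the method actually uses (LD):

- **Genotypes** via a Gaussian copula: each haplotype is a latent MVN draw
  thresholded at Φ⁻¹(1−p_j); a genotype sums two independent haplotypes.
  Dichotomization attenuates correlation, so pair targets are specified on
  the genotype scale and converted with a numeric bivariate-normal solver
  (`latent_from_genotype_corr`); tests compare realized LD against the
  analytic genotype-scale value.
- **Phenotypes** by liability threshold: standardized causal genotypes plus
  age (uniform 45–84, standardized, coefficient 0.15) and sex
  (Bernoulli(½), coefficient 0.10) plus Gaussian noise scaled to total
  variance 1; cases exceed Φ⁻¹(1−K), K = 0.10. The demographic coefficients
  are modest values typical of adult cardiometabolic cohorts and are
  configurable.
- **Summary statistics** from per-SNP logistic regressions (vectorized
  two-parameter Newton fits) on a GWAS cohort of 50,000 by default;
  reference (6,000 — the scale shown adequate for LD estimation) and
  validation (2,000) cohorts are independent draws.

The masked-pair preset places two causal SNPs (standardized liability
effects 0.15 each) at risk-allele genotype correlation −0.54 among 50 null
SNPs in mild block LD, so each expected standardized marginal effect is
β(1 + r) ≈ 0.069. Frequencies are 0.43 and 0.75: with 0.43 and ~0.8 (the
frequencies at the motivating locus) a correlation of −0.54 violates the
Fréchet bound for Bernoulli margins (≈ −0.53) and is unattainable under any
bivariate allele distribution, so the second frequency is set to the
nearest value that admits the target. The chain preset places three causal
SNPs with consecutive genotype correlations (0.344, −0.126) closed into a
positive-definite Markov-chain structure.

What the generator does *not* emulate: recombination-map realism,
population structure and cryptic relatedness, imputation error, genotyping
batch effects, and case-control ascertainment beyond the liability
threshold. Tests passing on these simulations therefore demonstrate the
estimator's algebra and calibration under its own assumptions, not
robustness to those real-data complications.

## Truth definitions used in the coverage tests

On the quantitative (liability) scale the true per-dosage effect of a
causal SNP is known exactly (0.15/sd_j), so estimator coverage is asserted
there, with LD and dosage variance measured on the same cohort: each SNP's
joint estimate covers its truth within 2 SE in ≥90% of replicates. For the
binary pipeline the method combines marginal log odds ratios linearly;
because the odds ratio is non-collapsible, its large-sample target differs
from the individual-level joint logistic coefficient by a small systematic
amount (~3% here), and reference-panel LD error adds variance the reported
SEs do not track. The selection-power and prediction acceptance checks
therefore run on the binary pipeline, while 2-SE coverage is asserted on
the quantitative scale where the estimand is exact. Both effects are real
properties of this method class and are documented rather than corrected.

## Problem sizes

The acceptance-level simulations use the scenario defaults: 200 replicates
at n = 50,000 for masked-pair recovery and coverage, 500 null regions at
n = 20,000 for discovery calibration, 2,000 replicates (200 cases / 1,800
controls) for DeLong calibration, and 100 replicates with validation
cohorts of 2,000 for the directional prediction property. The worked-example
joint fits are deterministic and run in milliseconds.

## Known limitations

- Reported joint SEs ignore LD-estimation error in the reference panel;
  with a 6,000-sample reference and |r| ≈ 0.5 the empirical spread of joint
  estimates is ~20% wider than the nominal SE.
- Joint log-OR estimates inherit the non-collapsibility bias described
  above; effects here are small (|b| ≤ 0.5) where the approximation is good.
- Per-SNP effective sample size is taken from the reported `n` column, not
  re-estimated from `se` and frequency.
- Cross-region LD is assumed zero; overlapping regions must be merged by
  the caller (duplicate SNPs across region weight sets raise an error).
- The liability-variance formula treats SNPs as independent; summing over
  SNPs in LD double-counts shared variance.
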