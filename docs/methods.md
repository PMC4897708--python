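# Methods

## Model and estimator

We assume a quantitative trait standardized to unit variance and genotypes
standardized per SNP to mean 0, SD 1 (population SD, denominator *n*, so the
correlation of two SNP columns is exactly `x_k'x_l / n`). Under a strictly
additive random-effects model — `y = Xβ + ε` with independent mean-zero
effects of variance σ² on the order of 1/M and Gaussian noise, no
interaction or haplotype effects — the expected univariate squared effect of
SNP *d* picks up the signal of every SNP in LD with it:
`E[b_d²] ≈ Σ_l r²_{d,l} β_l² + Var(y)/N`. Summing `b_d²` over a region
therefore counts each causal signal once per correlated SNP, which is the
reason raw sums of squared GWAS effects overestimate regional variance under
LD.

The LD adjustment divides each squared effect by

    η_d = Σ_{k: |k−d| ≤ w, same arm}  r²_{d,k}   (self term r²=1 included),

the windowed LD score of SNP *d*. Since each causal signal appears in the
numerator of roughly η neighbours and is divided by η in each, the adjusted
sum counts it once. The regional estimate is

    ρ̂²(S) = Σ_{d∈S} b_d²/η_d − m_eff(S)/N,     m_eff(S) = Σ_{d∈S} 1/η_d.

The correction term `m_eff/N` is the expectation of the adjusted sum under
the null (each `b_d²` contributes ≈ 1/N of noise, shrunk by 1/η_d), so the
estimator is null-centred — the summary-statistic analogue of the fact that
the expected adjusted R² of a multiple regression is zero under no
association. Under the additive model the expectations of `ρ̂²(S)` and of the
per-block multiple-regression R² agree as N grows, with the number of
regressors *m* replaced by `m_eff`; the estimator's variance is bounded by

    Var(ρ̂²) ≤ 2·m_eff/N² + 4·max(ρ̂², 0)/N,

whose first term is exact for Gaussian effect estimates under the null and
whose second term covers the signal contribution. Analytic 95% CIs use
`±1.96·sqrt(bound)` (conservative); genome-wide sums can instead use a
delete-one-block jackknife over the partition (≥ 30 blocks required).

With per-SNP sample sizes (meta-analysis input) the noise term is summed
SNP-wise as `Σ 1/(η_d n_d)`. Effects supplied on the per-allele scale are
converted with `b·sqrt(2·maf·(1−maf))/sd_Y`; alternatively `b` is rebuilt
from the z-score as `z/sqrt(n)`, the recommended mode when trait units are
unknown.

## Sampling correction of η

η must estimate the *population* LD sum, but each sample r² is inflated:
`E[r̂²] = r² + (1−r²)/(n−2)` per pair, i.e. ≈ 2w/n per SNP over the window.
Uncorrected, this deflates the variance estimate by a relative ≈ 2w/n_panel
(noticeable when the LD panel is modest and η is near 1). `eta_adjustments`
therefore enters each stored pair as the approximately unbiased
`r̂² − (1−r̂²)/(n−2)` — the same correction LD-score estimators apply — and
floors η at its mathematical minimum of 1. The raw convention remains
available (`sampling_correction=False`). Pairs beyond the window or across
chromosome arms are treated as exact zeros (linkage equilibrium assumed);
without a centromere annotation each chromosome is one arm.

## Block partition

Blocks are contiguous runs of SNPs, bounded between a minimum and maximum
count, chosen greedily from the low-coordinate end of each arm: every
admissible cut for the current block is scored by the maximal r² over stored
SNP pairs spanning it, and the cut with the smallest score wins, ties going
to the smallest index (deterministic, order-stable). A terminal residue
shorter than the minimum merges into the last block, which may thus exceed
the maximum by less than the minimum; every SNP belongs to exactly one
block. The algorithm is greedy by design; it makes no global-optimality
claim. Typical operating points are 85–95 or 195–205 SNPs per block.

## Individual-level comparator

With genotypes available, the variance explained by a block is the adjusted
R² (Wherry/Ezekiel: `1 − (1−R²)(n−1)/(n−m−1)`) of OLS of the trait on all
block SNPs, and regional contributions sum over blocks. Perfectly collinear
duplicate columns are dropped, with *m* counting retained regressors so the
adjustment stays null-centred; blocks need `n > m+1`. The trait is
preprocessed once — percentile trimming (default 1st–99th), residualization
on covariates and optionally on genotype principal components (eigenvectors
of XX'/m with a deterministic sign convention), then z-scoring — rather than
including covariates in every block model; this is an approximation that
keeps per-block fits cheap. `BlockRegressor` factorizes each block's Gram
matrix once (with a 1e-10·n ridge against numerically singular high-LD
blocks) so that many phenotypes can be scored cheaply; it matches the direct
fits to numerical precision.

## Enrichment test

The estimate for SNPs within ± half-width of a center is compared against
`n_resample` contiguous windows with the **same SNP count** placed uniformly
at random along the genome (never spanning a chromosome break). Matching on
SNP count rather than bp equalizes the null variance, which scales with
m_eff. The two-sided p-value is `(r+1)/(n_resample+1)` with `r` the number
of reference windows whose centred estimate is at least as extreme as the
observed excess; the CI shifts the reference quantiles to the excess scale
(basic/reflected construction). Reference windows are drawn from the whole
genome including the target, matching a comparison against the genome-wide
average; a target that dominates the genome therefore slightly inflates its
own null. The resampling seed is a parameter and is logged.

Both CI constructions (analytic bound, jackknife) and both enrichment
conventions are packaged choices: the published analyses they echo do not
state their interval or p-value constructions, and no claim is made that
these reproduce them exactly.

## Simulator

Haplotypes are latent Gaussian vectors with one of three SNP-SNP correlation
structures — independent; AR(1) with parameter ρ (geometric LD decay);
blockwise equicorrelation ρ within consecutive blocks of `block_len` SNPs —
dichotomized at per-SNP allele-frequency quantiles (frequencies uniform on
the configured MAF range, default 0.05–0.5); a genotype is the sum of two
independent haplotypes. This gives exact control of LD and allele
frequencies at O(nm) cost; it is not a coalescent model and makes no claim
of realistic recombination maps, allele-frequency spectra, or population
structure (a two-population binomial construction is used only for the PC
test). Thresholding attenuates latent correlations, so configured ρ is an
upper bound on realized genotype LD.

Traits are `y = Xβ + ε` with Gaussian effects on a uniformly drawn causal
set, rescaled so the *realized* `Var(Xβ)` equals the configured h² exactly
(removing effect-sampling noise from recovery comparisons); the reported
ground truth for a region is the realized `Var(X_S β_S)/Var(y)`. GWAS
summary statistics are per-SNP OLS with intercept (b, SE, two-sided t-test
p, N).

What passing simulation tests shows: calibration, recovery, equivalence and
power of the estimators under controlled LD of the configured forms and
strictly additive architecture. What they do not show: behaviour under
haplotype/interaction effects, LD-panel/GWAS-population mismatch, MAF-
dependent architectures, or uncorrected stratification.

## Study conditions used in the validation suite

Problem sizes were chosen once as desk-scale study conditions and are fixed
in the tests and acceptance script:

* Null calibration: n = 2000, m = 300, AR(1) ρ = 0.8, 500 phenotype
  replicates on a fixed panel (the model treats X as fixed).
* Recovery: n = 5000, m = 500, h² ∈ {0.05, 0.2}, 200 replicates, all three
  LD models (blockwise ρ = 0.7, block 20).
* Asymptotic equivalence: m = 500, h² = 0.2, AR(1) ρ = 0.5, 100 replicates
  at N ∈ {2000, 5000, 10000, 20000}, blocks of 40–60 SNPs. AR(1) is used
  here because under long-range equicorrelated LD the per-replicate
  difference between the summary and individual-level estimators contains an
  N-independent effect-realization term (both are unbiased, but they weight
  the β cross-terms differently), so per-replicate convergence is a property
  of decaying LD — a known limitation of the equivalence, documented rather
  than hidden.
* Variance-bound dominance: independent SNPs, n = 2000, m = 100, 1000
  replicates. The bound's leading term is a null-variance statement; under
  strong positive LD the between-SNP covariance of squared effects can
  exhaust it, so dominance is claimed and tested in the regime the bound
  targets.
* Enrichment: calibration on a 1000-SNP null genome (500 draws, 400
  resamples); power with a 51-SNP window carrying 0.05 variance planted in a
  3000-SNP otherwise-null genome at N = 5000. The genome size was set so
  that a random reference window almost never nearly-coincides with the
  planted window (overlap probability ≈ 0.2%), since reference windows are
  drawn genome-wide including the target.

## Numerical choices and degenerate inputs

* Missing dosages are mean-imputed before standardization (they become
  exact zeros); monomorphic SNPs are rejected by name. QC order is fixed:
  individual missingness → SNP missingness → MAF → Hardy-Weinberg exact test
  (Wigginton recurrence, no mid-p).
* r² values are clipped to [0, 1] against floating-point overshoot; the
  banded store is filled in 512-column BLAS chunks.
* Cut-point ties break to the smallest index with a 1e-15 guard; partitions
  are byte-identical across runs.
* η < 1 anywhere downstream is an error (violated self-term convention).
* Harmonization drops allele-mismatched records, optionally drops
  strand-ambiguous (A/T, C/G) SNPs, and logs flip/drop counts; under 50%
  overlap triggers a warning.
* An enrichment window equal to the whole (single-chromosome) genome yields
  excess 0 and p = 1 by construction.
* All simulations are `numpy.random.Generator`-seeded; identical seeds give
  identical panels, traits and resamples.

## Known limitations

* The estimator assumes the LD panel represents the GWAS population; the
  window treats LD beyond w SNPs as zero, so very long-range LD leaks into
  neither η nor the correction and can bias regional estimates.
* Binary traits (liability scale) and haplotype/interaction effects are out
  of scope; covariate adjustment inside per-block models is approximated by
  one-shot phenotype residualization.
* The analytic CI uses a variance *bound* and is conservative; the jackknife
  requires many blocks.
* Per-replicate summary-vs-individual agreement degrades under long-range
  equicorrelated LD (see above), although both estimators remain unbiased
  for the realized regional variance.
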