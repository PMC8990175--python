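# Methods

This note documents the models, estimators, defaults and numerical choices
behind `transgwas`, and what the synthetic-data experiments do and do not
establish.

## Synthetic multi-ancestry data

Genotypes follow a Balding-Nichols divergence model: each variant has an
ancestral allele frequency p (default Uniform(0.05, 0.95)), and every
ancestry group with divergence parameter F draws its population frequency
from Beta(p(1−F)/F, (1−p)(1−F)/F); F = 0 degenerates to p itself.  Within
an LD block, each haplotype's alleles come from thresholding equicorrelated
Gaussian latents (a shared factor with weight √r), so the latent
correlation r is a monotone dial on genotype LD; the realized genotype
correlation is attenuated relative to r (tetrachoric-style), which is
acceptable because everything downstream consumes *empirical* LD from the
panel.  Dosages are hard {0, 1, 2} genotypes by default (stored as float32
— integers are exact in float32); a `fractional` option perturbs them into
[0, 2] at 6-decimal precision to exercise dosage-handling code, and
per-variant imputation info is a stated attribute rather than an estimate.
Positions are 1-based at fixed spacing on one chromosome (VCF convention).

Phenotypes are additive: a genetic value over `n_causal` variants scaled to
variance h², plus Gaussian noise scaled so genetic + noise variance is 1,
plus an *environmental* shift `strat_delta` per unit of a latent
geographic/ancestry axis.  The axis term deliberately sits outside the
unit-variance budget: it is the confounder, not part of the trait model.
Age and sex are drawn independently of genotype so stratification is the
only confounder in play.  Expression matrices are slope × dosage + noise.

Study fixtures round-trip through VCF 4.2 (GT + DS) via cyvcf2; fractional
dosages are recovered exactly by rounding the float32 DS value back to its
stored 6 decimals.

What the generator does *not* emulate: realistic human LD maps, admixture
tracts, relatedness, case-control ascertainment.  Passing tests therefore
demonstrate the estimators' correctness and calibration under clean
structured-population conditions, not robustness to every feature of real
cohort data.

## Trait preparation and association

Raw traits are residualized by OLS on [1, age, age², covariates (, BMI for
WHR)] within sex strata, then rank-inverse-normal transformed
(Φ⁻¹((rank−0.5)/n), average ranks on ties — making the transform symmetric
under negation) or standardized to Z scores (residual / SD of all
residuals).  Association is OLS of the prepared trait on dosage +
covariates + leading genotype PCs, computed by projecting trait and
dosages onto the covariate complement; this is algebraically identical to
the full-design solve (verified against statsmodels at 1e-10) and runs one
matrix product per panel.  p-values are two-sided normal everywhere — the
convention the summary-statistic machinery downstream assumes — rather
than t; at GWAS sample sizes the difference is negligible.  Relatedness
corrections (GEE/mixed models) are out of scope: synthetic samples are
unrelated.  The PC count per study defaults to 5 and is configurable.

QC removes records by strict inequality: info < 0.4, MAC < 5, or N < 100;
records exactly at a threshold are retained.

## Meta-analysis

Fixed-effect inverse-variance pooling with Cochran's Q and
I² = max(0, 100(Q−(k−1))/Q); EAF pooled as the N-weighted mean; direction
strings use +/−/? in study input order.  Genomic control uses
λ = median(z²)/median(χ²₁) with the exact 1-df chi-square median
(0.4549364…) and inflates SEs by √λ only when λ > 1, leaving betas
untouched; it is applied per input study before pooling, with an optional
(default off) second pass on the pooled result.  Harmonization matches
(EA, OA) directly or swapped (flipping beta and EAF); strand-ambiguous
A/T / C/G variants are resolved by allele frequency only when both sources
have |EAF − 0.5| > 0.1, otherwise dropped with a log entry.  Two-stage
combination pools the replication studies first and then combines two
rows; genome-wide runs can instead enter every study individually — the
bundled published combined rows were produced the latter way, which is why
the decision-rule checks treat them as inputs while the worked-example
arithmetic uses the two-row mode.

## Locus decision rules

Lead selection is greedy smallest-p among genome-wide-significant records,
removing candidates within ±500 kb or with reference r² ≥ 0.2 (the
independence cutoff is the package's own default — the criterion is
usually stated without a number — and configurable).  The ±500 kb
established-locus window is read inclusively.  Proxies are the top-k
(default 2) variants with r² ≥ 0.9.  Replication/novelty and
transferability verdicts implement the stated thresholds exactly
(consistency of direction only, no stage-2 significance requirement).  The
directional-consistency test is the exact two-sided binomial at p₀ = 0.5,
summing outcome probabilities no larger than the observed one.

## Conditional/joint analysis from summary statistics

The normal equations are reconstructed as X'X[j,k] = r_jk √(D_j D_k) and
X'y[j] = D_j b_j with D_j = n_j var(x_j); var(x_j) is 2p(1−p) under HWE
unless the LD matrix carries observed reference genotype variances (the
`ld_from_panel` path), in which case in-sample reconstructions reproduce
full-data regression point estimates exactly.  Phenotypic variance is the
median of se²·n·var(x) across region variants; the joint residual variance
is (var_y·n − b'X'y)/(n − k), floored at a small positive value.  Forward
selection admits the candidate with the smallest joint p below 5e-8 whose
r² with every selected variant is below 0.9 (the conventional collinearity
default; reference-vs-GWAS frequency checks are not implemented), with a
backward pass dropping variants whose joint p deteriorates.  Variants
absent from the LD reference are excluded and logged.

## Fine-mapping

For configuration S the Bayes factor is
N(z_S; 0, R_SS + n·w·R_SS²)/N(z_S; 0, R_SS), evaluated by Cholesky on the
|S|-dimensional system (eigenvalue-clipped repair plus a small ridge on
failure).  The prior effect-size variance w defaults to 0.05² per
standardized effect, and the prior on the causal count is a truncated
Binomial(p, 1/p) — one causal variant expected per region — uniform over
subsets of a given size; regions allow up to 10 causal variants.
Exhaustive enumeration handles regions up to 20 variants; beyond that the
shotgun stochastic search proposes add/delete/swap neighbors, samples the
next configuration proportionally to posterior mass, and retains every
evaluated configuration's score; the posterior is renormalized over the
evaluated set (an approximation, standard for this search).  Convergence
is declared when the best configuration stops changing in the final
quarter of the iterations.  The conditional fallback counts causal
variants by stepwise conditional z-scores at 5e-8 and can pin the search
to that size.  Credible sets are per-signal: for each slot of the top
configuration, the posterior over which variant fills it (conditional on
the other top-configuration members) is sorted and cut at 0.95; totals
short of 0.95 return the whole support, flagged.

## Stratification diagnostic

Pruning: MAF strictly > 0.05, then greedy 2 kb distance thinning, then
windowed LD pruning (50-SNP windows stepping by 5; iteratively remove the
larger-index member of the worst pair until all pairwise r² ≤ 0.2), then
exclusion regions (half-open; empty by default — long-range-LD lists are a
caller input).  PCA standardizes genotypes by √(2p(1−p)) and uses the
sample-space Gram decomposition; each PC is oriented so its
largest-magnitude sample score is positive.  Loadings are intercept-only
OLS slopes of PC score on allelic count, with the counted allele recorded;
GWAS betas are sign-harmonized to the counted allele before the Pearson
correlation over shared variants with MAF > 1% (harmonized signed betas —
the only choice under which the sign of rho is meaningful).  Jackknife
blocks are consecutive runs of equal variant count in genome order
(remainder on the leading blocks, blocks may span chromosomes);
SE² = ((g−1)/g)·Σ(ρ₍ⱼ₎ − ρ̄)²; p = 2Φ(−|ρ/SE|), floored at the smallest
positive double when the leave-one-out values are identical.  With fewer
than 10,000 variants the block count scales down to max(20, m/100) so
leave-one-out sets stay meaningful.  Cross-dataset comparison restricts
both datasets to the shared harmonized variants and jackknifes the
*difference* over identical blocks, so the SE respects the dependence
between the two correlations.

## Experiment scales

The bundled experiments run at: stratification recovery — 20 replicates of
20,000 independent variants, three cohorts of 2,000 (two populations at
F = 0.1 on a 0/1 axis, delta = 0.5, 500-sample reference panel, 1,000
jackknife blocks); fine-mapping equivalence — 20 regions of 12 variants,
50,000 search iterations against exhaustive enumeration; credible-set
calibration — 200 single-causal regions of 15 variants at n = 5,000 with
causal z ≈ 6, enumerated to two causal variants; joint-model agreement —
100 replicates of 50-variant regions (blocky LD, two causals, n = 5,000)
against full-data multiple regression at 3 SE; type-I error — 2,000 null
variants at n = 1,000 for the scan and 100 null replicates of 20,000
variants for the jackknife test.  These sizes keep the full run around ten
minutes on one CPU while leaving each check's binomial/Monte-Carlo error
well inside its acceptance margin.

## Known limitations

The copula LD scheme produces only non-negative within-block LD; the
stochastic search's posterior is conditional on the explored space; the
COJO-style reconstruction omits GCTA's reference-vs-GWAS allele-frequency
consistency checks; random-effects meta-analysis is not provided; and the
published rho values for real consortium data are not reproducible here —
they require the original reference panels and summary statistics — so the
stratification experiment checks the directional mechanism (bias detected
where injected; attenuated by pooling), not the published magnitudes.
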