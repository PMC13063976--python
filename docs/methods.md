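# Methods

This note documents the models implemented in `stratiqtl`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions a
maintainer would want recorded.

## Statistical model

Gene expression of one gene in one breed × tissue is modeled as

    y = X a + s b + g + e,    g ~ N(0, G s2g),    e ~ N(0, I s2e)

with `y` the inverse-normal-transformed expression across n samples,
`X` an intercept plus expression-PC covariates, `s` the mean-centered
dosage (0/1/2 alternate-allele count) of one candidate variant, and `G`
the genomic relationship matrix

    G = M M' / (2 * sum_i p_i (1 - p_i))

built from mean-centered dosages `M` of all QC-passing genome-wide
variants (the cis region is not excluded). Breeds are analyzed
separately throughout; no genotype × breed interaction terms are
fitted.

### REML fitting

The null model (no variant term) is fitted by restricted maximum
likelihood. After an eigendecomposition `G = U D U'`, rotating by `U'`
diagonalizes the covariance, and both variance components profile out
of the likelihood except for the ratio γ = s2g/s2e. The search runs on
a 41-point grid over log γ ∈ [−10, 10], refined by a bounded
golden-section/Brent step around the best grid point (`xatol` 1e-8).
Eigenvalues are floored at 1e-8 (with a warning when the matrix was
numerically non-PSD). A fit at the lower search edge reports s2g = 0.
When `G = I` the model is over-parametrized (only s2g + s2e is
identified); the covariate estimates then equal OLS exactly, which the
test suite uses as an oracle.

### Cis scan and permutation calibration

The cis window is `TSS ± 1,000,000 bp`, both boundaries inclusive,
anchored at the TSS regardless of strand. Each cis variant is tested
by GLS in the rotated space with the variance *ratio* held at the null
fit while the residual scale is re-estimated per variant; the statistic
is Student-t with n − c − 1 degrees of freedom (c = covariates incl.
intercept). This makes the scan reduce *exactly* to an OLS regression
scan when `G = I`, and is the standard score/Wald approximation of
mixed-model eQTL mappers (refitting variance components per variant
changes nothing appreciably at cis sample sizes but costs an
optimization per variant).

Gene-level p-values come from permuting the raw expression vector
(k_perm default 1,000; tests and the acceptance script use 200 to keep
runtimes in minutes), re-rotating, and re-running the fixed-ratio scan;
the minimum nominal p is recorded per permutation and

    p_gene = (1 + #{perm min-p <= observed min-p}) / (k_perm + 1).

Optionally a Beta(a, b) distribution is fitted to the permutation
minima by maximum likelihood and `p_gene = BetaCDF(observed min-p)`;
this extrapolates below the 1/(k_perm+1) floor. The empirical estimator
is the default because it is assumption-free; the Beta option matches
the common practice of large eQTL consortia.

Permuting the phenotype ignores the polygenic covariance of `y` under
the null; with the moderate relatedness of the simulated design (and of
outbred commercial populations) the resulting calibration error is
negligible, which the null-calibration tests verify directly.

### eGene calling and the variant-level threshold

`p_gene` values are Benjamini–Hochberg corrected across genes within a
breed × tissue; eGenes have q < 0.05. For each eGene the variant-level
nominal-p cutoff is the empirical quantile of that gene's permutation
minima at p*, where p* is the largest gene-level p among significant
genes (the q = 0.05 boundary); cis variants with nominal p below the
cutoff are that gene's significant cis-eQTLs.

## Preprocessing

* **Genotype QC** — pooled stage: MAF ≥ 0.05 and MAC ≥ 6 (inclusive);
  per-breed stage: MAF > 0.01, MAC > 6 (strict) and heterozygote
  fraction < 0.99 within every breed, intersected across the three
  breeds. The inclusive/strict boundary difference between the two
  stages is intentional and preserved exactly; the test suite pins it.
* **TPM** — counts / (length in kb), scaled per sample to sum to 1e6.
* **Low-expression filter** — drop genes with TPM ≤ 0.1 in strictly
  more than 80% of samples, per breed × tissue.
* **TMM** — trimmed mean of M-values against a reference sample (the
  one whose upper-quartile expression of depth-scaled counts is closest
  to the mean upper quartile): gene-wise log2 ratios M and average
  abundances A over genes positive in both samples, double trimming
  (30% of M, 5% of A, rank-based with the `floor(n·f)+1` convention),
  precision weights from the delta-method variance of M, factors
  rescaled to unit geometric mean. Normalized values are
  counts-per-million divided by the factor. The implementation
  reproduces the reference R implementation to 6+ decimals and an
  independent Python re-implementation to 1e-10 (tested).
* **Inverse normal transform** — per gene, `Phi^-1((r - 3/8)/(n + 1/4))`
  with average ranks for ties (Blom offsets; no convention was imposed
  by the upstream description, Blom is the common default).
* **Expression-PC covariates** — sample-space PCs of the
  gene-standardized TMM matrix. The elbow rule selects the smallest n
  such that the variance-share increments of PCs n+1 *and* n+2 are each
  below 0.1% of the cumulative share of the first n PCs (a "combined"
  single-increment reading is available as a switch). PCs are
  recomputed after gene filtering. Two artifact decisions: when the
  rule never fires, min(10, n−2) PCs are used with a warning; and the
  selection is capped at the same value even when the rule fires,
  because on spectra without factor structure the rule first fires only
  at the rank cliff of the sample spectrum (around n−9 of n
  components), which would consume nearly all residual degrees of
  freedom and zero out mapping power. The cap (`max_pcs`) is
  overridable.

## Differential expression

One breed vs the other two, per tissue, on `log2(TPM + 1)`: difference
of group means as log2 fold change, pooled-variance two-sided t-test,
BH correction across genes, significance at |log2FC| > 1 and
FDR < 0.05. This is a plain-linear-model stand-in for moderated
statistics: the downstream use is purely threshold-based, and at 100
samples per breed variance moderation changes little. The +1
pseudo-count is an artifact decision.

## Effect sharing

Per breed, lead-variant effects of shared eGenes are shrunken with an
empirical-Bayes normal-means model: prior `pi_0 δ0 + Σ_k pi_k N(0,
tau_k²)` with tau on a geometric grid from min(se)/10 to 2·max|beta|
(about one point per octave), weights by EM on the marginal likelihood
(tolerance 1e-8 on the relative log-likelihood increase, max 1,000
iterations; non-convergence returns the last iterate with a warning).
The local false sign rate of an effect is
`min(P(b >= 0 | data), P(b <= 0 | data))`, both sides including the
point mass. This condition-by-condition scheme replaces full
multivariate adaptive shrinkage: the reported quantities (sign and
factor-K magnitude sharing with LFSR gating) only need per-condition
posteriors, and cross-condition covariance learning is out of
proportion to that purpose.

Pairwise sharing between breeds is computed on posterior means (raw
estimates by flag), restricted to effects with LFSR < 0.05 in at least
one breed of the pair ("both" by flag): `prop_sign` is the fraction
with concordant direction, `prop_magK` additionally requires
max/min ≤ K for K = 2, 4. The invariant
`prop_mag2 ≤ prop_mag4 ≤ prop_sign` is asserted on construction.

## Breed-specific characterization

* **LD score** of a variant: sum over region variants of squared
  Pearson dosage correlation, self term included (score ≥ 1);
  zero-variance variants are excluded from both sides.
* **MAF by breed**: folded allele frequency per breed.
* **Conservation**: mean per-base score over the gene body (TSS to
  TSS + length − 1, strand ignored) from a 0-based half-open score
  track; reported only when ≥ 50% of the gene's bases are covered.

## GWAS integration

Traits are retained when their minimum p ≤ 5×10⁻⁸. eGene regions are
`TSS ± 1 Mb` clamped at position 1 and merged when overlapping, so a
SNP between two nearby eGenes counts once. Enrichment: significant
SNPs (p ≤ 5×10⁻⁸) vs 1,000 equal-size control sets drawn *without
replacement* from the non-significant SNPs (the source procedure does
not state the sampling scheme; without replacement and without MAF/LD
matching is the literal reading; matched sampling is a documented
extension point); fold = observed in-region proportion / mean control
proportion; empirical p uses the +1-smoothed tail count.

Colocalization follows the single-causal-variant ABF framework: per
SNP, `log ABF = 0.5 log(1−r) + 0.5 r z²` with `r = W/(V+W)`,
`V = se²`, prior effect variance `W = 0.15²` for quantitative traits
(overridable per dataset); hypothesis sums are accumulated by
log-sum-exp over SNP configurations with priors p1 = p2 = 1e-4,
p12 = 1e-5; a pair colocalizes when PP.H4 > 0.8. Regions with a single
shared SNP get PP.H3 = 0 by construction.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with defaults matching the three-breed design: 100 individuals per
breed, Fst 0.1 between breeds (Balding–Nichols Beta-distributed
frequencies around ancestral values uniform on [0.05, 0.95]),
haplotypes from thresholded latent AR(1) Gaussians with adjacent-variant
correlation `ld_rho` (0.6 default), evenly spaced positions on one
synthetic chromosome (all downstream procedures are per-chromosome
agnostic). Expression: per gene a latent trait = centered causal
dosage scaled to a `cis_h2` variance share (0.3 default, the planted
effect size used throughout the recovery tests) + a polygenic draw with
covariance `polygenic_h2 ·` (breed's realized GRM) + Gaussian noise;
counts are Poisson around `library_factor × baseline × exp(latent)`
with log-normal baselines (median ≈ 200 counts) and library factors —
a monotone positive link; only its monotonicity is relied on. Planted
categories (shared3 / shared2-pair / breed-specific / null) follow the
configured fractions; shared genes get sign-concordant per-breed betas.
Planted causal variants are required to be common (MAF ≥ 0.05) within
*every* breed so the effect is observable in each active breed and the
variant survives the cross-breed QC intersection — consistent with the
empirical observation that lead SNPs of eGenes have the highest MAF in
the breed of detection. GWAS summary statistics use
`se² = 1/(2 n p(1−p))`, marginal z-means spread through realized
genotype correlations, and iid N(0,1) sampling noise per variant; a
configurable fraction of planted trait signals reuses the eQTL causal
variant, the rest are planted at a low-LD (pooled r² < 0.2) variant
inside the gene's cis window.

What the generator does **not** emulate: distance-dependent LD decay
(correlation is index-based AR(1)), recombination hotspots, rare
variants and frequency-dependent architecture, relatedness/pedigree
structure within breeds (founders are unrelated; the polygenic term is
the only source of sample covariance), multi-mapping/overdispersed
counts, batch effects or hidden expression factors (so selected PCs are
mostly noise directions), sex chromosomes, and correlated GWAS noise
across variants (z-score *means* carry LD, the noise does not).
Passing tests therefore demonstrate correctness and calibration of the
statistical machinery under the assumed model, not robustness to the
unmodeled features of real data.

## Problem sizes used by tests and the acceptance script

Chosen so the whole suite runs in minutes on one CPU: recovery and
classification use 150 genes × 1,500 variants × 100 samples/breed with
200 permutations per gene; the null calibration study uses 200 genes;
heritability recovery uses 50 replicates at n = 300; enrichment
calibration uses 100–200 traits × 1,000 resamples; colocalization
discrimination uses 50 replicates in a dense-LD window (300 variants
over 2 Mb, `ld_rho` 0.97, causal MAF ≥ 0.25 — mirroring a WGS panel
where lead variants are common and have many near-perfect proxies; in
sparse low-LD windows the eQTL window evidence at n = 100, R² = 0.3
sits at the H3-vs-H2 prior boundary and discrimination is undefined by
design rather than by implementation).

## Known limitations

* Permutation floor 1/(k_perm+1) limits gene-level resolution; use the
  Beta smoothing option when ranking among highly significant genes.
* The per-variant scan fixes the variance ratio at the null fit; for
  variants explaining a large variance share the ratio is mildly
  misspecified (conservative).
* Condition-by-condition shrinkage ignores cross-breed effect
  correlation, so LFSR is conservative for effects that are truly
  shared; an externally computed posterior matrix can be plugged in.
* Mean imputation of sporadic missing genotypes slightly deflates
  variance at low call rates; upstream filtering is assumed.
* The enrichment control sampling is not MAF- or LD-matched.
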