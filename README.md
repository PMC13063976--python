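# stratiqtl

Breed-stratified *cis*-eQTL mapping and GWAS integration for multi-breed
livestock transcriptome studies.

Modern pig breeds (Duroc, Landrace, Yorkshire) differ in growth, meat
quality and reproduction, and part of that difference is regulatory:
some genetic effects on gene expression are shared across breeds while
others act in only one. `stratiqtl` implements the full analysis chain
for characterizing that structure from genotypes and bulk RNA-seq in a
balanced three-breed design:

1. **Per-breed cis-eQTL mapping** with a linear mixed model

   *y* = **X**α + **s**β + **g** + *e*,  **g** ~ N(0, **G**σ²_g),
   *e* ~ N(0, **I**σ²_e),

   where **G** = **MM**′ / 2Σᵢ pᵢ(1−pᵢ) is the genomic relationship
   matrix from mean-centered dosages, **X** holds an intercept plus
   expression-PC covariates, and **s** is the centered dosage of a
   variant within ±1 Mb of the gene's TSS. The null model is fitted by
   REML (eigendecomposition + 1-D search over σ²_g/σ²_e); the scan holds
   the variance ratio fixed.
2. **Permutation-calibrated eGene discovery**: the gene-level p-value is
   the +1-smoothed tail probability of the observed minimum nominal p
   under permutations of the expression vector, corrected across genes
   by Benjamini–Hochberg; eGenes are genes with q < 0.05.
3. **Sharing classification**: eGenes detected in exactly one breed
   (within a tissue) are breed-specific; in two or three breeds,
   breed-shared.
4. **Effect-sharing quantification**: lead effects are shrunken with an
   empirical-Bayes normal-means mixture per breed; pairwise sharing is
   the proportion of effects (local false sign rate < 0.05) with the
   same direction, optionally within a factor 2 or 4 in magnitude.
5. **GWAS integration**: fold enrichment of significant GWAS SNPs
   (p ≤ 5×10⁻⁸) in eGene ±1 Mb regions against 1,000 resampled
   non-significant control sets, and colocalization posteriors
   (PP.H0–H4 from per-SNP Wakefield approximate Bayes factors; a pair
   colocalizes when PP.H4 > 0.8).

Supporting stages follow the conventions of the field: genotype QC
(pooled MAF ≥ 0.05 & MAC ≥ 6; per-breed MAF > 0.01, MAC > 6, het < 0.99
intersected across breeds), TPM, a low-expression filter (TPM ≤ 0.1 in
more than 80% of samples), TMM normalization, rank-based inverse normal
transformation, one-vs-rest differential expression (|log2FC| > 1 and
FDR < 0.05), per-breed LD scores, per-breed MAF and mean per-gene
conservation scores (≥50% coverage rule).

A first-class synthetic-data module (`stratiqtl.synthetic_data`)
emulates the three-breed design — Balding–Nichols allele-frequency
divergence, first-order haplotype LD, planted shared/specific cis
effects with a GRM-structured polygenic background, Poisson read
counts, and GWAS summary statistics with planted (non-)colocalizing
causal variants — so the whole chain runs and is tested end to end with
no external data.

## Worked example

```python
import stratiqtl as sq
from stratiqtl.preprocess import (genotype_qc, counts_to_tpm, filter_low_expressed,
                                  tmm_normalize, inverse_normal_transform,
                                  select_expression_pcs)
from stratiqtl.eqtl_lmm import compute_grm, map_breed_eqtls
from stratiqtl.classify_share import classify_egenes, classification_summary

cfg = sq.SimConfig(n_per_breed=100, n_variants=1000, n_genes=120,
                   chrom_length=100_000_000, frac_shared_egenes=0.5,
                   frac_specific_egenes=0.2, cis_h2=0.3, seed=1)
genotypes, counts, truth, gwas = sq.simulate_study(cfg)

genotypes, _ = genotype_qc(genotypes, "pooled")
genotypes, report = genotype_qc(genotypes, "per_breed")
print(f"variants after QC: {report.n_output} of {report.n_input}")

flags = {}
for breed in sq.BREEDS:
    gb = genotypes.for_breed(breed)
    expr = counts.subset_samples(list(gb.samples["id"]))
    tpm = counts_to_tpm(expr)
    tpm, _ = filter_low_expressed(tpm)
    expr = expr.subset_genes(expr.genes["id"].isin(set(tpm.genes["id"])).to_numpy())
    tmm, _ = tmm_normalize(expr)
    covariates = select_expression_pcs(tmm)
    y = inverse_normal_transform(tmm)
    grm = compute_grm(gb)
    summary, assoc = map_breed_eqtls(gb, y, covariates.pcs, grm,
                                     k_perm=200, seed=cfg.seed)
    flags[breed] = summary[["gene_id", "is_egene"]]
    print(f"{breed}: {int(summary['is_egene'].sum())} eGenes "
          f"of {len(summary)} genes tested")

classification = classify_egenes(flags, tissue="muscle")
print(classification_summary(classification).to_string(index=False))
```

Output:

```
variants after QC: 819 of 952
Duroc: 63 eGenes of 120 genes tested
Landrace: 56 eGenes of 120 genes tested
Yorkshire: 65 eGenes of 120 genes tested
    breed  n_egenes  n_shared  n_specific  shared_fraction
    Duroc        63        53          10         0.841270
 Landrace        56        50           6         0.892857
Yorkshire        65        55          10         0.846154
```

Here 120 genes carry planted effects (50% shared across breeds, 20%
breed-specific, each explaining 30% of expression variance in its
active breeds); the mapper recovers most of them, and the
classification summary reports, per breed, how many of its eGenes are
also found in at least one other breed. `truth` holds the planted
ground truth for comparing against.

The same stages are available from the shell:

```bash
stratiqtl simulate --seed 1 --out-dir sim/
stratiqtl qc sim/genotypes.vcf sim/samples.tsv --stage pooled --out-dir sim/
stratiqtl normalize sim/counts.tsv sim/genes.tsv --out-dir sim/
stratiqtl map-eqtl sim/genotypes.qc.vcf sim/samples.tsv sim/int.tsv \
    sim/genes.filtered.tsv --breed Duroc --k-perm 1000 --seed 1 --out-dir sim/
```

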