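# cgvscreen

Analysis toolkit for quantitative modifier screens of the kind used to expose
cryptic genetic variation (CGV) in *Caenorhabditis elegans* embryogenesis:
essential maternal-effect genes are knocked down by RNAi in a panel of wild
inbred strains, each strain × gene combination is replicated in multi-well
liquid culture, and the penetrance of embryonic lethality (dead embryos vs
hatched larvae per well) is the phenotype. Differences in penetrance between
strains reveal segregating modifier alleles: *informational* modifiers that
change germline RNAi efficacy for every targeted gene, and *gene-specific*
modifiers whose effect depends on which gene is perturbed.

The package is aimed at quantitative geneticists analysing such screens (or
prototyping new ones against simulated data). It provides:

- **Penetrance GLM** — the factorial quasi-binomial model with logit link,

  `E(Y) = g⁻¹(β₀ + β_strain + β_gene + β_adults + β_date + β_strain×gene + β_strain×adults + β_gene×adults)`,

  fitted by IRLS with a free dispersion φ (Pearson χ²/df), sequential
  analysis of deviance with F = (Δdev/Δdf)/φ, and extraction of the
  strain-by-gene interaction coefficients as derived CGV phenotypes
  (`PenetranceModel`, a scikit-learn-style estimator).
- **Mixed-model association** — an EMMA-style engine: identity-by-state
  kinship, REML/ML variance components by spectral profiling over
  δ = Ve/Vg, genomic heritability h² = Vg/(Vg+Ve) with permutation
  significance, and a per-SNP maximum-likelihood LRT scan
  (`VarianceComponentModel`, `ml_lrt_scan`).
- **GWAS post-processing** — minor-allele-count filtering, Bonferroni
  correction over *unique genotype classes*, single-linkage LD haplotype
  blocks (R² > 0.9), cross-phenotype co-association, and marker-identity
  genotype imputation.
- **Secondary statistics** — Spearman correlation structure among gene
  perturbations, Kruskal–Wallis enrichment for known-interacting gene pairs,
  per-gene expression ANOVA, and the exact two-tailed binomial sign test.
- **Off-target scan** — exact 21-mer matching of RNAi clone sequences
  against a reference genome, both strands.
- **Synthetic screens** — `simulate_genotypes` / `simulate_screen` generate
  genotype panels with LD blocks and beta-binomial well counts from a known
  planted architecture, so every stage can be checked against ground truth.

## Worked example

```python
import cgvscreen as cgv

cfg = cgv.SimulationConfig(n_strains=20, n_genes=5, wells_per_cell=8, n_snps=200, seed=42)
genotypes = cgv.simulate_genotypes(cfg)
wells, truth = cgv.simulate_screen(cfg, genotypes)

table = cgv.sequential_anova(wells)
print(table)
pct = cgv.partition_deviance(table, ["strain", "strain:gene"])
print(f"strain + strain:gene share of total deviance: {pct:.1f}%")
```

prints the sequential analysis of deviance,

```
         term  df  deviance  resid_df  resid_dev     F         p
         NULL NaN       NaN       799   6.28e+04   NaN       NaN
       strain  19  2.52e+04       780   3.77e+04  65.1 1.38e-138
         gene   4  8.89e+03       776   2.88e+04   109  8.77e-72
       adults   1      15.8       775   2.88e+04 0.778     0.378
         date   0  7.28e-12       775   2.88e+04   NaN       NaN
  strain:gene  76  1.42e+04       699   1.46e+04  9.16  3.45e-64
strain:adults  19       518       680   1.41e+04  1.34     0.151
  gene:adults   4      58.9       676    1.4e+04 0.725     0.575
strain + strain:gene share of total deviance: 62.6%
```

The strain row is the informational (RNAi-efficacy) modifier signal, the
strain:gene row the gene-specific modifier signal; both are tested against
the full model's dispersion. The date row is aliased (0 df) because in this
simulated design every strain is assayed in exactly one date batch. The
interaction coefficients then become per-gene phenotypes for the mixed
model:

```python
fit = cgv.fit_quasibinomial_glm(wells)
pheno = cgv.extract_cgv_phenotypes(fit)

sensitive = truth.strains[:18]            # drop the two RNAi-resistant strains
K = cgv.compute_kinship(genotypes.take_strains(sensitive))
y = pheno.estimates.loc[sensitive, "gene03"].to_numpy()
h2, p = cgv.heritability_permutation_test(y, K, n_perm=200, seed=1)
print(f"gene03 genomic heritability: {h2:.2f} (permutation p = {p:.3f})")

gf, _ = cgv.filter_mac(genotypes.take_strains(sensitive), 6)
n_classes, _ = cgv.unique_genotype_classes(gf)
thr = cgv.bonferroni_threshold(0.05, n_classes)
scan = cgv.ml_lrt_scan(y, K=K, genotypes=gf)
```

```
gene03 genomic heritability: 1.00 (permutation p = 0.100)
55 SNPs pass MAC >= 6; 29 unique classes; threshold 1.72e-03
```

A heritability near 1 says genome-wide relatedness explains nearly all of
this gene's modifier variation (a polygenic, common-allele architecture); the
scan table (`snp`, `lrt`, `p`, `mac`) is then thresholded at α divided by the
number of distinct genotype classes, not raw SNPs. The same steps are
available from the shell via the `cgvscreen` console script (`simulate`,
`fit`, `anova`, `phenotypes`, `kinship`, `h2`, `gwas`, `blocks`, `impute`,
`coassoc`, `correlations`, `enrichment`, `expression`, `offtarget`).

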