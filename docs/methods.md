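# Methods

## The penetrance model

Each well contributes a two-column response (dead embryos, hatched larvae).
With m offspring and lethality probability p, the factorial model is a
binomial GLM with logit link over strain, targeted gene, adults per well
(numeric, single df), date batch, and the strain×gene, strain×adults and
gene×adults interactions, in that order. Real screen counts are strongly
overdispersed — offspring within a well share a mother, a bacterial culture
and a micro-environment — so the model is *quasi*-binomial: the variance is
Var(Y) = φ·m·p(1−p) with φ estimated as Pearson χ²/df from the fullest
model. Coefficient significance uses t = β̂/SE on the residual df;
term-level tests are sequential (type-I) analysis-of-deviance F ratios
F = (Δdeviance/Δdf)/φ̂. Because the decomposition is sequential, a term's
deviance is conditional on the terms before it; the default order puts
strain first, so the strain row is marginal over genes, which is the reason
the term-orthogonality test in the suite permutes labels *within* gene
(permuting across genes unbalances the layout and lets strain absorb gene
signal — a property of type-I ANOVA, not of the implementation).

Fitting is IRLS on the weighted least-squares normal equations, relative
deviance tolerance 1e-8, 100 iterations maximum. Exactly collinear columns
are detected once by pivoted QR (a rank property of the design alone) and
dropped, as R's `glm` does; an aliased term yields a 0-df row with no test.
Wells with zero offspring are dropped and counted. Cells with no surviving
(or no dead) embryos are completely separated in the logit parameterization;
the optimizer still converges in deviance, and any coefficient beyond 15
logits is flagged `separated` rather than reported as a finite estimate —
flagged cells should be excluded from downstream association.

### Interaction coefficients as phenotypes, and what is identifiable

The strain-by-gene coefficients are the screen's derived phenotypes:
gene-specific modifier effects after the strain main effect has absorbed
RNAi-efficacy variation and nuisance terms. Contrast coding is treatment by
default (reference strain/gene = alphabetically first, matching R's factor
default), with sum-to-zero available. Only a contrast of the cell-effect
matrix is estimable: under treatment coding the estimand of cell (i, g) is
M[i,g] − M[i,g₀] − M[i₀,g] + M[i₀,g₀]; under sum-to-zero coding it is the
doubly centered matrix. The two codings therefore do **not** differ by a
per-column constant — their coefficients differ by an additive
f(strain)+h(gene) field — but their doubly centered interaction matrices are
identical, which is the invariant the tests assert and the parameterization
(`identifiable_contrast`) in which simulation recovery is scored. Under
treatment coding the reference gene's phenotype column is structurally zero;
the CLI skips zero-variance phenotype columns in `h2`/`gwas` rather than
scanning them.

## Mixed model

y = Xb + u + e with u ~ N(0, Vg·K), e ~ N(0, Ve·I). K is identity-by-state
allele sharing over pairwise-complete sites (diagonal 1; a centered-
covariance alternative sits behind a flag), stabilized by adding 1e-6 to the
diagonal if the smallest eigenvalue is negative. Writing δ = Ve/Vg, one
eigendecomposition of S(K+I)S (S the residual-maker of X) profiles the REML
or ML likelihood down to a 1-D function of ln δ, maximized on a grid over
[−10, 10] with 100 intervals, derivative sign-change bracketing and Brent
refinement. h² = 1/(1+δ); the bounded search clamps h² into
[≈4.5e-5, ≈1−4.5e-5], so a phenotype with no kinship signal reports h² ≈ 0
(never negative) — the same boundary behaviour as the published 0.0000
heritability rows. A flat profile (e.g. K = I, where only Vg+Ve is
identified) sets `identifiable=False`. Heritability significance: phenotype
permutations with the add-one estimator p = (1+#{h²_perm ≥ h²_obs})/(1+n_perm),
so p is never 0 and the smallest achievable value at 1000 permutations is
1/1001. Per-SNP association is the ML likelihood-ratio test of the SNP as a
fixed effect, χ²(1); identical genotype columns share one computation (and
thus bit-identical statistics); missing calls are mean-imputed per SNP;
monomorphic SNPs must be removed by the MAC filter first.

Small-sample note: ĥ² = 1/(1+δ̂) is a nonlinear transform, and with few
independent kinship blocks its sampling distribution piles at the
boundaries; at 10 families of 5 with true h² = 0.5 the mean estimate is
≈0.44. The estimator is consistent (≈0.48 at 60 families).

## GWAS post-processing

In a small inbred panel many SNPs are carried by exactly the same strain
subset, so they are statistically one test: multiplicity is corrected over
unique genotype classes (missing treated as its own symbol; an optional
flip-collapse mode also merges allele-complement columns, which give
identical tests). Haplotype blocks are single-linkage connected components
of the pairwise R² > 0.9 graph (deterministic and order-independent),
within-chromosome by default with a genome-wide flag since selfing species
hold long-range LD; SNPs with >20% missingness are excluded from blocking.
R² is the squared Pearson correlation of 0/1 genotype vectors over
pairwise-complete strains. Imputation by marker identity reports *every*
reference strain with zero mismatches at the target's assayed markers, so an
ambiguous target can be analysed once per proxy; with no perfect match it
returns per-strain mismatch counts for diagnosis.

## Secondary statistics

Spearman rank correlation (average-rank ties) compares the per-strain
coefficient vectors of two gene perturbations; p-values come from exhaustive
permutation enumeration for n ≤ 9 and the t approximation above.
Known-interaction enrichment is a two-group Kruskal–Wallis on the rho values
(tie-corrected, df 1), hence invariant to monotone transforms. Expression
variation uses a per-gene one-way fixed-effects ANOVA over strains, and the
expression-versus-phenotype comparison counts genes whose Spearman
correlation between mean expression and strain coefficients is negative
(lower expression with a less severe phenotype, given coefficients oriented
so larger = more lethal); the count is tested with the exact two-tailed
binomial sign test at null 1/2, defined as twice the smaller tail (observed
value included) capped at 1.

## Off-target scan

Exact k-mer matching (default k = 21, the canonical siRNA length; step 1;
k-mers containing N skipped) between an RNAi clone and a reference genome,
via a hashed index of the clone's k-mers slid over both genome strands.
Matches overlapping the clone's own locus are partitioned from off-target
hits; coordinates are 1-based inclusive on the plus strand. No mismatch
tolerance or thermodynamic scoring — the prediction is presence/absence of a
perfect 21-mer.

## Synthetic screens

The generator emulates the screen's design: by default 55 strains × 29
genes × 8 wells, ~10 adults per well (Poisson), mean 150 offspring per well
(Poisson; the real screens report only "hundreds"), three date batches
assigned by strain thirds, and two RNAi-resistant strains with a −4 logit
offset. Genotypes are haploid 0/1 (fully homozygous lines) in LD blocks of 5
SNPs built by copy-with-probability 0.95 along the chromosome; MAF uniform
on (0.1, 0.5). The architecture is polygenic: 10 informational loci
(N(0, 0.5) logits) build the strain main effect and 8 modifier loci per gene
(N(0, 1.2) logits) build the interaction, all mean-centered over strains so
per-gene baselines (spread 0.25–0.75) keep their interpretation. The effect
scale was set so the simulated sequential-deviance F ratios land in the
published order of magnitude (interaction F ≈ 10 at dispersion ≈ 20).
`planted_modifiers` overrides the random draw with fixed loci/effects for
power studies. Well counts are beta-binomial with intra-well correlation
ρ = 0.15, giving Pearson dispersion 1+(m−1)ρ ≈ 20 at m = 150; because the
effective information per well saturates at 1/ρ as m grows, replication
(wells), not brood size, limits precision. With seed fixed the output is
bit-identical; the genotype and count streams are decoupled so the same
panel can host different screens.

What the generator does not emulate: image-analysis error in the dead/alive
calls, plate-position and bacterial-culture effects, shared ancestry beyond
block-copy LD (no pedigree or recombination model), and linkage between a
gene's modifier loci and the gene itself. Passing recovery tests therefore
demonstrate correctness of the estimators under the stated noise model, not
robustness to those real-data artifacts.

## Verification strategy and problem sizes

Each engine is checked against an independent oracle: the GLM against an
explicit normal-equations IRLS loop (agreement ~1e-8 logits) and against
statsmodels' binomial GLM (note statsmodels' `scale='X2'` divides the same
Pearson χ² by total trials minus rank, not wells minus rank — the R
convention used here — so the cross-check compares coefficients and χ²
itself); the REML/ML optimum against a direct multivariate-normal likelihood
maximized by brute force over (Vg, Ve) within ln δ ∈ [−10, 10], including
the 0.5·log|X'X| REML convention constant; the LRT against the difference of
two such brute-force optima; blocks, classes, MAC filtering and the k-mer
scan against quadratic enumeration. Simulation recovery runs at 40 strains ×
10 genes × 8 wells (interaction Spearman > 0.9 against the identifiable
contrast, resistant strains excluded as in the original association
analysis), 200 replicates for heritability, 50 replicates of a planted
1.5-logit locus for localization power, and 500 null replicates for F-test
calibration at ρ = 0 (the model-correct null; under beta-binomial noise the
test is mildly conservative because the true variance inflation grows with
well size while quasi-likelihood assumes a constant φ). These sizes keep the
full suite and the acceptance script each within a few minutes on one CPU
while leaving the Monte-Carlo error well inside the asserted bands.

## Known limitations

- Separated cells are flagged, not resolved; no bias-reduced (Firth-type)
  fallback is provided.
- The LRT scan recomputes one eigendecomposition per SNP (exact); for panels
  far larger than ~10⁴ SNPs an approximate shared-decomposition variant
  would be the natural extension.
- Sequential (type-I) deviance only; marginal (type-II/III) tests are out of
  scope, as is any random-effects refit of the penetrance model.
- The per-plate introgression validation counts of the original study were
  published only as a supplementary file not redistributed here; the
  corresponding F-test is exercised on constructed and simulated data
  instead.
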