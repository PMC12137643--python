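# orchardpop

Population-genetics tooling for clonally propagated orchard crops (peach
and its relatives), aimed at breeders and germplasm curators who work with
SNP-array genotypes, recorded pedigrees, and fruit-quality phenotypes.

The package chains, as importable Python modules, the computational steps
of an array-driven germplasm study:

- **`array_design`** — the staged SNP-selection funnel for building a
  genotyping array from resequencing variants: sequencing QC (missing rate
  ≤ 0.4, mean depth ≥ 2, mean GQ ≥ 10, site QUAL ≥ 50), a shared-variant
  filter (ALT in ≥ 2 accessions), a deterministic probe-uniqueness
  surrogate, genotype-performance categories (PolyHighResolution,
  NoMinorHom, …, call rate ≥ 97.5%), legacy-array integration by position
  union, and the annotation/interval statistics that describe the result.
- **`kinship`** — genomic relatedness (VanRaden GRM,
  `K = Z Zᵀ / Σ 2pₖ(1−pₖ)` with column-centred dosages `Z`), recursive
  pedigree relatedness with clonal-sport handling (sport–source pairs set
  to 0.97), method-of-moments inbreeding `F`, and threshold-network
  clustering (edges at relatedness > 0.45, connected components ≥ 3).
- **`ibd`** — an identity-run IBD segment caller for phased haplotypes
  (RefinedIBD output files are read by `orchardpop.io` and can be used
  instead), per-cluster segment pileup, and top-decile shared-IBD regions.
- **`lmm`** — single-kinship linear mixed model GWAS in the EMMA /
  FaST-LMM spectral parameterisation: `y = Wα + u + ε`,
  `u ~ N(0, σ²_g K)`; REML profile over `δ = σ²_e/σ²_g`, Wald scans with
  the null-model `δ`, the 1/n significance convention, and per-variant
  PVE `β̂² · 2p(1−p) / Var(y)`.
- **`haplotypes`** — greedy contiguous LD blocks (min pairwise r² ≥ 0.6),
  within-block haplotype groups with the count-≥-2 filter, ANOVA +
  Fisher's-LSD phenotype comparisons, and minimum-spanning haplotype
  networks on Hamming distance.
- **`sweep`** — the two-population windowed selection scan (MAF ≥ 5%,
  50 kb windows / 10 kb step, ≥ 5 SNPs per window, top 1% merged into
  candidate regions) around a pluggable per-SNP differentiation statistic,
  default `d = (p₁−p₂)² / (p̄(1−p̄))`.
- **`kasp`** — a 3-marker allele-specific (KASP-style) early-flowering
  classifier: R/A genotype coding, the 2-of-3 alternate-allele rule, and
  contingency-based accuracy evaluation against day-of-year bloom dates.
- **`phenostats`** — Spearman correlation matrices with significance
  masks, normality-gated cluster-vs-rest tests (Shapiro–Wilk →
  Student's t or Mann–Whitney U), component ratios, flowering
  distributions.
- **`simulate`** — a gene-dropping simulator (founder haplotypes, Haldane
  recombination through arbitrary pedigrees, sport mutants, planted QTLs
  scaled to target PVE, missing/depth/GQ artifacts) that records descent,
  so kinship, IBD and GWAS machinery can be validated against exact truth.

## Worked example

`examples/04_gwas_flowering.py` plants a single flowering-time QTL with a
30% variance share in a 400-accession panel (5,000 SNPs), runs the mixed
model with a genomic-kinship correction, and prints:

```
scanned 5000 SNPs, lambda_GC = 0.985
significance threshold 1/n = 2.00e-04
top hit: Chr1:25005000 p = 1.01e-41, beta = 0.950, PVE = 0.404
planted QTL at 25005000 with realized PVE 0.333
1 SNPs below the threshold
```

The genomic-control factor near 1 shows the kinship term absorbs the
panel structure; the scan's top hit is the planted locus, and its
estimated variance share (0.40) brackets the realized simulated share
(0.33). The other scripts in `examples/` walk through the array-design
funnel, kinship networks, IBD sharing, haplotype blocks with the marker
classifier, the selection scan, and the trait statistics — each is a few
dozen lines, prints what it computes, and ends with a line on what the
numbers mean.

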