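# Methods

This note records the models, conventions, and numerical choices behind
`orchardpop`, and what the synthetic-data validation does and does not
demonstrate.

## Data model and conventions

External formats keep their native coordinates (VCF and GFF3 are 1-based
inclusive); everything in memory is 0-based half-open, converted exactly
once at the I/O boundary. Missing dosages are NaN; missing haplotype
alleles use a dedicated integer sentinel that is only ever compared, never
summed. Every numeric consumer states its own imputation rule: the GRM
and the GWAS scan mean-impute per variant, inbreeding and concordance
drop missing calls, the IBD caller treats them as mismatches.
Multiallelic and indel records are skipped at read time with a count —
the downstream array is SNP-only.

## Array-design cascade

The sequencing-QC thresholds (missing rate ≤ 0.4, depth ≥ 2.0, genotype
quality ≥ 10, allele quality ≥ 50) are applied with depth and GQ
interpreted as **per-variant means over non-missing calls** and allele
quality as the site QUAL field; the per-call-versus-mean reading is
ambiguous in common pipeline descriptions and the mean was chosen as the
stabler statistic at low depth. A metric that is absent altogether counts
as failing rather than passing.

Commercial probe-convertibility scores are proprietary, so probe
suitability is a deterministic surrogate: a variant is rejected when its
±35 bp flank contains any 16-mer occurring more than once in the
reference (forward strand; the surrogate is deterministic either way), or
when a second polymorphism falls inside the probe window, or when the
window runs off the contig. This captures the same failure mode —
repetitive flanking sequence — reproducibly.

Genotype-performance categories are derived from called genotypes, not
hybridisation intensities (none exist in this artifact): call rate below
97.5% → CallRateBelowThreshold; monomorphic → MonoHighResolution; all
three genotype classes → PolyHighResolution; polymorphic without the
minor homozygote → NoMinorHom; anything else (e.g. both homozygote
classes with no heterozygote) → Other. OffTargetVariant is assignable
only from an external cluster-quality flag. The final selection retains
PolyHighResolution ∪ NoMinorHom; legacy-array integration is a union by
(chromosome, position) with the exact identity |A∪B| = |A|+|B|−|A∩B|.
Percentages are rendered half-up to two decimals with `decimal.Decimal`,
never binary-float rounding.

## Kinship

All kinship is reported on the relatedness scale — parent–offspring 0.5,
non-inbred self 1.0, diagonal 1 + F — because the clustering threshold
(0.45), full-sib means (~0.6) and the sport convention (0.97) are only
mutually coherent there. The genomic estimator is the VanRaden form
`Z Zᵀ / Σ 2pₖqₖ` (centred dosages, in-sample frequencies, mean-imputation
before centring keeps K positive semidefinite); a per-column-standardised
variant is available. Because frequencies are estimated in-sample, rows
of K sum to ≈ 0 and the off-diagonal null mean is ≈ −(1+F̄)/(n−1), not
exactly 0 — tests assert the centring identity rather than a naive zero.

Pedigree relatedness uses the recursive tabular method, φ(i,i) =
(1+φ(s,d))/2 and φ(i,j) = (φ(s,j)+φ(d,j))/2 in topological order, scaled
to 2φ. A sport (bud mutation) is a clone: it copies its source's kinship
row and self-value, after which the sport–source entry itself is set to
the conventional 0.97, reflecting near-but-not-exact genetic identity.
The network clustering uses strict `> 0.45` edges ("exceeding" the
threshold), connected components of size ≥ 3 as clusters (smaller
components are reported as isolated pairs/small groups; both knobs are
configurable), ordered by size with a deterministic tie-break.

Inbreeding is the method-of-moments estimator
F = (O_hom − E_hom)/(m − E_hom) with E_hom = Σ(1 − 2pₖqₖ) over the
sample's non-missing calls at panel-polymorphic sites. With heavily
inbred panels the in-sample frequencies themselves shift, so F is
recovered to ~0.05 rather than exactly (see the selfing-chain test).

## IBD

The caller is an identity-run finder on phased haplotypes: for each
sample pair and each of the four haplotype combinations, maximal runs of
marker identity allowing one mismatching marker per run, kept at
≥ 500 kb and ≥ 25 markers by default, then union-merged per pair.
Per-combination runs (rather than per-marker any-combination matching)
are essential: at common alleles, "any combination matches" is true at
most markers and would produce long spurious segments between unrelated
samples. IBS runs overhang true IBD boundaries by a geometric number of
coincidentally matching markers (mean ≈ 1/heterozygosity), a few tens of
kb at the default marker density — negligible against Mb-scale segments.

Descent truth from the simulator can contain *sub-resolution gaps*: two
meioses recombining at adjacent markers leave a one-marker non-IBD gap
that no identity-by-state caller tolerating g mismatches can see.
`TruthSet.ibd_segments(..., merge_gap_markers=g)` expresses the truth at
the caller's resolution by fusing gaps of ≤ g markers; recovery tests
compare at matched resolution and require ≥ 90% reciprocal overlap.

Shared regions: within-cluster pairwise segments are piled into 10 kb
bins (a pair counts once per bin when a segment covers the bin midpoint);
the threshold is the 90th-percentile (lower nearest-rank, for
determinism) of the *positive* bin counts; bins at or above it merge into
regions. Frequency is counted in pairs because pairwise segment files
are the input; counting accessions would need an arbitrary tie to one
member of each pair.

## Mixed-model GWAS

The model is y = Wα + u + ε with u ~ N(0, σ²_g K). The eigendecomposition
K = U S Uᵀ rotates the model to independent observations with weights
Sᵢ + δ, so REML is a one-dimensional profile in δ = σ²_e/σ²_g, optimised
on a 100-point log₁₀ grid over [−5, 5] with bounded Brent refinement of
the best bracket. The scan reuses the null δ for every marker (fast
FaST-LMM mode; exact per-marker REML sits behind a flag) and tests each
marker by a Wald t-test in the rotated, covariate-residualised basis —
with K = I this reduces exactly to OLS, which the tests exploit as an
oracle, alongside an independent dense matrix-inversion REML likelihood
(agreement to 1e-8). Eigenvalues are clipped at zero; K must be PSD to
−1e-8·trace.

The significance convention 1/n is implemented as printed (alongside the
standard 0.05/n); PVE per variant is β̂²·2p(1−p)/Var(y), the standard
interpretation where no formula is published. Genomic-control λ is
reported with every scan.

## Haplotype blocks and networks

Blocks are found by greedy contiguous extension: a block grows rightward
while the minimum r² (composite LD, squared Pearson correlation of
dosages over jointly non-missing samples) between the candidate and every
current member stays ≥ 0.6. This replaces clique-partition heuristics
with a deterministic rule that brute-force interval search can verify;
downstream analyses only consume block intervals. Haplotype frequency is
counted in carrier accessions (copy counting behind a flag) and strings
carried by fewer than two accessions are dropped. For phenotype
comparisons, an accession joins a haplotype group only when both copies
carry the same string — ambiguous heterozygotes are excluded. Group
comparisons are one-way ANOVA followed by Fisher's LSD using the pooled
error variance, with a compact letter display; with two groups LSD is
algebraically Student's t. The haplotype network is a minimum-spanning
network on Hamming distance that keeps every minimum-weight tie (the
median vectors of full median-joining networks are intentionally
omitted).

## Selection scan

The windowing protocol — pooled-MAF ≥ 5% filter, 50 kb windows on a
10 kb step, windows with < 5 SNPs unscored, top 1% by lower nearest-rank
quantile, overlapping/book-ended windows merged — frames a pluggable
per-SNP statistic. The default is the symmetric normalised frequency
differentiation d = (p₁−p₂)²/(p̄(1−p̄)) (4 at a fixed difference);
composite-likelihood sweep statistics can be plugged in without touching
the windowing. Frequencies are allele counts with missing-call
exclusion, unpolarised.

## Marker classifier

Markers are coded R/R, R/A, A/A from dosage 0/1/2; a sample is predicted
early-flowering when ≥ 2 of the 3 markers carry the alternate allele.
Missing markers never count toward the quorum, so an all-missing sample
is conservatively non-early. The flowering cutoff is day-of-year 90
(March 31 in a non-leap year, configurable); April 1 bloomers are *not*
early. Accuracies are computed over records with observed dates, and the
early-phenotype prevalence over the same denominator. Marker selection
ranks candidates by single-marker classification accuracy with call-rate
then p-value tie-breaks — a documented reconstruction, since assay-cost
criteria are not computable here.

## Phenotype statistics

Correlations are Spearman with pairwise-complete deletion (maximises
usable records); the significance mask marks p ≥ 0.05. The two-group
comparison gates on Shapiro–Wilk at α = 0.05 per group — Student's t when
both pass, Mann–Whitney U otherwise; the gate test itself is a documented
choice, as is pooling years by averaging when no year is specified.
Sugar ratios divide component means by the sorbitol mean; the
malate/citrate range is over samples with both acids present.

## Synthetic-data generator

The generator emulates the structure of a multi-family inbred orchard
panel: founder haplotypes with i.i.d. variants (ALT frequency uniform on
[0.05, 0.5] by default — founder diversity parameters are invented, no
published values exist), Hardy–Weinberg pairing, descent with Haldane
(no-interference) crossovers at a constant 2.5 cM/Mb, clonal sports with
5 random somatic changes by default (so sport pairs sit near but not at
the self value, mirroring the 0.97 convention), planted QTLs whose
effects are scaled to target variance shares against observed dosage
variances (total variance 1 by construction), an optional polygenic
background, and an artifact layer (per-variant missing probability,
Poisson depth, GQ = min(99, 5·DP), optional genotype errors). All
randomness flows from one seed through named streams, one per operation.

What it does **not** emulate: linkage disequilibrium within founders
(founder variants are independent, so LD arises only from co-descent),
ascertainment bias of array content, genotype-intensity clustering,
crossover interference, selection during descent, and population
structure beyond the scripted pedigree. Passing tests therefore
demonstrate correctness of the machinery under the stated model, not
performance on real array data; in particular, data-dependent published
quantities (the r = 0.60 field correlation between SNP and pedigree
kinship, the 93.22% array–sequencing concordance, observed haplotype
frequencies) depend on the real panel and are *not* reproduced at
simulation scale — the suite validates the corresponding machinery by
parameter-recovery properties instead.

## Problem sizes and determinism

Simulation-based checks use panels of 200–400 accessions and 2,000–10,000
variants, 30–100 seed replicates for rate assertions, and 10⁴ Monte-Carlo
gene drops for the pedigree-kinship oracle — sizes at which the asserted
expectations (0.5 parent–offspring relatedness, r ≥ 0.9 kinship
correlation, 4–6% type-I error band, ≥ 95% QTL-recovery rate) have
comfortable sampling margins. Quantiles use lower nearest-rank
throughout; percentage rendering is decimal half-up; ties in peak-SNP and
marker selection break by effect size, call rate, then position, so every
pipeline output is reproducible bit-for-bit from its seed.

## Known limitations

- The IBS caller is for clean, phased, densely genotyped data; with
  genotyping error or sparse markers, use external RefinedIBD output.
- The probe-uniqueness surrogate is not a hybridisation-energy model; it
  ranks flank repetitiveness only.
- The greedy LD-block finder emits maximal *contiguous* blocks scanned
  left-to-right; it does not optimise a global partition.
- `pedigree_kinship` is O(n²) per individual and intended for recorded
  orchard pedigrees (hundreds of individuals), not population-scale
  genealogies.
- The LSD letter display is the standard insert-and-absorb construction;
  with many groups it is a readable summary, not a partition proof.
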