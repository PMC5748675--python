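# Methods

This note documents the models, parameter choices and numerical decisions
behind `triadexpr`, and what its synthetic-data tests do and do not
demonstrate about real data.

## Study design being emulated

The package targets the allopolyploid-triad design: two diploid progenitor
species (D3, D4) and their allopolyploid (T2), each represented by three
accessions sampled under mock inoculation and rhizobial inoculation —
18 RNA-seq libraries in a 3 species × 2 treatments × 3 accessions layout.
Accessions are the unit of replication throughout. Trait data (root-hair
deformation ratio, nodule mass, nodule number, percent of plants
nodulated) attach to the inoculated accessions.

## Synthetic data generator

`synthdata` produces every input the chain consumes, with a ground-truth
record per gene and per read.

**References and reads.** Each gene gets a random D3 transcript of
`gene_length` bases (default 500); the D4 homoeologue substitutes each base
independently with probability `divergence_rate` (default 0.02, percent-level
homoeologue divergence). Reads are single-end, `read_length` = 100 bases,
drawn uniformly over genes with subgenome chosen from the gene's true D3
proportion — Beta(c/2, c/2) with concentration `homoeolog_bias_concentration`
= 50, centring usage near 50:50 — and sequencing error flips each base with
probability `error_rate`. Homoeologue pairs are colinear with no indels, so
ungapped mismatch scoring is exact and a brute-force assignment oracle is
feasible.

**Counts.** Counts are generated directly at the gene level (reads exist
only to exercise the assignment arm; the two arms are deliberately
decoupled). Per-gene baseline log2 means are Normal(6.5, 1.5). Planted
pattern genes separate the parents by `lfc_magnitude` (default 2 log2
units; the diploid–diploid divergence magnitude is a test setting, not an
empirical value) and place T2 at the arithmetic midparent (additivity), at
one parent (dominance), or beyond max/min(parents) by another
`lfc_magnitude` (transgressive). Inoculation-responsive genes shift their
mean by ±`lfc_magnitude` under inoculation in designated species. Counts
are NB with dispersion φ (variance μ + φμ²; φ = 0 gives Poisson), scaled by
per-sample depths drawn log-normally around `library_size` with 10% CV to
exercise normalisation. Planted co-expression modules
(`n_modules` × `module_size` genes, default 5 × 60) share a per-sample
latent factor with log2-scale loading `module_strength` = 1; module genes
are drawn from the non-pattern genes so module recovery is not confounded
with species effects.

**Traits.** The HAD ratio is a linear function of the trait-generating
module's mean standardised log expression in inoculated samples plus
Gaussian noise (`noise_sd`); nodule mass, number and percent nodulated are
correlated surrogates (target correlations 0.8/0.7/0.6 with HAD — chosen
once as plausible phenotypic coupling).

**What the generator does not emulate:** transcript isoforms, paired-end
reads, GC and positional bias, gene-length effects, correlated dispersion
structure, batch effects, and the variance-stabilisation behaviour of
regularised-log transforms. Passing recovery tests therefore demonstrates
correctness of the statistical machinery under its own model assumptions,
not robustness to real-library artefacts.

## Homoeologue assignment

Reads are seeded into a shared k-mer index (k = 21, stride k plus the final
window) and every candidate placement is scored on both homoeologues of its
gene by full-read mismatch count. A read is assigned to the subgenome with
strictly fewer mismatches; equal counts are ambiguous; reads tying across
genes, or exceeding `max_mismatch_per_100` = 5 mismatches per 100 bp, are
unmapped (unique mapping only). Usage percentages exclude genes with zero
counts for both copies, are computed per accession, and the inoculation
effect is a paired t-test on accession-level mean percent-D3 (all-zero
differences give p = 1 flagged degenerate; zero-variance nonzero
differences give infinite t, flagged). The mismatch threshold and
tie-breaking are explicit package choices; no published stringency exists
for this step.

## Differential expression

One engine serves within-species treatment contrasts and between-species
contrasts. Size factors are median-of-ratios over genes positive in all
samples, rescaled to geometric mean 1. The expression filter keeps genes
with ≥ 1 CPM in ≥ 3 samples of the contrast. The common dispersion is a
pooled per-gene method-of-moments estimate, φ_g = max(0, (s² − m)/m²) on
size-factor-scaled counts, averaged over genes with scaled mean ≥ 1: the
mean rather than the median of this right-skewed statistic, because at
three replicates per group the median underestimates φ (≈ 0.08 at a true
0.1 in simulation), which would inflate the exact test's type-I error; the
mean is near-unbiased (≈ 0.098) while remaining ≈ 0.003 under Poisson data.

The exact conditional NB test scales counts by size factors and rounds to
integers (a stated simplification of quantile-adjusted pseudo-counts),
conditions on the two-group total t with per-sample mean t/(n_A + n_B), and
sums conditional probabilities ≤ the observed one (minimum-likelihood
two-sidedness, capped at 1; ties included with 1e-10 relative slack so
float noise cannot drop the observed outcome's partners). φ = 0 reduces to
the conditional binomial test. Log2 fold-changes use scaled group means
with a 0.5 pseudo-count; directions are called at BH-adjusted p < α = 0.05.

## Dominance classification

Sign triples come from three DE tables (T2 vs D3, T2 vs D4, D3 vs D4) at
FDR < 0.05, restricted to genes passing the filter in all three
comparisons; treatments are classified separately. The decision table maps
13 triples to named categories and the remaining 14 to ambiguous; a
dominance call requires the parents to differ (s3 ≠ 0) — a dominance claim
without parental divergence is untestable. Roman labels beyond the
anchored II/IV (higher-parent) and IX/XI (lower-parent) pairs are cosmetic;
the functional class is the authoritative output. Silencing = below one
read in all T2 accessions while at least one diploid accession is
expressed; novel = expressed in ≥ 1 T2 accession while below threshold in
every diploid accession, both on raw counts.

## Co-expression network

Expression is log2(count/size-factor + 1) — a stated, monotone substitute
for regularised-log transforms, which are tool-specific; zero-variance
genes are removed first. Signed adjacency ((1 + r)/2)^β uses Pearson
correlation throughout. β is the smallest power in 1..20 whose signed
scale-free fit −sign(slope)·R² reaches 0.8, computed by discretising
connectivities into 10 equal-width bins and regressing log10 p(k) on
log10 mean(k); if no power reaches the target the argmax is returned with
a flag. On small homogeneous simulations (a few equal-size blocks, no
background genes) the fit plateaus below 0.8 because the connectivity
distribution is bimodal rather than power-law-like; heterogeneous networks
(varied module sizes plus unassigned genes) do reach the target.

TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij). Modules
are detected by average-linkage hierarchical clustering of 1 − TOM with a
static cut at 0.995 of the maximum merge height (a deterministic, fully
specified substitute for dynamic hybrid tree cutting, whose parameters are
not portable); clusters below `min_module_size` (default 100; demo runs use
30 at their smaller gene counts) become 'grey', and surviving modules take
colour labels in decreasing size order. Eigengenes are the first principal
component of the standardised module submatrix (unit norm, sign fixed to
correlate positively with members). Module–trait p-values use the
t-transform of Pearson r with df = n − 2 and a 0.01 flagging threshold;
hub genes require |GS| > 0.7 and |MM to own module| > 0.7, strict
inequalities on absolute values. Eigengene differences across species use
one-way ANOVA (df k−1, N−k). Sample ordination is PCA of samples on the
top-500-variance genes.

## Enrichment

One-sided hypergeometric overrepresentation per term, BH-adjusted within
each ontology class, sorted by adjusted then raw p. The annotation is a
user-supplied gene→term table; parent-term propagation is expected to have
been applied upstream, and under-representation is out of scope.

## Pipeline

`run_all` executes simulate → homoeolog → diffexpr → dominance → network →
enrichment from one validated config, writing TSVs with SHA-256 checksums
into a JSON manifest; a stage failure halts with the stage name and a
partial manifest. All randomness derives from the single config seed via
SeedSequence stream-splitting (one stream per stage, one substream per
simulated library). The read-QC thresholds (minimum base quality 30,
minimum read length 50) are recorded as provenance only; synthetic reads
are pre-clean and no trimmer runs.

## Problem sizes and verification

Unit and recovery tests run at desk scale, chosen to make sampling bands
tight while keeping the full suite around a minute: 2000-gene null and
planted DE simulations at 3 vs 3; 2000-gene dominance recovery at
lfc 2, μ 200, φ 0.05; 100-gene/4000-read assignment studies; 300-gene
5-block network recovery at correlation 0.7; a 500-gene end-to-end demo.
Exact statistics are verified against independent oracles: pure-python
lgamma enumeration for the conditional NB test (plus an edgeR
cross-check), a direct-formula BH implementation, a triple-loop TOM, exact
rational hypergeometric enumeration, and raw SVD for eigengenes.

## Known limitations

- Numerical equality with DESeq2/edgeR pipelines on real data is not a
  goal; dispersion shrinkage, GLM/quasi-likelihood testing and rlog are out
  of scope.
- The static dendrogram cut can merge planted blocks at low soft-threshold
  powers; automatic β selection mitigates this but module boundaries on
  real data would benefit from dynamic cutting.
- The assignment arm handles substitutions only (no indels or splicing) and
  single-end reads.
- Enrichment treats terms independently; no term-graph propagation.
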