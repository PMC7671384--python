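# Methods

This note documents the models, defaults and numerical choices behind
`locuskit`, and what the synthetic-data generator does and does not emulate.

## Coordinates and file dialects

All intervals are held 0-based half-open (BED convention) internally. SNP
positions and transcription start sites are 1-based in input files and
converted on read; a SNP at 1-based position p occupies `[p-1, p)`. When a
gene table lacks a `tss` column, the TSS is derived from strand
(`start + 1` for `+`, `end` for `-`). The only missing-value token in
expression files is `NA`; anything else non-numeric is an error, never a
silent zero. Summary bundles are serialized as sorted-key JSON, one file per
lead SNP, so re-runs are byte-identical and diffs are meaningful.

## LD regions and search-space expansion

A region is the span of the lead plus all proxies with r² at or above the
threshold (default 0.80, inclusive, as printed; a lead with no qualifying
proxy yields a 1-bp span; no padding is applied beyond min/max positions).
When r² is computed from data it is the squared Pearson correlation of
unphased dosages (composite LD) — a deliberate choice over haplotype-EM r²,
since the package's inputs are phase-free dosage matrices.

Candidate genes combine two routes with provenance tags:

* **window** — TSS within 1 Mb of the lead position (inclusive boundary),
  same chromosome; gene-body overlap is deliberately not used, mirroring
  standard cis-eQTL mapping-window semantics.
* **interaction** — for an interaction with exactly one anchor overlapping
  the region span, genes whose body overlaps the other anchor; when both
  anchors overlap the region, genes under either anchor qualify (the
  permissive, order-independent reading). Recruitment is restricted to the
  region's chromosome; interaction tissue labels are carried through for
  reporting but do not gate recruitment.

## eQTL model

Expression is regressed on dosage one SNP-gene pair at a time:
β = cov(g, y)/var(g), SE from the residual variance with n − 2 df, two-sided
t p-value floored at the smallest positive double. No covariates are
included — the model is a documented, transparent substitute for
consortium-grade pipelines that regress out expression PCs and genotype
ancestry components; absolute p-values on real data would differ. eGene
selection is per-tissue at nominal P ≤ 0.05 with no multiple-testing
correction (the enrichment stage reports BH-adjusted values separately); the
minimal-p record per tissue is kept as the supporting association.

kNN imputation (default k = 10) replaces each missing cell with the mean of
the k nearest gene profiles observed in that sample; gene-gene distance is
the RMS difference over mutually observed samples (scale-balanced by the
shared-coordinate count), with ties broken by gene order. If fewer than k
genes are complete the whole matrix falls back to per-gene row means and the
result is flagged (`meta['row_mean_fallback']`). Observed entries are never
altered.

## Co-expression modules and the gap statistic

The module gene set is eGene-anchored and non-transitive: a gene joins only
if its Spearman |ρ| to some eGene reaches the threshold (default 0.90,
inclusive; the comparison carries a 1e-12 guard so a partner at exactly the
printed threshold is not lost to floating-point rounding). Spearman
correlations use average ranks for ties; constant genes are flagged as
undefined and reported, and clustering refuses to proceed while any are
present.

Clustering is agglomerative with **average linkage** on d = 1 − ρ (range
[0, 2]). The linkage choice is the field's standard for correlation-distance
co-expression; single linkage chains and complete linkage fragments tight
modules.

The number of modules is selected with the gap statistic using the
pairwise-distance form of the within-cluster dispersion,
W_k = Σ_r D_r / (2 n_r), which stays valid for the non-Euclidean 1 − ρ
distance. Reference datasets (B = 50 by default) permute each gene's values
across samples — destroying gene-gene correlation while preserving
marginals — because the uniform-box reference of the original formulation is
ill-suited to TPM scales; the box reference remains available
(`reference="uniform"`). Gap(k) = mean_b log W*_kb − log W_k and
s_k = sd_b(log W*_kb)·√(1 + 1/B) (the sd term is zero at B = 1). K is the
smallest k with Gap(k) ≥ Gap(k*) − s_{k*}, k* the global maximum (smallest
index on ties) — the globalSEmax rule. The search range defaults to
1..min(10, n_genes − 1).

Two behaviours of this statistic are worth knowing. First, on a single tight
correlated block the gap curve can drift slowly upward past the true K
because splitting a correlated block shrinks log W slightly faster than
splitting the permuted reference; the one-SE rule absorbs this when blocks
hold ~20+ genes, but very small modules (≤ ~10 genes) are selected less
reliably. Second, the permutation reference has a small between-replicate
sd, so s_k is tight; this makes the rule decisive rather than conservative.

Modules without an eQTL gene are dropped at the cut; modules without any
pathway at raw p ≤ α_enrich (default 0.05) are dropped by the enrichment
stage — together these implement the omission rule.

## Pathway enrichment

One-sided (greater) Fisher exact test per (module, pathway): the p-value is
the hypergeometric tail P(X ≥ a) at the table's margins, the odds ratio the
sample OR (a·d)/(b·c) with +∞ when b·c = 0 and a·d > 0. One-sidedness is a
semantic choice — a depleted module is not "enriched"; the two-sided variant
is available. The gene universe is the tissue's expression matrix after
filtering, not the whole genome, to avoid background inflation. BH
adjustment runs across all (module, pathway) pairs within a tissue; both raw
and adjusted values are always reported, and the omission rule uses raw p.
The cross-tissue aggregate keeps the best module-level (p, OR) per
(pathway, tissue), ties resolved to the smaller module label.

## Colocalization

Per SNP, the Wakefield log approximate Bayes factor is
lABF = ½[log(1 − r) + r·z²] with r = W/(W + V), z = β/√V. The prior effect
variance W defaults to 0.0225 (sd 0.15 on a standardized quantitative-trait
scale), configurable per trait. Hypothesis masses are accumulated with
log-sum-exp (stable for lABF up to ~700; verified to 10⁴ SNPs at |z| = 40):
S₁, S₂ over each trait's lABFs and S₁₂ over their sums; posteriors are
proportional to {1, p1·e^S₁, p2·e^S₂, p1·p2·(e^(S₁+S₂) − e^S₁₂),
p12·e^S₁₂} with priors p1 = p2 = 1e-4, p12 = 1e-5. The H3 subtraction is
mathematically a sum over off-diagonal SNP pairs and hence non-negative; a
negative value from floating cancellation is clamped to zero with a warning.
SNPs present in only one trait are dropped and counted, not imputed. The
per-SNP causal posterior is the softmax of lABF₁ + lABF₂ over shared SNPs;
single-trait fine-mapping is the softmax of one trait's lABFs.

A unit change of a trait (β and SE scaled by a constant) leaves all
posteriors unchanged exactly when the prior variance is expressed on the
same scale (W scaled by the square of the constant); at fixed W the
posteriors shift slightly because r = W/(W + V) depends on V. The tests
assert the former, which is the invariance users of effect-scale priors
should expect.

## Synthetic data: what it emulates, what it does not

Genotypes come from a Gaussian copula: equicorrelated latent blocks
(default 10 SNPs at latent ρ = 0.8, MAF 0.3) thresholded at Hardy–Weinberg
genotype frequencies. This gives direct control of the LD structure at
trivial runtime — the reason it was chosen over coalescent simulation — but
note the ordinal thresholding attenuates correlation: latent ρ of 0.8/0.95/
0.99 realizes dosage r² of roughly 0.58/0.69/0.86 at MAF 0.3. Generators
return realized r² alongside the target, and the proxies table is built from
realized values.

Expression uses one latent factor per module (K = 4 modules of 20 genes,
within-module correlation 0.9, between 0.1 by default); eQTL effects add
β·dosage to the configured genes (several effects may be planted, e.g. one
eGene per module driven by leads in different LD blocks, which is the
multi-SNP study shape the integrated analysis expects). Values are shifted
to a non-negative TPM-like scale — a monotone shift only, which the
Spearman-based stages are invariant to, so no attempt is made to match real
TPM distributions, library-size effects, batch structure or real Roadmap
state frequencies. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not robustness to
the full messiness of consortium data.

Summary statistics per trait come from independent cohorts (n = 1000 by
default) drawn from the same LD structure; the phenotype is the standardized
causal dosage scaled to the configured variance explained (5%) plus Gaussian
noise, and per-SNP marginal OLS supplies β and var(β). Every generator
returns its ground truth alongside the data, and the same seed yields
byte-identical fixture directories (each generator draws from its own seed
stream, so outputs do not depend on call order).

## Problem sizes used in the acceptance script

Oracle sweeps: all 46,376 contingency tables with total ≤ 30; 100 Spearman
fixtures including heavy ties; 50 OLS fixtures; trees to n = 12. Calibration:
5,000 null eQTL tests at n = 80. Recovery: 100 colocalization replicates per
scenario (200 SNPs, n = 1000/trait) and 50 module-recovery seeds (80 genes,
100 samples, B = 50 gap references). These sizes make the whole script run
in well under a minute on one CPU while leaving the Monte-Carlo rates stable
to a few percent.

## Known limitations

* No covariates or permutation-based FDR in the eQTL stage; nominal p-values
  only.
* Single-causal-variant assumption in colocalization (no SuSiE-style
  multi-signal extension, no conditional analysis).
* Hard module assignment only (no soft/overlapping membership, no WGCNA-style
  soft thresholding).
* LD computation from dosages only; no haplotype phasing, no population-panel
  management, no genome-build conversion.
* The static HTML report is an export of the analysis tables and tracks, not
  an interactive dashboard.
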