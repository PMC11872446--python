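# Methods

## Summary-statistics handling

A summary-statistics table carries one record per variant: chromosome
(normalized without a `chr` prefix), 1-based position, effect/other
allele, and any of β, se, p, N, MAF.  A record is usable if it has either
a (β, se) pair or a p-value; p-values are clipped to ≥ 1e-300 before any
log or quantile transform.  Harmonization matches two tables on
(chromosome, position) and the allele *set*: swapped effect/other alleles
flip the sign of the second table's β; allele-set mismatches are dropped
with a logged count.  Palindromic (A/T, C/G) variants are retained with a
warning rather than dropped — the colocalization evidence here is
magnitude-based (p-value route), where a strand flip does not change the
statistic — and a strict caller can drop them by filtering on the
`palindromic` flag.

Locus windows are closed intervals `center ± half_width` with
`half_width` defaulting to 500 kb, i.e. a total 1 Mb window.  The
half-width is a parameter everywhere because the "1 Mb window" convention
is ambiguous between ±500 kb and ±1 Mb in practice.

An optional coordinate-mapping join (per-chromosome old→new position
table, applied at read time) substitutes for chain-file liftover;
unmapped rows are dropped with a log line.

## LD panel

LD r² is the squared Pearson correlation of unphased genotype dosages
(composite LD) over pairwise-complete samples.  At the decision
thresholds used downstream (0.50 proxy, 0.80 strong, 0.90 very strong)
the difference from haplotype-phase r² is immaterial, and dosage
correlation requires no phasing.  Monomorphic variants and pairs with
fewer than two complete observations raise an undefined-LD signal rather
than returning 0.  Proxy search excludes the query, restricts to a window
(default ±500 kb), and sorts by descending r² with ties broken by genomic
distance then position.

## Overlap enrichment

Each trait's significant variants (p ≤ 5×10⁻⁸ by default) are clumped
greedily: the smallest-p remaining variant becomes a lead and removes all
remaining significant variants with r² ≥ `clump_r2` to it (ties on p
break by chromosome, position).  Variants not covered by the panel are
retained as independent leads, logged.  Lead matching between traits is
one-to-one and greedy by descending r² (identity counts as r² = 1), so no
lead is counted in two shared pairs.  With n₁, n₂ independent leads,
n_share matches, and Mₑ effective independent SNPs in the population,
expected overlap is n₁·n₂/Mₑ and fold enrichment n_share/expected;
significance is the upper hypergeometric tail (one-sided Fisher exact
over the Mₑ-SNP universe), which reduces to the expected-count arithmetic
in the mean.  Mₑ is a required configuration scalar — it is a property of
the LD population, not estimable from a locus-scale panel.  `clump_r2`
and `share_r2` default to 0.4; neither is dictated by the upstream
methodology, so both are prominent, logged configuration knobs.  BH
adjustment across trait pairs uses the standard step-up procedure.

## Colocalization engine

Per-SNP evidence is the Wakefield approximate Bayes factor on the natural
log scale, `labf = 0.5·(log(1−r) + r·z²)` with `r = w/(w+V)`, `z = β/se`,
`V = se²`, and `w` the prior variance of the true effect.  When only
p-values are published, |z| is recovered from the two-sided p and V is
approximated by the allele-frequency variance of the score statistic:
`V = 1/(2N·f(1−f))` for quantitative traits and
`V = 1/(2N·f(1−f)·s(1−s))` for case-control traits with case fraction s.
Records missing MAF or N are excluded from this route with a logged
count.  The p-value route is direction-blind; hypothesis posteriors are
unaffected, but cross-trait effect-direction checks must come from β
signs where available.

Prior effect sd defaults: 0.15 for quantitative traits (trait-sd units —
with p-value inputs the trait sd cannot be estimated and is fixed at 1,
an assumption logged in the module) and 0.2 log-odds for case-control;
`w = sd²`.

Under one-causal-variant-per-trait, the five hypothesis weights are
accumulated in log space from S1 = logsumexp(l1), S2 = logsumexp(l2),
S12 = logsumexp(l1+l2): H0 = 0, H1 = log p1 + S1, H2 = log p2 + S2,
H3 = log p1 + log p2 + log(e^{S1+S2} − e^{S12}), H4 = log p12 + S12, and
posteriors are their softmax.  The H3 difference of exponentials is
computed as `D + log1p(−exp(S12 − D))` with D = S1+S2; when S12 ≥ D −
1e-12 (a single SNP, or the cross-variant mass numerically exhausted) the
H3 weight is exactly −∞ with a log note.  PP4/PP3 is reported as +∞ when
PP3 underflows to zero.  An independent oracle that enumerates every
causal configuration explicitly agrees with the engine to < 1e-10 on
random instances (tested); posteriors sum to 1 within 1e-12.

Interpretation bands are contiguous and exhaustive: PP4 > 0.900 "single
shared causal variant", (0.700, 0.900] "likely", [0.300, 0.700] "limited
evidence", below "no support"; endpoints of the verbally ambiguous middle
band are assigned inclusively to it.  The PP4/PP3 qualifier uses ≥ 5.00
(further support) and ≥ 3.00 (likely colocalization).

## eGene nomination and per-candidate statistics

A candidate (feature, context) is nominated when a conditionally
independent QTL equals the query SNP or has panel r² ≥ 0.50 to it;
duplicates keep the maximum-r² proxy, and user-curated
(literature-derived) candidates can be appended, flagged `curated`.  The
conditional-independence flags are consumed, not computed.  Per-candidate
statistics operate on raw (covariate-unadjusted) values: OLS slope of
measurement on dosage with a t-test on n−2 df, and an unpaired t-test
between groups (equal-variance Student by default, Welch by flag).
Covariate adjustment (PEER factors, age, sex, genotype PCs) is out of
scope and a documented deviation from full QTL pipelines.

## Pseudobulk differential expression

Filtering removes cells below 500 total counts first, then entire
cell-type clusters left with fewer than 10 cells; the order matters and
was chosen so the cluster threshold applies to analyzable cells (the
cluster minimum is dataset-wide, not per donor — both choices are
configurable).  Counts are summed within donor × cell type.  Size factors
are DESeq2-style median-of-ratios: per sample, exp of the median log
ratio to per-gene geometric means over genes expressed in all samples;
when no such gene exists, genes nonzero in ≥ 90% of samples are used with
geometric means over their nonzero entries (logged fallback).

The per-gene test is a two-group negative-binomial log-linear model,
log μ = log s_j + β₀ + β₁·disease, fitted by IRLS (vectorized across
genes) with per-gene method-of-moments dispersion
α̂ = max((s²−m̄)/m̄², 1e-8) on normalized counts pooled across
conditions; Wald z = β₁/se with a two-sided normal p, BH within cell
type, log2FC = β₁/ln 2.  Cell types with fewer than 2 donors per
condition are skipped with a log line; all-zero genes are excluded.
Deliberate simplifications relative to the full DESeq2 workflow: no
dispersion shrinkage across genes, no fold-change shrinkage, no Cook's
outlier refitting.  Two consequences, both verified by tests: per-gene
p-values differ from DESeq2 on real data (fold-change estimates agree —
a pydeseq2 cross-check bounds the median |Δlog2FC| below 0.1 on
simulated pseudobulk), and the pooled-dispersion estimate is inflated for
truly changed genes, costing power but not estimation accuracy or
ranking.  Bulk matrices take the same normalization after removing genes
whose max (configurable: sum) count across samples is below 5.

## Synthetic data

Haplotypes are a stationary latent Gaussian AR(1) process (coefficient
`ld_rho` per adjacent SNP) thresholded per SNP at the quantile of a
target allele frequency drawn uniformly from `maf_range`; genotypes are
sums of two independent haplotypes.  This gives direct, desk-scale
control of LD decay — the only genealogical feature colocalization
behavior depends on — at the cost of realism in recombination hotspots,
allele-frequency spectra, and long-range structure; thresholding
attenuates the latent correlation, so `ld_rho = 0.95` yields adjacent
genotype r² around 0.4.  GWAS cohorts are drawn fresh from the same
population model at the requested sample size; causal effects are scaled
so each SNP explains its requested variance fraction, and marginal
statistics come from per-SNP OLS (quantitative) or a logistic score test
under a liability threshold (case-control; realized prevalence logged).
Scenario builders cover H0–H4; H3 verifies its causal pair has panel
r² < 0.01 and errors otherwise.  Single-cell counts are NB draws with
per-gene lognormal base means, a lognormal donor random effect
(sd 0.15 on the log scale), per-cell dispersion 0.1, and planted disease
log2 fold changes; metadata carries donor, cell type, condition.

What passing tests show — and do not.  The generator reproduces the
*statistical* structure the methods rely on (LD decay, marginal summary
statistics under known causal placement, donor-structured
overdispersion), so recovery tests validate the inference machinery.
They do not certify performance on real data, where allele-frequency and
LD structure are irregular, effect sizes are small and polygenic,
single-cell data carry ambient RNA, doublets, and batch effects, and
published summary statistics contain harmonization errors.

## Benchmark problem sizes

The replicate colocalization benchmark uses a 1,000-individual ×
300-SNP panel (ld_rho 0.95, MAF 0.05–0.5), 50 replicates per scenario,
trait sample sizes 20,000 and 5,000, and 2% variance explained per causal
SNP — sizes at which a shared causal variant is decisively detectable and
the whole benchmark runs in minutes on one CPU.  The DE benchmark uses
8+8 donors, one ~100-cell cluster per donor, and 1,000 genes with 5%
planted at log2FC = 1, measuring bias over planted genes with base mean
≥ 50 (weakly counted genes carry little fold-change information).

## Numerical and degenerate-input conventions

Posterior arithmetic is entirely in log space; ABF values are finite by
construction after p-clipping.  Empty harmonized overlap and empty
windows return empty/None signals rather than raising.  Ties in greedy
procedures break deterministically (p, then chromosome, then position;
r², then distance, then position), so all pipeline stages are
deterministic given inputs and seeds.  The IRLS clamps the linear
predictor to ±30 and floors the 2×2 determinant at 1e-12; convergence
tolerance is 1e-8 on coefficients with a 50-iteration cap.

## Known limitations

Single-causal-variant assumption per trait (no SuSiE-style multi-signal
colocalization, no credible sets, no conditional analysis); p-value-route
colocalization is direction-blind; no covariate adjustment in
per-candidate statistics; composite (unphased) LD; no population
stratification handling beyond the user's choice of panel; DE lacks
dispersion/LFC shrinkage and outlier handling, so single-gene p-values
near the significance boundary should not be over-read.
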