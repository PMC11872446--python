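# pleioqtl

Tools for asking a common post-GWAS question: when two diseases associate
with the same genomic region, is the overlap driven by a single shared
causal variant, and which gene (in which tissue, cell type, or disease
state) does that variant act through?

The package implements the four stages of that analysis as a reusable
library with a CLI, and ships a synthetic-data generator so the whole
pipeline runs and is tested offline with known ground truth:

1. **Pleiotropic-locus overlap** (`pleioqtl.overlap`) — greedy LD clumping
   of genome-wide-significant variants (p ≤ 5×10⁻⁸) into independent
   leads, one-to-one matching of leads between two traits, and enrichment
   of the shared count against the expectation n₁·n₂/Mₑ (Mₑ = effective
   number of independent SNPs in the LD population), scored with a
   one-sided Fisher exact test and Benjamini–Hochberg adjustment.
2. **Bayesian colocalization** (`pleioqtl.coloc`) — per-SNP Wakefield-style
   approximate Bayes factors, log ABF = ½(log(1−r) + r·z²) with
   r = w/(w+V), computed from (β, se) or, when effect sizes are
   unpublished, from (p, MAF, N); posterior probabilities PP0–PP4 of the
   five causal configurations under priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵; and
   the interpretive decision rules (PP4 > 0.900 → shared causal variant;
   0.700–0.900 → likely; 0.300–0.700 → limited evidence; PP4/PP3 ≥ 5.00 →
   further support, ≥ 3.00 → likely colocalization).
3. **Candidate eGene nomination** (`pleioqtl.egenes`) — LD-proxy search
   (r² > 0.50) of a conditionally independent QTL catalog, plus the small
   statistics used on individual candidates: OLS of a molecular value on
   genotype dosage and the unpaired t-test.
4. **Pseudobulk differential expression** (`pleioqtl.pseudobulk`) —
   single-cell filtering (cells ≥ 500 counts, clusters ≥ 10 cells),
   donor × cell-type aggregation, median-of-ratios size factors, and a
   per-gene negative-binomial Wald test of disease vs control with BH
   adjustment and star annotations (padj < 0.05/0.001/0.0001).

LD comes from a user-supplied genotype reference panel (VCF or dosage
TSV); r² is the squared Pearson correlation of dosages.
`pleioqtl.simulate` generates LD-structured panels (latent Gaussian AR(1)
haplotypes), GWAS summary statistics under shared/distinct causal-variant
scenarios, and single-cell counts with donor structure and planted fold
changes.

## Worked example

```bash
pleioqtl make-fixtures --outdir demo --seed 5
pleioqtl coloc --gwas-a demo/gwas_trait1.tsv --gwas-b demo/gwas_trait2.tsv \
    --center 1:1120000 --route p-maf-n --outdir demo/coloc
```

The fixture plants one causal SNP shared by both simulated traits, and the
engine prints:

```
    locus status  n_snps          pp0          pp1          pp2          pp3  pp4      pp4_pp3                                                        label
1:1120000     ok     120 8.444666e-93 4.597332e-20 1.836863e-76 5.708399e-10  1.0 1.751805e+09 single shared causal variant; further support (PP4/PP3 >= 5)
```

PP4 = 1.0 with PP4/PP3 ≈ 1.8×10⁹: essentially all posterior mass is on a
single shared causal variant, and the PP4/PP3 ratio is far above the 5.00
support bound — the correct call for this simulation.  PP0–PP3 are the
posteriors of no association, single-trait association, and two distinct
causal variants; they are negligible here.

The numbered scripts under `analysis/` run the full narrative on larger
simulations: `01_simulate_inputs.py` writes panels, trait pairs, a QTL
catalog and single-cell counts to `scratch/inputs/`; `02`–`05` then run
overlap (the shared-causal pair shares its locus at 6,667-fold enrichment,
the distinct-causal pair shares nothing), the replicate colocalization
benchmark, eGene nomination, and pseudobulk DE (mean estimated log2FC
0.974 for 50 genes planted at 1.0; 0.1% of null genes flagged), writing
summary tables under `results/`.

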