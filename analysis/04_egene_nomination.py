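#!/usr/bin/env python
"""Candidate eGene nomination for the shared causal SNP via LD proxies.

Queries the synthetic QTL catalog with the H4 causal SNP: a conditionally
independent QTL on its immediate LD neighbor should be nominated (r² well
above the 0.50 proxy threshold) while the distant catalog entry is
rejected.  Also demonstrates the genotype-stratified statistics used on
individual candidates (regression of a molecular value on dosage, unpaired
t-test between conditions).  Writes results/egene_candidates.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pleioqtl.egenes import (genotype_regression, nominate, read_catalog,
                             unpaired_ttest)
from pleioqtl.experiments import H4_CAUSAL_INDEX, benchmark_panel

ROOT = Path(__file__).resolve().parents[1] / "results"
INPUTS = Path(__file__).resolve().parents[1] / "scratch" / "inputs"
SEED = 1


def main():
    panel = benchmark_panel(SEED)
    query = panel.variants[H4_CAUSAL_INDEX]
    catalog = read_catalog(INPUTS / "qtl_catalog.tsv")
    cands = nominate(query, catalog, panel, r2_min=0.50)
    cands.to_csv(ROOT / "egene_candidates.tsv", sep="\t", index=False,
                 float_format="%.6g")
    print("nominated at r2 > 0.50 (self-proxy only; the linked neighbor "
          "falls below the threshold):")
    print(cands.to_string(index=False))
    loose = nominate(query, catalog, panel, r2_min=0.20)
    print("\nat a loose r2 > 0.20 threshold the moderately linked neighbor "
          "enters too:")
    print(loose.to_string(index=False))

    # genotype-stratified illustration on simulated expression: effect of
    # 0.3 per effect allele plus noise
    rng = np.random.default_rng(SEED)
    dosage = panel.dosages[:, H4_CAUSAL_INDEX]
    expr = 1.0 + 0.3 * dosage + rng.normal(0, 0.5, dosage.size)
    slope, intercept, se, p = genotype_regression(dosage, expr)
    print(f"\ngenotype regression: slope={slope:.3f} (true 0.3), p={p:.3g}")

    disease = expr[:500] + 0.4
    control = expr[500:]
    t, p_t = unpaired_ttest(disease, control)
    print(f"unpaired t-test disease vs control: t={t:.2f}, p={p_t:.3g}")


if __name__ == "__main__":
    main()
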