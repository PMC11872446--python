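#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes under scratch/inputs/ (large, regenerable): the LD reference panel (1,000 individuals,
300 SNPs, AR(1) LD), one shared-causal (H4) GWAS trait pair, one
distinct-causal (H3) pair, a small QTL catalog containing a strong LD
proxy of the shared causal SNP, and a single-cell count dataset (8+8
donors) with two planted disease fold changes.
"""

import json
from pathlib import Path

import pandas as pd
from scipy.io import mmwrite

from pleioqtl.experiments import (H3_CAUSAL_INDEX_1, H3_CAUSAL_INDEX_2,
                                  H4_CAUSAL_INDEX, benchmark_panel)
from pleioqtl.ldpanel import ld_r2, write_panel_tsv
from pleioqtl.simulate import (ScSimSpec, ScenarioSpec, simulate_sc_counts,
                               simulate_scenario)
from pleioqtl.sumstats import write_sumstats

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "scratch" / "inputs"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    panel = benchmark_panel(SEED)
    write_panel_tsv(panel, OUT / "panel_dosages.tsv", OUT / "panel_variants.tsv")

    g1, g2, truth4 = simulate_scenario(panel, ScenarioSpec(
        "H4", causal_index_trait1=H4_CAUSAL_INDEX, seed=SEED))
    write_sumstats(g1, OUT / "h4_trait1.tsv")
    write_sumstats(g2, OUT / "h4_trait2.tsv")

    g3, g4, truth3 = simulate_scenario(panel, ScenarioSpec(
        "H3", causal_index_trait1=H3_CAUSAL_INDEX_1,
        causal_index_trait2=H3_CAUSAL_INDEX_2, seed=SEED + 100))
    write_sumstats(g3, OUT / "h3_trait1.tsv")
    write_sumstats(g4, OUT / "h3_trait2.tsv")

    # QTL catalog: one conditionally independent QTL at the causal SNP
    # itself (self-proxy), one at a moderately linked neighbor (below the
    # 0.50 proxy threshold), one at a distant unlinked SNP
    causal = panel.variants[H4_CAUSAL_INDEX]
    proxy = panel.variants[H4_CAUSAL_INDEX + 3]
    distant = panel.variants[10]
    rows = []
    for v, feature, ctx in [(causal, "GENE_A", "fibroblasts"),
                            (proxy, "GENE_B", "lung"),
                            (distant, "GENE_C", "whole_blood")]:
        rows.append({"snp": v.rsid, "chrom": v.chrom, "pos": v.pos,
                     "effect_allele": v.effect_allele,
                     "other_allele": v.other_allele, "feature": feature,
                     "context": ctx, "p": 1e-8, "beta": 0.3,
                     "conditionally_independent": True})
    pd.DataFrame(rows).to_csv(OUT / "qtl_catalog.tsv", sep="\t", index=False)

    sc = simulate_sc_counts(ScSimSpec(
        n_genes=1000, seed=SEED, base_mean_log_mu=0.0,
        planted_log2fc=tuple((i, 1.0) for i in range(50))))
    mmwrite(str(OUT / "sc_counts.mtx"), sc.counts.T.tocoo())
    sc.cell_meta.to_csv(OUT / "sc_cell_meta.tsv", sep="\t", index=False)
    pd.Series(sc.cell_meta["barcode"]).to_csv(OUT / "sc_barcodes.tsv",
                                              index=False, header=False)
    pd.Series(sc.gene_ids).to_csv(OUT / "sc_genes.tsv", index=False,
                                  header=False)

    r2 = ld_r2(panel, causal, proxy).r2
    summary = {
        "seed": SEED,
        "truth_h4": truth4, "truth_h3": truth3,
        "proxy_r2_to_causal": r2,
        "sc_cells": sc.n_cells,
    }
    (OUT / "ground_truth.json").write_text(json.dumps(summary, indent=2))
    print(f"inputs written to {OUT}")
    print(f"  causal SNP {causal.rsid}; catalog neighbor {proxy.rsid} "
          f"(r2={r2:.3f}, below the 0.50 proxy threshold)")
    print(f"  single-cell dataset: {sc.n_cells} cells, 1000 genes, "
          f"50 planted log2fc=1 genes")


if __name__ == "__main__":
    main()
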