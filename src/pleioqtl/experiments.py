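"""Reference study conditions: replicate simulations used by the analysis
drivers, the test suite, and the results-reproduction script.

The colocalization benchmark fixes one LD panel (1,000 individuals, 300
SNPs, latent AR(1) rho 0.95, MAF 0.05-0.5) and, per replicate, simulates a
pair of quantitative GWAS (n = 20,000 and 5,000) in which a causal SNP
explains 2% of each trait's variance.  Shared-causal (H4) replicates plant
one SNP for both traits; distinct-causal (H3) replicates plant two SNPs in
near-linkage-equilibrium.  Colocalization runs on the p-value ABF route
with prior effect sd 0.15 and priors p1 = p2 = 1e-4, p12 = 1e-5, a ±500 kb
window centered on trait 1's lead variant.

The DE benchmark simulates 8+8 donors, one cell type of ~100 cells per
donor, per-cell NB counts at dispersion 0.1 with a lognormal donor effect
(sd 0.15), and optionally plants log2 fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coloc import ColocPriors, ColocResult, coloc_region
from .ldpanel import GenotypePanel
from .pseudobulk import (celltype_proportions, de_all_celltypes,
                         filter_cells_clusters, pseudobulk)
from .simulate import (PanelSpec, ScSimSpec, ScenarioSpec, simulate_panel,
                       simulate_sc_counts, simulate_scenario)
from .sumstats import LocusWindow, VariantKey

H4_CAUSAL_INDEX = 150
H3_CAUSAL_INDEX_1 = 50
H3_CAUSAL_INDEX_2 = 250
VARIANCE_EXPLAINED = 0.02
N_TRAIT1 = 20_000
N_TRAIT2 = 5_000
N_REPLICATES = 50
PRIOR_SD = 0.15
HALF_WIDTH = 500_000


def benchmark_panel(seed: int = 1) -> GenotypePanel:
    """The fixed LD panel of the colocalization benchmark."""
    return simulate_panel(PanelSpec(n_individuals=1000, n_snps=300,
                                    maf_range=(0.05, 0.5), ld_rho=0.95,
                                    seed=seed))


def run_scenario_replicate(panel: GenotypePanel, hypothesis: str,
                           seed: int) -> ColocResult:
    """One replicate: simulate the trait pair and colocalize at trait 1's lead."""
    if hypothesis == "H4":
        spec = ScenarioSpec("H4", causal_index_trait1=H4_CAUSAL_INDEX,
                            variance_explained=VARIANCE_EXPLAINED,
                            n1=N_TRAIT1, n2=N_TRAIT2, seed=seed)
    elif hypothesis == "H3":
        spec = ScenarioSpec("H3", causal_index_trait1=H3_CAUSAL_INDEX_1,
                            causal_index_trait2=H3_CAUSAL_INDEX_2,
                            variance_explained=VARIANCE_EXPLAINED,
                            n1=N_TRAIT1, n2=N_TRAIT2, seed=seed)
    else:
        raise ValueError(f"unsupported hypothesis {hypothesis!r}")
    t1, t2, _ = simulate_scenario(panel, spec)
    lead = t1.df.loc[t1.df["p"].idxmin()]
    window = LocusWindow(VariantKey(lead["chrom"], int(lead["pos"]), "A", "G"),
                         HALF_WIDTH)
    res = coloc_region(t1, t2, window, ColocPriors(),
                       prior_sd_a=PRIOR_SD, prior_sd_b=PRIOR_SD,
                       route="p-maf-n")
    assert res is not None
    return res


def replicate_coloc(hypothesis: str, panel_seed: int, rep_seeds: Sequence[int]
                    ) -> pd.DataFrame:
    """Run the benchmark over replicate seeds; one row of posteriors each."""
    panel = benchmark_panel(panel_seed)
    rows = []
    for s in rep_seeds:
        r = run_scenario_replicate(panel, hypothesis, int(s))
        rows.append({"seed": int(s), "pp0": r.pp0, "pp1": r.pp1, "pp2": r.pp2,
                     "pp3": r.pp3, "pp4": r.pp4, "pp4_pp3": r.pp4_pp3,
                     "n_snps": r.n_snps, "label": r.label})
    return pd.DataFrame(rows)


def h4_replicates(seed: int = 1, n_reps: int = N_REPLICATES) -> pd.DataFrame:
    """Shared-causal-variant replicates (panel seed = seed, reps seed..seed+n-1)."""
    return replicate_coloc("H4", seed, [seed + i for i in range(n_reps)])


def h3_replicates(seed: int = 1, n_reps: int = N_REPLICATES) -> pd.DataFrame:
    """Distinct-causal-variant replicates (reps seed+100..seed+100+n-1)."""
    return replicate_coloc("H3", seed, [seed + 100 + i for i in range(n_reps)])


# ---------------------------------------------------------------------------
# pseudobulk DE benchmark


@dataclass
class DEBenchmarkResult:
    de: pd.DataFrame
    planted_genes: list[str]
    planted_log2fc: float
    null_fp_fraction: float
    planted_bias: Optional[float]


def de_benchmark(seed: int = 1, n_genes: int = 1000, n_planted: int = 0,
                 planted_log2fc: float = 1.0, base_mean_min: float = 50.0
                 ) -> DEBenchmarkResult:
    """Run the full sc -> filter -> pseudobulk -> NB Wald pipeline.

    With ``n_planted = 0`` this is a global-null calibration run; otherwise
    the first ``n_planted`` genes carry the planted disease log2 fold
    change, and bias is measured over planted genes whose pseudobulk base
    mean reaches ``base_mean_min`` (weakly counted genes carry little
    information about the fold change).
    """
    planted = tuple((i, planted_log2fc) for i in range(n_planted))
    spec = ScSimSpec(n_genes=n_genes, planted_log2fc=planted, seed=seed)
    m = filter_cells_clusters(simulate_sc_counts(spec))
    pb = pseudobulk(m)
    de = de_all_celltypes(pb).set_index("gene")
    planted_names = [f"gene{i}" for i in range(n_planted)]
    null_names = [g for g in de.index if g not in set(planted_names)]
    null_fp = float((de.loc[null_names, "p_adj"] < 0.05).mean())
    bias = None
    if n_planted:
        sub = de.loc[[g for g in planted_names if g in de.index]]
        sub = sub[sub["base_mean"] >= base_mean_min]
        bias = float(sub["log2fc"].mean() - planted_log2fc)
    return DEBenchmarkResult(de.reset_index(), planted_names, planted_log2fc,
                             null_fp, bias)
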