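"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* **Genotype panels** — haplotypes from a stationary latent Gaussian AR(1)
  process thresholded per SNP to hit target allele frequencies; genotypes
  are sums of two independent haplotypes.  The AR(1) coefficient controls
  how fast LD decays with distance, which is the only genealogical feature
  colocalization behavior depends on.

* **GWAS summary statistics** — fresh cohorts drawn from the panel's
  population model, a phenotype built from planted causal effects (scaled
  to a requested fraction of trait variance), and per-SNP marginal tests:
  OLS for quantitative traits, a logistic score (trend) test under a
  liability-threshold model for case-control traits.  Scenario builders
  cover the five colocalization hypotheses H0-H4 for a pair of traits on
  one panel.

* **Single-cell counts** — negative-binomial draws with per-gene base
  means, a lognormal donor random effect, and planted disease fold
  changes, with donor/cell-type/condition metadata.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .ldpanel import GenotypePanel
from .pseudobulk import CellCountsMatrix
from .sumstats import SumStatTable, VariantKey, table_from_records

logger = logging.getLogger(__name__)

_ALLELES = ("A", "G")


@dataclass(frozen=True)
class PanelSpec:
    """Population model for a simulated genotype panel."""

    n_individuals: int = 1000
    n_snps: int = 300
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.95
    chrom: str = "1"
    start: int = 1_000_000
    spacing: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ValueError("need positive panel dimensions")


@dataclass(frozen=True)
class ScenarioSpec:
    """Colocalization ground truth for a pair of traits on one panel.

    ``hypothesis`` is one of H0..H4; causal indices are panel positions
    (ignored where the hypothesis has no causal variant for that trait;
    for H4 the trait-2 index defaults to trait 1's).
    """

    hypothesis: str
    causal_index_trait1: Optional[int] = None
    causal_index_trait2: Optional[int] = None
    variance_explained: float = 0.02
    n1: int = 20_000
    n2: int = 5_000
    trait_type1: str = "quantitative"
    trait_type2: str = "quantitative"
    case_fraction1: Optional[float] = None
    case_fraction2: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hypothesis not in ("H0", "H1", "H2", "H3", "H4"):
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if not (0 < self.variance_explained < 0.5):
            raise ValueError("variance_explained must lie in (0, 0.5)")


@dataclass(frozen=True)
class ScSimSpec:
    """Single-cell count simulation with planted disease fold changes.

    ``cell_types`` maps a type name to the (min, max) number of cells per
    donor; ``planted_log2fc`` maps gene index to the disease log2 fold
    change.  ``donor_sd`` is the standard deviation of the lognormal donor
    random effect on the natural-log scale.
    """

    n_donors_per_condition: int = 8
    cell_types: tuple = (("alveolar", 80, 120),)
    n_genes: int = 1000
    base_mean_log_mu: float = 0.0   # per-cell scale: lognormal median 1 count
    base_mean_log_sd: float = 1.0
    dispersion: float = 0.1
    donor_sd: float = 0.15
    planted_log2fc: tuple = ()      # ((gene_index, log2fc), ...)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.donor_sd < 0:
            raise ValueError("donor_sd must be >= 0")


# ---------------------------------------------------------------------------
# genotype panels


def _draw_haplotypes(rng: np.random.Generator, n_hap: int, freqs: np.ndarray,
                     rho: float) -> np.ndarray:
    """Latent AR(1) Gaussians thresholded per SNP at the frequency quantile."""
    m = freqs.size
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        innov = rng.standard_normal((n_hap, m - 1)) * np.sqrt(1.0 - rho ** 2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    thresh = stats.norm.ppf(freqs)
    return (z < thresh[None, :]).astype(np.int8)


def simulate_panel(spec: PanelSpec) -> GenotypePanel:
    """Simulate a genotype reference panel with AR(1)-decaying LD.

    Target allele frequencies are drawn uniformly inside ``maf_range``;
    the generating model is attached to the panel (``population``) so
    fresh GWAS cohorts can be drawn from the same population.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = rng.uniform(*spec.maf_range, size=spec.n_snps)
    h1 = _draw_haplotypes(rng, spec.n_individuals, freqs, spec.ld_rho)
    h2 = _draw_haplotypes(rng, spec.n_individuals, freqs, spec.ld_rho)
    dosages = (h1 + h2).astype(float)
    variants = [
        VariantKey(spec.chrom, spec.start + j * spec.spacing,
                   _ALLELES[0], _ALLELES[1], rsid=f"sim{j}")
        for j in range(spec.n_snps)
    ]
    samples = [f"ind{i}" for i in range(spec.n_individuals)]
    panel = GenotypePanel(dosages, variants, samples,
                          population={"freqs": freqs, "rho": spec.ld_rho,
                                      "spec": spec})
    return panel


def _draw_cohort(panel: GenotypePanel, n: int, rng: np.random.Generator) -> np.ndarray:
    """A fresh genotype cohort from the panel's population model."""
    if panel.population is None:
        raise ValueError("panel carries no population model; use simulate_panel")
    freqs = panel.population["freqs"]
    rho = panel.population["rho"]
    g = (_draw_haplotypes(rng, n, freqs, rho)
         + _draw_haplotypes(rng, n, freqs, rho)).astype(float)
    return g


# ---------------------------------------------------------------------------
# GWAS summary statistics


def _marginal_ols(g: np.ndarray, y: np.ndarray):
    """Vectorized per-SNP simple regression of y on dosage."""
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    sxx = np.where(sxx <= 0, np.nan, sxx)
    beta = sxy / sxx
    rss = syy - beta * sxy
    s2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.sqrt(s2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return beta, se, p


def _score_test(g: np.ndarray, y: np.ndarray):
    """Per-SNP logistic score (Cochran-Armitage trend) test for binary y."""
    n = g.shape[0]
    ybar = y.mean()
    gc = g - g.mean(axis=0)
    u = gc.T @ (y - ybar)
    v = ybar * (1.0 - ybar) * np.einsum("ij,ij->j", gc, gc)
    v = np.where(v <= 0, np.nan, v)
    z = u / np.sqrt(v)
    p = 2.0 * stats.norm.sf(np.abs(z))
    # implied log-odds effect and se from the score statistic
    beta = u / v
    se = 1.0 / np.sqrt(v)
    return beta, se, p


def simulate_gwas(
    panel: GenotypePanel,
    causal_indices: Sequence[int],
    variance_explained: Sequence[float],
    n: int,
    trait_type: str = "quantitative",
    case_fraction: Optional[float] = None,
    seed: int = 0,
    trait_label: str = "trait",
) -> SumStatTable:
    """Marginal per-SNP summary statistics for one simulated trait.

    A fresh cohort of ``n`` individuals is drawn from the panel's
    population.  Each causal SNP's effect size is scaled so the SNP
    explains its requested fraction of (liability) variance; residual
    variance tops the trait up to unit variance.  Quantitative traits are
    tested by per-SNP OLS; case-control traits arise from a liability
    threshold at prevalence ``case_fraction`` and are tested with a
    logistic score test.  MAF (cohort) and N are attached per record.
    """
    rng = np.random.default_rng(seed)
    g = _draw_cohort(panel, n, rng)
    m = g.shape[1]
    betas = np.zeros(m)
    total_ve = float(np.sum(variance_explained))
    if total_ve >= 1:
        raise ValueError("total variance explained must be < 1")
    for idx, ve in zip(causal_indices, variance_explained):
        var_g = g[:, idx].var()
        if var_g <= 0:
            raise ValueError(f"causal SNP {idx} monomorphic in cohort")
        betas[idx] = np.sqrt(ve / var_g)
    liability = g @ betas + rng.standard_normal(n) * np.sqrt(1.0 - total_ve)

    if trait_type == "quantitative":
        beta, se, p = _marginal_ols(g, liability)
    elif trait_type == "case-control":
        if case_fraction is None or not (0 < case_fraction < 1):
            raise ValueError("case-control requires case_fraction in (0,1)")
        thresh = np.quantile(liability, 1.0 - case_fraction)
        y = (liability > thresh).astype(float)
        logger.info("simulate_gwas(%s): realized prevalence %.4f",
                    trait_label, y.mean())
        beta, se, p = _score_test(g, y)
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")

    freq = g.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    records = []
    for j, v in enumerate(panel.variants):
        if not np.isfinite(p[j]):
            continue
        records.append({
            "rsid": v.rsid, "chrom": v.chrom, "pos": v.pos,
            "effect_allele": v.effect_allele, "other_allele": v.other_allele,
            "beta": beta[j], "se": se[j],
            "p": max(min(p[j], 1.0), 1e-300),
            "n": n, "maf": max(maf[j], 1e-6),
        })
    return table_from_records(
        records, trait_type=trait_type, case_fraction=case_fraction,
        trait_label=trait_label)


_SCENARIO_CAUSALS = {
    "H0": (False, False),
    "H1": (True, False),
    "H2": (False, True),
    "H3": (True, True),
    "H4": (True, True),
}


def simulate_scenario(panel: GenotypePanel, spec: ScenarioSpec
                      ) -> tuple[SumStatTable, SumStatTable, dict]:
    """A pair of summary-statistic tables under one colocalization hypothesis.

    For H4 both traits share trait 1's causal SNP; for H3 the two causal
    SNPs must be in near-linkage-equilibrium in the panel (r² < 0.01,
    checked, else a spec error).  Returns (table1, table2, truth).
    """
    use1, use2 = _SCENARIO_CAUSALS[spec.hypothesis]
    c1 = spec.causal_index_trait1
    c2 = spec.causal_index_trait2
    if spec.hypothesis == "H4":
        c2 = c1 if c2 is None else c2
        if c2 != c1:
            raise ValueError("H4 requires a single shared causal index")
    if spec.hypothesis == "H3":
        if c1 is None or c2 is None or c1 == c2:
            raise ValueError("H3 requires two distinct causal indices")
        x1 = panel.dosages[:, c1]
        x2 = panel.dosages[:, c2]
        r2 = float(np.corrcoef(x1, x2)[0, 1] ** 2)
        if r2 >= 0.01:
            raise ValueError(
                f"H3 causal pair has panel r²={r2:.3g} >= 0.01; pick distant SNPs")
    ci1 = [c1] if use1 else []
    ci2 = [c2] if use2 else []
    rng = np.random.default_rng(spec.seed)
    seed1, seed2 = rng.integers(0, 2 ** 31 - 1, size=2)
    t1 = simulate_gwas(panel, ci1, [spec.variance_explained] * len(ci1),
                       spec.n1, spec.trait_type1, spec.case_fraction1,
                       seed=int(seed1), trait_label="trait1")
    t2 = simulate_gwas(panel, ci2, [spec.variance_explained] * len(ci2),
                       spec.n2, spec.trait_type2, spec.case_fraction2,
                       seed=int(seed2), trait_label="trait2")
    truth = {"hypothesis": spec.hypothesis, "causal1": ci1, "causal2": ci2}
    return t1, t2, truth


# ---------------------------------------------------------------------------
# single-cell counts


def simulate_sc_counts(spec: ScSimSpec) -> CellCountsMatrix:
    """Cell x gene NB counts with donor structure and planted fold changes.

    Per cell of donor d in condition c the count of gene g is drawn
    NB(mean = base_mean_g * donor_factor_d * fc_gc, dispersion) where
    ``fc_gc`` is 2**log2fc for planted genes in disease and 1 otherwise;
    donor factors are lognormal(0, donor_sd).
    """
    rng = np.random.default_rng(spec.seed)
    n_genes = spec.n_genes
    base = rng.lognormal(spec.base_mean_log_mu, spec.base_mean_log_sd, n_genes)
    fc = np.ones(n_genes)
    for gi, l2 in spec.planted_log2fc:
        fc[int(gi)] = 2.0 ** float(l2)

    blocks, meta = [], []
    r_nb = 1.0 / spec.dispersion
    for cond in ("control", "disease"):
        for d in range(spec.n_donors_per_condition):
            donor = f"{cond[:3]}{d}"
            donor_factor = rng.lognormal(0.0, spec.donor_sd)
            for ct_name, lo, hi in spec.cell_types:
                n_cells = int(rng.integers(lo, hi + 1))
                mu = base * donor_factor
                if cond == "disease":
                    mu = mu * fc
                p_nb = r_nb / (r_nb + mu)
                counts = rng.negative_binomial(r_nb, p_nb[None, :],
                                               size=(n_cells, n_genes))
                blocks.append(counts)
                for k in range(n_cells):
                    meta.append({"barcode": f"{donor}_{ct_name}_{k}",
                                 "donor_id": donor, "cell_type": ct_name,
                                 "condition": cond})
    counts = sparse.csr_matrix(np.vstack(blocks))
    genes = [f"gene{j}" for j in range(n_genes)]
    return CellCountsMatrix(counts, pd.DataFrame(meta), genes)
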