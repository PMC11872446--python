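"""Cross-phenotype overlap of independent genome-wide-significant loci.

Two traits are compared by (1) greedy LD-clumping each trait's significant
variants into independent lead SNPs, (2) matching leads between traits
(identity or LD above a threshold), and (3) scoring the shared count
against the expectation n1*n2/Me, where Me is the effective number of
independent SNPs in the LD population.  Significance is a one-sided
Fisher exact (hypergeometric upper tail) over the Me-SNP universe, with
Benjamini-Hochberg adjustment across trait pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ldpanel import GenotypePanel, UndefinedLDError, ld_r2
from .sumstats import SumStatTable, VariantKey

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
DEFAULT_CLUMP_R2 = 0.4
DEFAULT_SHARE_R2 = 0.4


@dataclass
class LeadSnpSet:
    """Independent lead SNPs for one trait after greedy LD clumping."""

    trait_label: str
    p_threshold: float
    leads: list[tuple[VariantKey, float]]

    def __len__(self) -> int:
        return len(self.leads)


@dataclass(frozen=True)
class OverlapResult:
    """Shared-locus enrichment between two traits (the iCPAGdb arithmetic)."""

    n1: int
    n2: int
    n_share: int
    me: float
    expected: float
    fold: float
    p: float
    p_adj: Optional[float] = None


def clump_hits(
    table: SumStatTable,
    panel: GenotypePanel,
    p_threshold: float = GENOME_WIDE_P,
    clump_r2: float = DEFAULT_CLUMP_R2,
) -> LeadSnpSet:
    """Greedy LD clumping of significant variants into independent leads.

    Repeatedly takes the smallest-p remaining significant variant as a lead
    and removes all remaining significant variants with panel r² >= clump_r2
    to it.  Ties on p break by (chrom, pos).  Variants absent from the panel
    are treated as independent (retained as their own leads) with a log line.
    """
    df = table.df[table.df["p"] <= p_threshold]
    cand: list[tuple[float, VariantKey]] = []
    n_uncovered = 0
    for r in df.itertuples():
        v = VariantKey(r.chrom, int(r.pos), r.effect_allele, r.other_allele,
                       None if (r.rsid != r.rsid) else r.rsid)
        if v not in panel:
            n_uncovered += 1
        cand.append((float(r.p), v))
    if n_uncovered:
        logger.info("clump_hits(%s): %d significant variants not in panel, "
                    "treated as independent", table.trait_label, n_uncovered)
    cand.sort(key=lambda t: (t[0], t[1].chrom, t[1].pos))
    leads: list[tuple[VariantKey, float]] = []
    remaining = cand[:]
    while remaining:
        p_lead, v_lead = remaining.pop(0)
        leads.append((v_lead, p_lead))
        kept = []
        for p, v in remaining:
            linked = False
            if v_lead in panel and v in panel:
                try:
                    linked = ld_r2(panel, v_lead, v).r2 >= clump_r2
                except UndefinedLDError:
                    linked = False
            if not linked:
                kept.append((p, v))
        remaining = kept
    return LeadSnpSet(table.trait_label, p_threshold, leads)


def count_shared(
    a: LeadSnpSet,
    b: LeadSnpSet,
    panel: GenotypePanel,
    share_r2: float = DEFAULT_SHARE_R2,
) -> list[tuple[VariantKey, VariantKey, float]]:
    """One-to-one matching of leads between traits.

    A pair is shareable iff the leads are the same variant or panel
    r² >= share_r2.  Matching is greedy by descending r² (identity counts
    as r²=1), so each lead participates in at most one shared pair.
    """
    pairs: list[tuple[float, int, int]] = []
    for i, (va, _) in enumerate(a.leads):
        for j, (vb, _) in enumerate(b.leads):
            if (va.chrom, va.pos, va.allele_set) == (vb.chrom, vb.pos, vb.allele_set):
                pairs.append((1.0, i, j))
                continue
            if va in panel and vb in panel:
                try:
                    r2 = ld_r2(panel, va, vb).r2
                except UndefinedLDError:
                    continue
                if r2 >= share_r2:
                    pairs.append((r2, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared = []
    for r2, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared.append((a.leads[i][0], b.leads[j][0], r2))
    return shared


def overlap_enrichment(n1: int, n2: int, n_share: int, me: float) -> OverlapResult:
    """Expected overlap, fold enrichment, and one-sided Fisher exact p.

    expected = n1*n2/me; fold = n_share/expected.  p is the upper tail of
    the hypergeometric distribution for drawing >= n_share of trait 1's n1
    loci when sampling n2 loci from an Me-SNP universe (equivalently a
    one-sided Fisher exact test on the 2x2 table with alternative
    'enrichment').
    """
    me_int = int(round(me))
    if n1 <= 0 or n2 <= 0:
        raise ValueError("n1 and n2 must be positive")
    if not (0 <= n_share <= min(n1, n2)):
        raise ValueError(f"n_share={n_share} outside [0, min(n1,n2)]")
    if me_int < n1 + n2 - n_share:
        raise ValueError("me too small for the observed counts")
    expected = n1 * n2 / me
    fold = n_share / expected
    # P(X >= n_share), X ~ Hypergeom(M=me, n=n1, N=n2)
    p = float(stats.hypergeom.sf(n_share - 1, me_int, n1, n2))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return OverlapResult(n1, n2, n_share, me, expected, fold, p)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def trait_pair_overlap(
    a: SumStatTable,
    b: SumStatTable,
    panel: GenotypePanel,
    me: float,
    p_threshold: float = GENOME_WIDE_P,
    clump_r2: float = DEFAULT_CLUMP_R2,
    share_r2: float = DEFAULT_SHARE_R2,
) -> tuple[OverlapResult, LeadSnpSet, LeadSnpSet, list]:
    """Convenience pipeline: clump both traits, match leads, score enrichment."""
    la = clump_hits(a, panel, p_threshold, clump_r2)
    lb = clump_hits(b, panel, p_threshold, clump_r2)
    shared = count_shared(la, lb, panel, share_r2)
    res = overlap_enrichment(max(len(la), 1), max(len(lb), 1), len(shared), me) \
        if la.leads and lb.leads else \
        OverlapResult(len(la), len(lb), len(shared), me, 0.0, 0.0, 1.0)
    return res, la, lb, shared
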