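"""Bayesian colocalization of two association signals at one locus.

Given per-SNP evidence for two traits over a shared set of variants, the
engine computes posterior probabilities of five hypotheses:

* H0 — neither trait associated in the locus,
* H1 / H2 — only trait 1 / only trait 2 associated,
* H3 — both associated, but through distinct causal variants,
* H4 — both associated through a single shared causal variant.

Per-SNP evidence is a Wakefield-style approximate Bayes factor computed on
the natural-log scale::

    log ABF = 0.5 * (log(1 - r) + r * z**2),   r = w / (w + V)

where z = beta/se, V = se**2, and w is the prior variance of the true
effect.  When only p-values are available, |z| is recovered from the
two-sided p and V is approximated from the sample size and allele
frequency: V = 1/(2*N*f*(1-f)) for quantitative traits and
V = 1/(2*N*f*(1-f)*s*(1-s)) for case-control traits with case fraction s.
This p-value route is direction-blind: it carries no effect sign, which is
immaterial for the hypothesis posteriors.

Under a single-causal-variant-per-trait assumption the hypothesis weights
are sums of per-configuration prior x Bayes-factor products, accumulated in
log space; the posteriors are their softmax.  Priors default to
p1 = p2 = 1e-4 and p12 = 1e-5 per SNP.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .sumstats import (LocusWindow, P_FLOOR, SumStatTable, VariantKey,
                       extract_window, harmonize_pair)

logger = logging.getLogger(__name__)

# default prior standard deviations of the true effect size
PRIOR_EFFECT_SD_QUANT = 0.15   # in trait-sd units (sdY taken as 1)
PRIOR_EFFECT_SD_CC = 0.2       # in log-odds units

#: interpretation bands on PP4 (upper-exclusive at 0.900, inclusive elsewhere)
LABEL_SHARED = "single shared causal variant"
LABEL_LIKELY = "likely single shared causal variant"
LABEL_LIMITED = "limited evidence"
LABEL_NONE = "no colocalization support"


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of association with either or both traits."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2) < 1):
            raise ValueError("require 0 < p12 <= p1, p2 < 1")

    def check_n_snps(self, n_snps: int) -> None:
        if n_snps * (self.p1 + self.p2 + self.p12) >= 1:
            raise ValueError(
                f"priors sum to >= 1 over {n_snps} SNPs; reduce p1/p2/p12")


@dataclass
class ABFVector:
    """Aligned per-variant log approximate Bayes factors for one trait."""

    variants: list[VariantKey]
    labf: np.ndarray
    w: float
    route: str  # "beta-se" or "p-maf-n"

    def __post_init__(self) -> None:
        self.labf = np.asarray(self.labf, dtype=float)
        if self.labf.shape != (len(self.variants),):
            raise ValueError("labf length must match variant list")
        if not np.all(np.isfinite(self.labf)):
            raise ValueError("labf values must be finite")


@dataclass
class ColocResult:
    """Posterior probabilities PP0..PP4 with priors and the interpretive label."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int
    priors: ColocPriors
    label: str = ""

    @property
    def pps(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])

    @property
    def pp4_pp3(self) -> float:
        if self.pp3 == 0.0:
            return math.inf
        return self.pp4 / self.pp3


def labf_from_beta_se(beta, se, w: float):
    """log ABF from an effect estimate and its standard error.

    Accepts scalars or arrays; ``se`` must be positive, ``w`` is the prior
    effect variance (sd squared).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if w < 0:
        raise ValueError("w must be >= 0")
    V = se ** 2
    r = w / (w + V)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z ** 2)
    return float(out) if out.ndim == 0 else out


def labf_from_p(p, maf, n, trait_type: str = "quantitative",
                case_fraction: Optional[float] = None,
                w: float = PRIOR_EFFECT_SD_QUANT ** 2):
    """log ABF from (p, MAF, N) when betas and standard errors are unavailable.

    |z| is the upper-tail standard-normal quantile at p/2; the sampling
    variance of the implied effect is approximated from allele-frequency
    variance.  p-values below 1e-300 are clipped there with a warning.
    """
    p = np.asarray(p, dtype=float)
    maf = np.asarray(maf, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p must lie in (0, 1]")
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    if np.any(n < 2):
        raise ValueError("n must be >= 2")
    n_clip = int(np.sum(p < P_FLOOR))
    if n_clip:
        logger.warning("labf_from_p: clipped %d p-values to %g", n_clip, P_FLOOR)
        p = np.clip(p, P_FLOOR, None)
    z = stats.norm.isf(p / 2.0)
    V = 1.0 / (2.0 * n * maf * (1.0 - maf))
    if trait_type == "case-control":
        if case_fraction is None or not (0 < case_fraction < 1):
            raise ValueError("case-control route requires case_fraction in (0,1)")
        V = V / (case_fraction * (1.0 - case_fraction))
    elif trait_type != "quantitative":
        raise ValueError(f"unknown trait_type {trait_type!r}")
    r = w / (w + V)
    out = 0.5 * (np.log1p(-r) + r * z ** 2)
    return float(out) if out.ndim == 0 else out


def coloc_posteriors(l1: ABFVector, l2: ABFVector,
                     priors: ColocPriors = ColocPriors()) -> ColocResult:
    """Posterior probabilities of H0..H4 from two aligned log-ABF vectors.

    All accumulation is in log space.  With S1 = logsumexp(l1),
    S2 = logsumexp(l2), S12 = logsumexp(l1+l2), the unnormalized log
    weights are::

        H0 = 0
        H1 = log p1 + S1
        H2 = log p2 + S2
        H3 = log p1 + log p2 + log(exp(S1+S2) - exp(S12))
        H4 = log p12 + S12

    The H3 difference-of-exponentials is evaluated stably via log1p; for a
    single SNP (or when the cross term exhausts the product numerically)
    the H3 weight is exactly -inf.
    """
    if len(l1.variants) != len(l2.variants) or any(
            a.chrom != b.chrom or a.pos != b.pos
            for a, b in zip(l1.variants, l2.variants)):
        raise ValueError("ABF vectors are not aligned on the same variants")
    n = len(l1.variants)
    if n < 1:
        raise ValueError("need at least one SNP")
    priors.check_n_snps(n)

    s1 = logsumexp(l1.labf)
    s2 = logsumexp(l2.labf)
    s12 = logsumexp(l1.labf + l2.labf)
    d = s1 + s2
    if n == 1 or s12 >= d - 1e-12:
        # no i != j mass (single SNP, or numerically exhausted)
        if n > 1:
            logger.info("coloc_posteriors: cross-variant H3 mass numerically zero")
        h3 = -np.inf
    else:
        h3 = math.log(priors.p1) + math.log(priors.p2) \
            + d + math.log1p(-math.exp(s12 - d))
    weights = np.array([
        0.0,
        math.log(priors.p1) + s1,
        math.log(priors.p2) + s2,
        h3,
        math.log(priors.p12) + s12,
    ])
    pps = np.exp(weights - logsumexp(weights))
    pps /= pps.sum()
    res = ColocResult(*pps, n_snps=n, priors=priors)
    res.label = interpret(res)
    return res


def interpret(result: ColocResult) -> str:
    """The printed decision rules on PP4 and PP4/PP3.

    PP4 > 0.900 -> shared causal variant; (0.700, 0.900] -> likely shared;
    [0.300, 0.700] -> limited evidence; below -> no support.  A qualifier is
    appended from PP4/PP3: >= 5.00 'further support', >= 3.00 'likely
    colocalization'.
    """
    pp4 = result.pp4
    if pp4 > 0.900:
        label = LABEL_SHARED
    elif pp4 > 0.700:
        label = LABEL_LIKELY
    elif pp4 >= 0.300:
        label = LABEL_LIMITED
    else:
        label = LABEL_NONE
    ratio = result.pp4_pp3
    if ratio >= 5.00:
        label += "; further support (PP4/PP3 >= 5)"
    elif ratio >= 3.00:
        label += "; likely colocalization (PP4/PP3 >= 3)"
    return label


def _abf_for_table(pair: pd.DataFrame, suffix: str, table: SumStatTable,
                   prior_sd: Optional[float], route: Optional[str] = None) -> ABFVector:
    """Build the ABF vector for one side of a harmonized pair.

    By default the (beta, se) route is used when fully available and the
    (p, MAF, N) route otherwise; ``route`` forces one of "beta-se" /
    "p-maf-n" (the latter mirrors analyses where effect sizes were absent
    from the published summary statistics).
    """
    if prior_sd is None:
        prior_sd = (PRIOR_EFFECT_SD_CC if table.trait_type == "case-control"
                    else PRIOR_EFFECT_SD_QUANT)
    w = prior_sd ** 2
    variants = [VariantKey(r.chrom, int(r.pos), r.effect_allele, r.other_allele)
                for r in pair.itertuples()]
    beta = pair[f"beta_{suffix}"].to_numpy(dtype=float)
    se = pair[f"se_{suffix}"].to_numpy(dtype=float)
    beta_ok = np.all(np.isfinite(beta)) and np.all(np.isfinite(se)) and np.all(se > 0)
    if route == "beta-se" and not beta_ok:
        raise ValueError("beta-se route requested but beta/se incomplete")
    if beta_ok and route != "p-maf-n":
        return ABFVector(variants, labf_from_beta_se(beta, se, w), w, "beta-se")
    p = pair[f"p_{suffix}"].to_numpy(dtype=float)
    maf = pair[f"maf_{suffix}"].to_numpy(dtype=float)
    n = pair[f"n_{suffix}"].to_numpy(dtype=float)
    usable = np.isfinite(p) & np.isfinite(maf) & np.isfinite(n)
    if not usable.all():
        logger.info("coloc: excluded %d records lacking maf/n on the p-value route",
                    int((~usable).sum()))
    labf = labf_from_p(p[usable], maf[usable], n[usable], table.trait_type,
                       table.case_fraction, w)
    kept = [v for v, u in zip(variants, usable) if u]
    return ABFVector(kept, labf, w, "p-maf-n")


def coloc_region(
    a: SumStatTable,
    b: SumStatTable,
    window: LocusWindow,
    priors: ColocPriors = ColocPriors(),
    prior_sd_a: Optional[float] = None,
    prior_sd_b: Optional[float] = None,
    route: Optional[str] = None,
) -> Optional[ColocResult]:
    """Windowed end-to-end colocalization of two tables.

    Pipeline: restrict both tables to the window, harmonize on shared
    variants, compute per-trait log-ABFs (route chosen per trait by
    available fields), then evaluate the hypothesis posteriors.  Returns
    ``None`` when no shared usable variants remain (the empty-overlap
    signal), never raising for emptiness.
    """
    wa = extract_window(a, window)
    wb = extract_window(b, window)
    pair = harmonize_pair(wa, wb)
    if pair.empty:
        logger.info("coloc_region: no shared variants in window")
        return None
    v1 = _abf_for_table(pair, "a", a, prior_sd_a, route)
    v2 = _abf_for_table(pair, "b", b, prior_sd_b, route)
    if len(v1.variants) != len(v2.variants) or not v1.variants:
        # align to the intersection of usable variants across routes
        keys1 = {(v.chrom, v.pos) for v in v1.variants}
        keys2 = {(v.chrom, v.pos) for v in v2.variants}
        common = keys1 & keys2
        if not common:
            logger.info("coloc_region: no jointly usable variants")
            return None
        m1 = [i for i, v in enumerate(v1.variants) if (v.chrom, v.pos) in common]
        m2 = [i for i, v in enumerate(v2.variants) if (v.chrom, v.pos) in common]
        v1 = ABFVector([v1.variants[i] for i in m1], v1.labf[m1], v1.w, v1.route)
        v2 = ABFVector([v2.variants[i] for i in m2], v2.labf[m2], v2.w, v2.route)
    return coloc_posteriors(v1, v2, priors)


def result_to_frame(results: Sequence[tuple[str, Optional[ColocResult]]]) -> pd.DataFrame:
    """Tabulate labelled ColocResults (None rows become status='empty')."""
    rows = []
    for name, r in results:
        if r is None:
            rows.append({"locus": name, "status": "empty"})
        else:
            rows.append({
                "locus": name, "status": "ok", "n_snps": r.n_snps,
                "pp0": r.pp0, "pp1": r.pp1, "pp2": r.pp2, "pp3": r.pp3,
                "pp4": r.pp4, "pp4_pp3": r.pp4_pp3, "label": r.label,
            })
    return pd.DataFrame(rows)
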