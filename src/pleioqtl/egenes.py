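"""Candidate causal-gene nomination via LD proxies, plus the small
genotype-stratified statistics used to inspect individual candidates.

A QTL catalog lists conditionally independent QTLs (variant, feature,
context, p).  A candidate is nominated for a query SNP when such a QTL is
the query itself or an LD proxy of it (panel r² above a threshold,
conventionally 0.50); one nomination is kept per (feature, context),
retaining the highest-r² proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .ldpanel import GenotypePanel, PROXY_R2, UndefinedLDError, ld_r2
from .sumstats import VariantKey, normalize_chrom

logger = logging.getLogger(__name__)

CATALOG_COLUMNS = ["snp", "chrom", "pos", "effect_allele", "other_allele",
                   "feature", "context", "p", "beta", "conditionally_independent"]


def read_catalog(path) -> pd.DataFrame:
    """Read a QTL catalog TSV with the :data:`CATALOG_COLUMNS` schema."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns and c != "beta"]
    if missing:
        raise KeyError(f"catalog missing columns: {missing}")
    if "beta" not in df.columns:
        df["beta"] = np.nan
    df["chrom"] = df["chrom"].map(normalize_chrom)
    bad = ~((df["p"] > 0) & (df["p"] <= 1))
    if bad.any():
        logger.info("read_catalog: dropped %d rows with invalid p", int(bad.sum()))
        df = df[~bad]
    return df.reset_index(drop=True)


def nominate(
    query: VariantKey,
    catalog: pd.DataFrame,
    panel: GenotypePanel,
    r2_min: float = PROXY_R2,
    extra_candidates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Nominate (feature, context) candidates whose conditionally independent
    QTL is the query SNP or an LD proxy of it.

    Returns a DataFrame (feature, context, proxy_rsid, proxy_chrom,
    proxy_pos, r2, source_p) sorted by descending r², de-duplicated on
    (feature, context) keeping the max-r² proxy.  ``extra_candidates``
    (columns feature, context) are user-curated additions appended with
    r2 = NaN and flagged ``curated=True``.
    """
    if query not in panel:
        raise UndefinedLDError(f"query {query} not in panel")
    rows = []
    for rec in catalog.itertuples():
        if not bool(rec.conditionally_independent):
            continue
        same = (normalize_chrom(rec.chrom) == query.chrom
                and int(rec.pos) == query.pos)
        if same:
            r2 = 1.0
        else:
            vk = VariantKey(rec.chrom, int(rec.pos), rec.effect_allele,
                            rec.other_allele, rec.snp)
            if vk not in panel:
                continue
            try:
                r2 = ld_r2(panel, query, vk).r2
            except UndefinedLDError:
                continue
        if r2 >= r2_min:
            rows.append({
                "feature": rec.feature, "context": rec.context,
                "proxy_rsid": rec.snp, "proxy_chrom": normalize_chrom(rec.chrom),
                "proxy_pos": int(rec.pos), "r2": r2, "source_p": rec.p,
                "curated": False,
            })
    out = pd.DataFrame(rows, columns=["feature", "context", "proxy_rsid",
                                      "proxy_chrom", "proxy_pos", "r2",
                                      "source_p", "curated"])
    if not out.empty:
        out = (out.sort_values(["r2", "source_p"], ascending=[False, True],
                               kind="mergesort")
               .drop_duplicates(subset=["feature", "context"], keep="first")
               .reset_index(drop=True))
    if extra_candidates is not None and len(extra_candidates):
        extra = extra_candidates[["feature", "context"]].copy()
        extra["curated"] = True
        out = pd.concat([out, extra], ignore_index=True)
    return out


def genotype_regression(dosage, value) -> tuple[float, float, float, float]:
    """OLS of a molecular measurement on allele dosage.

    Returns (slope, intercept, se_slope, p) with the two-sided p from the
    slope t-statistic on n-2 degrees of freedom — the statistic reported
    for genotype-stratified expression/methylation boxplots.
    """
    dosage = np.asarray(dosage, dtype=float)
    value = np.asarray(value, dtype=float)
    if dosage.shape != value.shape or dosage.size < 3:
        raise ValueError("need >= 3 paired samples")
    if np.unique(dosage).size < 2:
        raise ValueError("degenerate design: constant dosage")
    fit = stats.linregress(dosage, value)
    return float(fit.slope), float(fit.intercept), float(fit.stderr), float(fit.pvalue)


def unpaired_ttest(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sided unpaired t-test between two groups of measurements.

    Equal-variance (Student) by default; ``welch=True`` drops the
    equal-variance assumption.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    if np.isnan(p):  # both groups constant and equal: no evidence against null
        return 0.0, 1.0
    return float(t), float(max(min(p, 1.0), np.nextafter(0, 1)))
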