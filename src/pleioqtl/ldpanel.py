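"""Genotype reference panels: allele frequencies, pairwise LD r², proxy search.

The panel is an (individuals x variants) dosage matrix in {0, 1, 2} with NaN
for missing calls.  r² is the squared Pearson correlation of dosages over
pairwise-complete samples (composite LD on unphased genotypes); at the
threshold bands used downstream (0.50 / 0.80 / 0.90) the distinction from
haplotype-phase r² is immaterial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sumstats import LocusWindow, VariantKey, normalize_chrom

logger = logging.getLogger(__name__)

# LD bands used for proxy/clump decisions downstream
PROXY_R2 = 0.50
STRONG_LD_R2 = 0.80
VERY_STRONG_LD_R2 = 0.90


class UndefinedLDError(ValueError):
    """LD is undefined: a variant is monomorphic or has too few complete pairs."""


@dataclass(frozen=True)
class LDResult:
    variant_a: VariantKey
    variant_b: VariantKey
    r2: float
    n_samples: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 out of [0,1]: {self.r2}")


@dataclass
class GenotypePanel:
    """Sample x variant dosage matrix with variant metadata.

    ``dosages`` is float to allow NaN-coded missing entries; non-missing
    values must be 0, 1 or 2.  ``population`` optionally carries the
    generating model (per-SNP target allele frequencies and latent AR(1)
    correlation) for panels produced by the simulator, so fresh cohorts can
    be drawn from the same population.
    """

    dosages: np.ndarray
    variants: list[VariantKey]
    sample_ids: list[str]
    population: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if m != len(self.variants):
            raise ValueError("variant list does not match dosage columns")
        if n != len(self.sample_ids):
            raise ValueError("sample list does not match dosage rows")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
            raise ValueError("dosages must be in {0,1,2} or NaN")
        self._index = {self._keyid(v): j for j, v in enumerate(self.variants)}

    @staticmethod
    def _keyid(v: VariantKey) -> tuple:
        return (v.chrom, v.pos, frozenset({v.effect_allele, v.other_allele}))

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def index_of(self, v: VariantKey) -> int:
        try:
            return self._index[self._keyid(v)]
        except KeyError:
            raise KeyError(f"variant {v} not in panel") from None

    def __contains__(self, v: VariantKey) -> bool:
        return self._keyid(v) in self._index


def panel_from_vcf(path) -> GenotypePanel:
    """Load a panel from a VCF (plain or bgzipped), converting GT to dosage.

    Multi-allelic records are skipped with a log line; missing genotypes
    become NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, keys, skipped = [], [], 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        gts = np.asarray(rec.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
        dos = np.where(gts == 3, 2.0, gts)
        dos[gts == 2] = np.nan
        cols.append(dos)
        keys.append(VariantKey(rec.CHROM, rec.POS, rec.ALT[0], rec.REF,
                               rec.ID or None))
    if skipped:
        logger.info("panel_from_vcf(%s): skipped %d multi-allelic records", path, skipped)
    if not cols:
        raise ValueError(f"no usable biallelic records in {path}")
    return GenotypePanel(np.column_stack(cols), keys, samples)


def panel_from_tsv(dosage_path, variants_path) -> GenotypePanel:
    """Load a panel from a dosage TSV (rows = samples, first column = sample id)
    plus a sidecar variant table (rsid, chrom, pos, effect_allele, other_allele)."""
    dos = pd.read_csv(dosage_path, sep="\t", index_col=0)
    var = pd.read_csv(variants_path, sep="\t")
    keys = [VariantKey(r.chrom, int(r.pos), r.effect_allele, r.other_allele,
                       None if pd.isna(r.rsid) else r.rsid)
            for r in var.itertuples()]
    return GenotypePanel(dos.to_numpy(dtype=float), keys, [str(s) for s in dos.index])


def write_panel_tsv(panel: GenotypePanel, dosage_path, variants_path) -> None:
    pd.DataFrame(panel.dosages,
                 index=pd.Index(panel.sample_ids, name="sample_id"),
                 columns=[v.rsid or f"{v.chrom}:{v.pos}" for v in panel.variants]
                 ).to_csv(dosage_path, sep="\t", float_format="%g")
    pd.DataFrame({
        "rsid": [v.rsid for v in panel.variants],
        "chrom": [v.chrom for v in panel.variants],
        "pos": [v.pos for v in panel.variants],
        "effect_allele": [v.effect_allele for v in panel.variants],
        "other_allele": [v.other_allele for v in panel.variants],
    }).to_csv(variants_path, sep="\t", index=False)


def allele_freqs(panel: GenotypePanel) -> pd.DataFrame:
    """Per-variant alternate-allele frequency and MAF over non-missing samples.

    Variants that are all-missing get NaN frequency and ``flag='all_missing'``;
    monomorphic variants are flagged ``'monomorphic'``.
    """
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(panel.dosages, axis=0) / 2.0
    n_obs = np.sum(~np.isnan(panel.dosages), axis=0)
    freq = np.where(n_obs == 0, np.nan, freq)
    maf = np.minimum(freq, 1.0 - freq)
    flag = np.where(n_obs == 0, "all_missing",
                    np.where((freq == 0) | (freq == 1), "monomorphic", ""))
    return pd.DataFrame({
        "rsid": [v.rsid for v in panel.variants],
        "chrom": [v.chrom for v in panel.variants],
        "pos": [v.pos for v in panel.variants],
        "freq": freq, "maf": maf, "n_obs": n_obs, "flag": flag,
    })


def ld_r2(panel: GenotypePanel, a: VariantKey, b: VariantKey) -> LDResult:
    """Squared Pearson correlation of dosages over pairwise-complete samples."""
    ia, ib = panel.index_of(a), panel.index_of(b)
    ga, gb = panel.dosages[:, ia], panel.dosages[:, ib]
    ok = ~(np.isnan(ga) | np.isnan(gb))
    n = int(ok.sum())
    if n < 2:
        raise UndefinedLDError(f"fewer than 2 complete sample pairs for {a}, {b}")
    xa, xb = ga[ok], gb[ok]
    va, vb = xa.var(), xb.var()
    if va == 0 or vb == 0:
        raise UndefinedLDError(f"monomorphic variant in complete subset: {a}, {b}")
    cov = np.mean((xa - xa.mean()) * (xb - xb.mean()))
    r2 = float(min(cov * cov / (va * vb), 1.0))
    return LDResult(a, b, r2, n)


def find_proxies(
    panel: GenotypePanel,
    query: VariantKey,
    r2_min: float = PROXY_R2,
    window: Optional[LocusWindow] = None,
) -> list[LDResult]:
    """All panel variants with r² >= ``r2_min`` to ``query``, excluding the
    query itself, sorted by descending r² (ties: genomic distance, then pos).

    ``window`` restricts candidates; by default a 1 Mb window (±500 kb)
    centered on the query is used.
    """
    iq = panel.index_of(query)
    gq = panel.dosages[:, iq]
    if np.nanvar(gq) == 0 or np.all(np.isnan(gq)):
        raise UndefinedLDError(f"query variant {query} is monomorphic in the panel")
    if window is None:
        window = LocusWindow(center=query)
    out = []
    for j, v in enumerate(panel.variants):
        if j == iq or not window.contains(v.chrom, v.pos):
            continue
        try:
            res = ld_r2(panel, query, v)
        except UndefinedLDError:
            continue
        if res.r2 >= r2_min:
            out.append(res)
    out.sort(key=lambda r: (-r.r2, abs(r.variant_b.pos - query.pos), r.variant_b.pos))
    return out


def ld_results_to_tsv(results: Sequence[LDResult], path) -> None:
    pd.DataFrame({
        "rsid_a": [r.variant_a.rsid for r in results],
        "pos_a": [r.variant_a.pos for r in results],
        "rsid_b": [r.variant_b.rsid for r in results],
        "pos_b": [r.variant_b.pos for r in results],
        "r2": [r.r2 for r in results],
        "n_samples": [r.n_samples for r in results],
    }).to_csv(path, sep="\t", index=False, float_format="%.6g")
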