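"""Single-cell filtering, pseudobulk aggregation, normalization, and
negative-binomial Wald differential expression.

Cells below a total-count floor are removed first, then cell-type clusters
that retain fewer than a minimum number of cells are dropped entirely.
Counts are summed within donor x cell type ("pseudobulk"), normalized by
median-of-ratios size factors, and tested per gene and cell type with a
two-group negative-binomial log-linear model:

    log mu_ij = log s_j + beta0 + beta1 * disease_j

Per-gene dispersion comes from a method-of-moments estimate on normalized
counts; beta1 and its standard error come from iteratively reweighted
least squares, the Wald z = beta1/se gets a two-sided normal p, and BH
adjustment is applied within each cell type.  Deliberate simplifications
relative to full DESeq2-style workflows: no dispersion shrinkage across
genes, no fold-change shrinkage, no outlier refitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.io import mmread

from .overlap import bh_adjust

logger = logging.getLogger(__name__)

MIN_CELLS_PER_CLUSTER = 10
MIN_COUNTS_PER_CELL = 500
BULK_MIN_COUNT = 5
DISPERSION_FLOOR = 1e-8

META_COLUMNS = ["barcode", "donor_id", "cell_type", "condition"]


class EmptyResultError(ValueError):
    """All cells/genes were removed by filtering."""


@dataclass
class CellCountsMatrix:
    """Cell x gene integer counts with aligned per-cell metadata.

    ``counts`` may be dense or scipy.sparse; ``cell_meta`` needs columns
    barcode, donor_id, cell_type, condition (condition in
    {'disease', 'control'}).
    """

    counts: "sparse.spmatrix | np.ndarray"
    cell_meta: pd.DataFrame
    gene_ids: list[str]

    def __post_init__(self) -> None:
        n, g = self.counts.shape
        if n != len(self.cell_meta):
            raise ValueError("cell_meta rows must match count rows")
        if g != len(self.gene_ids):
            raise ValueError("gene_ids must match count columns")
        missing = [c for c in META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise ValueError(f"cell_meta missing columns: {missing}")
        bad = set(self.cell_meta["condition"]) - {"disease", "control"}
        if bad:
            raise ValueError(f"unknown conditions: {bad}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def total_counts(self) -> np.ndarray:
        t = self.counts.sum(axis=1)
        return np.asarray(t).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CellCountsMatrix":
        counts = self.counts[mask]
        meta = self.cell_meta.loc[np.asarray(mask)].reset_index(drop=True)
        return CellCountsMatrix(counts, meta, self.gene_ids)


@dataclass
class PseudobulkMatrix:
    """(donor, cell_type) x gene summed counts with group metadata."""

    counts: np.ndarray
    group_meta: pd.DataFrame  # donor_id, cell_type, condition, n_cells
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if self.counts.shape[0] != len(self.group_meta):
            raise ValueError("group_meta rows must match count rows")
        if self.counts.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids must match count columns")


def read_mtx_counts(mtx_path, barcodes_path, genes_path, meta_path) -> CellCountsMatrix:
    """Assemble a CellCountsMatrix from MatrixMarket triplet files plus a
    cell-metadata TSV keyed by barcode.  The MTX is gene x cell (the common
    triplet convention) and is transposed on load."""
    counts = mmread(str(mtx_path)).tocsr().T.tocsr()
    barcodes = pd.read_csv(barcodes_path, header=None)[0].astype(str).tolist()
    genes = pd.read_csv(genes_path, header=None, sep="\t")[0].astype(str).tolist()
    meta = pd.read_csv(meta_path, sep="\t")
    meta = meta.set_index("barcode").loc[barcodes].reset_index()
    return CellCountsMatrix(counts, meta, genes)


def filter_cells_clusters(
    m: CellCountsMatrix,
    min_cells_per_cluster: int = MIN_CELLS_PER_CLUSTER,
    min_counts_per_cell: int = MIN_COUNTS_PER_CELL,
) -> CellCountsMatrix:
    """Drop low-count cells, then entire clusters left with too few cells.

    Cells with total counts below ``min_counts_per_cell`` are removed first;
    the cluster-size threshold then applies to the surviving cells of each
    cell-type cluster (dataset-wide, not per donor).
    """
    totals = m.total_counts()
    keep = totals >= min_counts_per_cell
    n_low = int((~keep).sum())
    if n_low:
        logger.info("filter: removed %d cells below %d counts", n_low,
                    min_counts_per_cell)
    survivors = m.subset_cells(keep)
    if survivors.n_cells == 0:
        raise EmptyResultError("no cells pass the count filter")
    sizes = survivors.cell_meta.groupby("cell_type").size()
    small = set(sizes[sizes < min_cells_per_cluster].index)
    if small:
        logger.info("filter: dropped clusters below %d cells: %s",
                    min_cells_per_cluster, sorted(small))
    keep2 = ~survivors.cell_meta["cell_type"].isin(small).to_numpy()
    out = survivors.subset_cells(keep2)
    if out.n_cells == 0:
        raise EmptyResultError("no clusters pass the size filter")
    return out


def celltype_proportions(m: CellCountsMatrix) -> pd.DataFrame:
    """Per-donor cell-type fractions (rows sum to 1)."""
    if m.n_cells == 0:
        raise EmptyResultError("no cells")
    tab = pd.crosstab(m.cell_meta["donor_id"], m.cell_meta["cell_type"])
    return tab.div(tab.sum(axis=1), axis=0)


def pseudobulk(m: CellCountsMatrix) -> PseudobulkMatrix:
    """Sum counts within each (donor, cell_type) group."""
    meta = m.cell_meta
    groups = meta.groupby(["donor_id", "cell_type"], sort=True)
    rows, grows = [], []
    counts = m.counts.tocsr() if sparse.issparse(m.counts) else np.asarray(m.counts)
    for (donor, ctype), idx in groups.indices.items():
        block = counts[idx]
        s = np.asarray(block.sum(axis=0)).ravel()
        rows.append(s)
        cond = meta.loc[idx, "condition"].iloc[0]
        grows.append({"donor_id": donor, "cell_type": ctype,
                      "condition": cond, "n_cells": len(idx)})
    return PseudobulkMatrix(np.vstack(rows).astype(np.int64),
                            pd.DataFrame(grows), m.gene_ids)


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (samples are rows, genes columns).

    For each gene expressed in every sample, the ratio of each sample's
    count to the gene's geometric mean is formed; a sample's factor is the
    median of its ratios.  When no gene is expressed in all samples, genes
    nonzero in >= 90% of samples are used instead, with geometric means
    taken over their nonzero entries (logged fallback).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    all_nonzero = np.all(counts > 0, axis=0)
    if all_nonzero.any():
        sub = counts[:, all_nonzero]
        log_gm = np.mean(np.log(sub), axis=0)
        ratios = np.log(sub) - log_gm
    else:
        frac = np.mean(counts > 0, axis=0)
        usable = frac >= 0.9
        if not usable.any():
            raise EmptyResultError("no gene expressed widely enough for size factors")
        logger.warning("size_factors: no all-nonzero gene; falling back to genes "
                       "nonzero in >=90%% of samples (%d genes)", int(usable.sum()))
        sub = counts[:, usable]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub), np.nan)
        log_gm = np.nanmean(logs, axis=0)
        ratios = np.where(sub > 0, logs - log_gm, np.nan)
    sf = np.exp(np.nanmedian(ratios, axis=1))
    return sf


def _moment_dispersion(norm_counts: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments dispersion on normalized counts,
    floored at :data:`DISPERSION_FLOOR`."""
    m = norm_counts.mean(axis=0)
    s2 = norm_counts.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - m) / (m ** 2)
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return np.maximum(alpha, DISPERSION_FLOOR)


def _nb_irls(y: np.ndarray, sf: np.ndarray, cond: np.ndarray,
             alpha: np.ndarray, n_iter: int = 50, tol: float = 1e-8):
    """Vectorized two-group NB IRLS across genes.

    ``y`` is samples x genes, ``cond`` a 0/1 vector.  Returns (beta1, se)
    on the natural-log scale.  The design is an intercept plus the disease
    indicator, with log size factors as offsets.
    """
    eps = 1e-8
    n_genes = y.shape[1]
    y0 = y[cond == 0] / sf[cond == 0, None]
    y1 = y[cond == 1] / sf[cond == 1, None]
    mu0 = np.maximum(y0.mean(axis=0), eps)
    mu1 = np.maximum(y1.mean(axis=0), eps)
    b0 = np.log(mu0)
    b1 = np.log(mu1) - np.log(mu0)
    x = cond.astype(float)
    log_sf = np.log(sf)
    for _ in range(n_iter):
        eta = log_sf[:, None] + b0[None, :] + np.outer(x, b1)
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[None, :] * mu)          # samples x genes
        z = eta - log_sf[:, None] + (y - mu) / mu     # working response, offset removed
        # weighted normal equations for [1, x] design, per gene
        sw = w.sum(axis=0)
        swx = (w * x[:, None]).sum(axis=0)
        swxx = swx  # x is 0/1 so x^2 = x
        swz = (w * z).sum(axis=0)
        swxz = (w * x[:, None] * z).sum(axis=0)
        det = sw * swxx - swx ** 2
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        nb0 = (swxx * swz - swx * swxz) / det
        nb1 = (sw * swxz - swx * swz) / det
        shift = max(np.max(np.abs(nb0 - b0)), np.max(np.abs(nb1 - b1)))
        b0, b1 = nb0, nb1
        if shift < tol:
            break
    eta = np.clip(log_sf[:, None] + b0[None, :] + np.outer(x, b1), -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[None, :] * mu)
    sw = w.sum(axis=0)
    swx = (w * x[:, None]).sum(axis=0)
    det = sw * swx - swx ** 2
    det = np.where(np.abs(det) < 1e-12, 1e-12, det)
    se = np.sqrt(np.maximum(sw / det, 0.0))
    return b1, se


def significance_stars(p_adj: float) -> str:
    """Star annotation for adjusted p-values: * <0.05, ** <0.001, *** <0.0001."""
    if p_adj < 0.0001:
        return "***"
    if p_adj < 0.001:
        return "**"
    if p_adj < 0.05:
        return "*"
    return ""


def nb_wald_de(
    pb: PseudobulkMatrix,
    cell_type: str,
    min_donors_per_condition: int = 2,
) -> Optional[pd.DataFrame]:
    """Negative-binomial Wald test of disease vs control within one cell type.

    Returns a DataFrame (gene, cell_type, base_mean, log2fc, se, wald, p,
    p_adj, stars) sorted by p, or ``None`` (with a log line) when either
    condition has fewer than ``min_donors_per_condition`` donors.  Genes
    with all-zero counts in the cell type are excluded.
    """
    mask = (pb.group_meta["cell_type"] == cell_type).to_numpy()
    meta = pb.group_meta.loc[mask]
    counts = pb.counts[mask]
    n_dis = (meta["condition"] == "disease").sum()
    n_con = (meta["condition"] == "control").sum()
    if n_dis < min_donors_per_condition or n_con < min_donors_per_condition:
        logger.info("nb_wald_de: skipping %r (%d disease / %d control donors)",
                    cell_type, n_dis, n_con)
        return None
    expressed = counts.sum(axis=0) > 0
    genes = [g for g, e in zip(pb.gene_ids, expressed) if e]
    y = counts[:, expressed].astype(float)
    sf = size_factors(y)
    norm = y / sf[:, None]
    alpha = _moment_dispersion(norm)
    cond = (meta["condition"] == "disease").to_numpy().astype(int)
    b1, se = _nb_irls(y, sf, cond, alpha)
    wald = b1 / np.where(se > 0, se, np.inf)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    p_adj = bh_adjust(p)
    out = pd.DataFrame({
        "gene": genes,
        "cell_type": cell_type,
        "base_mean": norm.mean(axis=0),
        "log2fc": b1 / np.log(2.0),
        "se": se / np.log(2.0),
        "wald": wald,
        "p": p,
        "p_adj": p_adj,
    })
    out["stars"] = out["p_adj"].map(significance_stars)
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def de_all_celltypes(pb: PseudobulkMatrix) -> pd.DataFrame:
    """Run nb_wald_de for every cell type; skipped types are omitted."""
    frames = []
    for ct in sorted(pb.group_meta["cell_type"].unique()):
        res = nb_wald_de(pb, ct)
        if res is not None:
            frames.append(res)
    if not frames:
        return pd.DataFrame(columns=["gene", "cell_type", "base_mean", "log2fc",
                                     "se", "wald", "p", "p_adj", "stars"])
    return pd.concat(frames, ignore_index=True)


def bulk_normalize(counts: pd.DataFrame, min_count: int = BULK_MIN_COUNT,
                   rule: str = "max") -> pd.DataFrame:
    """Filter weakly counted genes and divide by median-of-ratios factors.

    ``counts`` is gene x sample.  A gene is removed when its max (default)
    or sum across samples is below ``min_count``.  Returns the normalized
    gene x sample matrix.
    """
    agg = counts.max(axis=1) if rule == "max" else counts.sum(axis=1)
    kept = counts.loc[agg >= min_count]
    if kept.empty:
        raise EmptyResultError("no genes pass the count filter")
    sf = size_factors(kept.to_numpy().T)
    return kept / sf[None, :]
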