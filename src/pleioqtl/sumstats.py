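"""Reading, validation, harmonization and windowing of association summary statistics.

A summary-statistics table holds one association record per variant for a
single trait in a single context (a GWAS, the eQTLs of one gene in one
tissue, or the mQTLs of one CpG).  Records may carry a full (beta, se)
pair, a p-value only, or both; downstream code chooses the evidence route
accordingly.  Tables are stored as pandas DataFrames with a fixed logical
schema so that harmonization and windowing are plain column operations.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: logical column order used everywhere downstream
COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "p", "n", "maf",
]

#: p-values are clipped to this floor before any log/quantile transform
P_FLOOR = 1e-300

_PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class SumStatsError(ValueError):
    """Raised for unusable summary-statistics input."""


class ConfigError(KeyError):
    """Raised when a column-name dialect does not cover the required columns."""


@dataclass(frozen=True)
class VariantKey:
    """Genomic identity of a variant: coordinates plus allele pair.

    ``chrom`` is stored without any ``chr`` prefix; ``pos`` is 1-based.
    """

    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    rsid: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect_allele and other_allele must differ")

    @property
    def allele_set(self) -> frozenset:
        return frozenset({self.effect_allele, self.other_allele})

    def is_palindromic(self) -> bool:
        return self.allele_set in _PALINDROMIC


@dataclass(frozen=True)
class LocusWindow:
    """A symmetric window around a center variant; closed on both ends.

    ``half_width`` defaults to 500 kb so the whole window spans 1 Mb.
    """

    center: VariantKey
    half_width: int = 500_000

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")

    def contains(self, chrom: str, pos: int) -> bool:
        return (normalize_chrom(chrom) == self.center.chrom
                and abs(pos - self.center.pos) <= self.half_width)


@dataclass
class SumStatTable:
    """Validated per-variant association records for one trait in one context."""

    df: pd.DataFrame
    trait_type: str = "quantitative"            # or "case-control"
    case_fraction: Optional[float] = None       # required iff case-control
    trait_label: str = ""
    context_label: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case-control"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "case-control":
            if self.case_fraction is None or not (0 < self.case_fraction < 1):
                raise ValueError("case-control tables require case_fraction in (0,1)")
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SumStatsError(f"table missing columns: {missing}")
        dup = self.df.duplicated(subset=["chrom", "pos", "effect_allele", "other_allele"])
        if dup.any():
            raise SumStatsError(f"{int(dup.sum())} duplicate variant keys in table")

    def __len__(self) -> int:
        return len(self.df)

    def keys(self) -> list[VariantKey]:
        return [
            VariantKey(r.chrom, int(r.pos), r.effect_allele, r.other_allele,
                       None if pd.isna(r.rsid) else r.rsid)
            for r in self.df.itertuples()
        ]

    def sorted(self) -> "SumStatTable":
        out = self.df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        return SumStatTable(out, self.trait_type, self.case_fraction,
                            self.trait_label, self.context_label)


def normalize_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


DEFAULT_DIALECT = {c: c for c in COLUMNS}


def _open_text(path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p, "rt")


def read_sumstats(
    path,
    dialect: Optional[Mapping[str, str]] = None,
    *,
    trait_type: str = "quantitative",
    case_fraction: Optional[float] = None,
    trait_label: str = "",
    context_label: str = "",
    sep: Optional[str] = None,
    pos_map: Optional[pd.DataFrame] = None,
) -> SumStatTable:
    """Read a delimited summary-statistics file into a validated table.

    ``dialect`` maps logical column names (:data:`COLUMNS`) to the file's
    headers; unmapped optional columns (beta, se, n, maf, rsid) are filled
    with NA.  Rows failing validation (p outside (0,1], pos < 1, identical
    alleles, no evidence at all) are dropped with a logged count.
    ``pos_map``, if given, is a coordinate-mapping table with columns
    (chrom, old_pos, new_pos) applied at read time; unmapped rows are
    dropped.  Gzip input is detected by the ``.gz`` suffix.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    required = ["chrom", "pos", "effect_allele", "other_allele", "p"]
    import csv as _csv
    try:
        with _open_text(path) as fh:
            raw = pd.read_csv(fh, sep=sep, engine="python")
    except (pd.errors.EmptyDataError, _csv.Error) as exc:
        raise SumStatsError(f"empty or undelimited input file: {path}") from exc
    for col in required:
        if dialect[col] not in raw.columns:
            raise ConfigError(f"required column {col!r} (mapped to {dialect[col]!r}) "
                              f"not found in {path}")
    df = pd.DataFrame(index=raw.index)
    for logical in COLUMNS:
        src = dialect.get(logical, logical)
        df[logical] = raw[src] if src in raw.columns else np.nan

    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    for col in ("beta", "se", "p", "maf"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()

    if pos_map is not None:
        df = _apply_pos_map(df, pos_map)

    n0 = len(df)
    ok = (
        df["pos"].notna() & (df["pos"] >= 1)
        & (df["effect_allele"] != df["other_allele"])
        & df["chrom"].astype(bool)
    )
    has_p = df["p"].notna() & (df["p"] > 0) & (df["p"] <= 1)
    has_beta_se = df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
    ok &= has_p | has_beta_se
    bad_maf = df["maf"].notna() & ~((df["maf"] > 0) & (df["maf"] <= 0.5))
    df.loc[bad_maf, "maf"] = np.nan
    dropped = n0 - int(ok.sum())
    if dropped:
        logger.info("read_sumstats(%s): dropped %d/%d invalid rows", path, dropped, n0)
    df = df[ok].copy()
    if df.empty:
        raise SumStatsError(f"no valid rows in {path}")
    df["pos"] = df["pos"].astype(np.int64)
    df["p"] = df["p"].clip(lower=P_FLOOR)
    df = df.drop_duplicates(
        subset=["chrom", "pos", "effect_allele", "other_allele"]).reset_index(drop=True)
    return SumStatTable(df, trait_type, case_fraction, trait_label, context_label).sorted()


def _apply_pos_map(df: pd.DataFrame, pos_map: pd.DataFrame) -> pd.DataFrame:
    pm = pos_map.copy()
    pm["chrom"] = pm["chrom"].map(normalize_chrom)
    merged = df.merge(pm, left_on=["chrom", "pos"], right_on=["chrom", "old_pos"],
                      how="left")
    unmapped = merged["new_pos"].isna()
    if unmapped.any():
        logger.info("coordinate map: dropped %d unmapped rows", int(unmapped.sum()))
    merged = merged[~unmapped].copy()
    merged["pos"] = merged["new_pos"].astype(np.int64)
    return merged.drop(columns=["old_pos", "new_pos"])


def write_sumstats(table: SumStatTable, path) -> None:
    """Write a table as TSV with the fixed column order, floats at 6 sig digits."""
    table.df[COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def table_from_records(records: Iterable[dict], **kwargs) -> SumStatTable:
    """Build a table from an iterable of dicts keyed by logical column names."""
    df = pd.DataFrame(list(records))
    for c in COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df["pos"] = df["pos"].astype(np.int64)
    return SumStatTable(df[COLUMNS].copy(), **kwargs).sorted()


def harmonize_pair(a: SumStatTable, b: SumStatTable) -> pd.DataFrame:
    """Align two tables on shared variants with matched effect alleles.

    Variants are matched on (chrom, pos) and on the allele *set*; when the
    effect/other alleles are swapped between the tables, b's beta sign is
    flipped so both effects refer to the same allele.  Variants whose allele
    sets differ are dropped with a log line; palindromic (A/T, C/G) variants
    are retained but logged because strand orientation cannot be verified
    from alleles alone.  Returns a DataFrame with ``_a``/``_b`` suffixed
    statistic columns; empty if there is no overlap (not an error).
    """
    m = a.df.merge(b.df, on=["chrom", "pos"], suffixes=("_a", "_b"))
    if m.empty:
        logger.info("harmonize_pair: zero shared variants")
        return _empty_pair()

    same = ((m["effect_allele_a"] == m["effect_allele_b"])
            & (m["other_allele_a"] == m["other_allele_b"]))
    swapped = ((m["effect_allele_a"] == m["other_allele_b"])
               & (m["other_allele_a"] == m["effect_allele_b"]))
    mismatched = ~(same | swapped)
    if mismatched.any():
        logger.info("harmonize_pair: dropped %d allele-set mismatches",
                    int(mismatched.sum()))
    m = m[~mismatched].copy()
    flip = swapped[~mismatched]
    m.loc[flip, "beta_b"] = -m.loc[flip, "beta_b"]
    m.loc[flip, ["effect_allele_b", "other_allele_b"]] = (
        m.loc[flip, ["other_allele_b", "effect_allele_b"]].values)

    pal = [frozenset({ea, oa}) in _PALINDROMIC
           for ea, oa in zip(m["effect_allele_a"], m["other_allele_a"])]
    m["palindromic"] = pal
    if any(pal):
        logger.warning("harmonize_pair: %d palindromic variants retained "
                       "(strand unverifiable)", int(np.sum(pal)))
    keep = (["chrom", "pos", "rsid_a", "effect_allele_a", "other_allele_a",
             "beta_a", "se_a", "p_a", "n_a", "maf_a",
             "beta_b", "se_b", "p_b", "n_b", "maf_b", "palindromic"])
    out = m[keep].rename(columns={"rsid_a": "rsid",
                                  "effect_allele_a": "effect_allele",
                                  "other_allele_a": "other_allele"})
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _empty_pair() -> pd.DataFrame:
    cols = (["chrom", "pos", "rsid", "effect_allele", "other_allele",
             "beta_a", "se_a", "p_a", "n_a", "maf_a",
             "beta_b", "se_b", "p_b", "n_b", "maf_b", "palindromic"])
    return pd.DataFrame(columns=cols)


def extract_window(table: SumStatTable, window: LocusWindow) -> SumStatTable:
    """Restrict a table to the closed interval ``center.pos ± half_width``."""
    df = table.df
    mask = ((df["chrom"] == window.center.chrom)
            & ((df["pos"] - window.center.pos).abs() <= window.half_width))
    out = df[mask].sort_values("pos", kind="mergesort").reset_index(drop=True)
    return SumStatTable(out, table.trait_type, table.case_fraction,
                        table.trait_label, table.context_label)
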