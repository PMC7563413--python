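"""Genomic-interval plumbing for the multi-omic integration stage.

Coordinates are 0-based half-open throughout (BED semantics). CpG tables
carry one row per site with per-sample methylation fractions and read
coverage; gene models are strand-aware, with the TSS at ``start`` on '+'
and ``end - 1`` on '-'. Promoter methylation is the coverage-weighted mean
fraction over CpGs within a window of the TSS. Peaks and CNVs link to a
gene when they overlap its 1000 bp-extended region by at least one base.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from intervaltree import IntervalTree

CPG_KEY_COLS = ["chrom", "pos"]
DELETION, AMPLIFICATION = "deletion", "amplification"


def tss(genes: pd.DataFrame) -> pd.Series:
    """Strand-aware transcription start site of each gene model."""
    for col in ("chrom", "start", "end", "strand"):
        if col not in genes.columns:
            raise ValueError(f"gene table needs column {col!r}")
    if not genes["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    if not (genes["start"] < genes["end"]).all():
        raise ValueError("gene start must be < end")
    return pd.Series(
        np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1),
        index=genes.index, name="tss")


def filter_cpgs(cpgs: pd.DataFrame, min_coverage: int = 10,
                coverage_rule: str = "all") -> pd.DataFrame:
    """Drop uninformative or poorly covered CpG sites.

    Removes sites unmethylated in every sample, fully methylated in every
    sample, or with coverage below ``min_coverage`` (strict <) in any
    sample (``coverage_rule='all'`` requires all samples to reach the
    floor; 'any' keeps a site if at least one sample does).
    """
    frac_cols = [c for c in cpgs.columns if c.startswith("frac_")]
    cov_cols = [c for c in cpgs.columns if c.startswith("cov_")]
    if not frac_cols or len(frac_cols) != len(cov_cols):
        raise ValueError("CpG table needs matching frac_*/cov_* columns")
    frac = cpgs[frac_cols].to_numpy(dtype=float)
    cov = cpgs[cov_cols].to_numpy(dtype=float)
    none_meth = (frac == 0).all(axis=1)
    all_meth = (frac == 1).all(axis=1)
    if coverage_rule == "all":
        cov_ok = (cov >= min_coverage).all(axis=1)
    elif coverage_rule == "any":
        cov_ok = (cov >= min_coverage).any(axis=1)
    else:
        raise ValueError(f"unknown coverage_rule {coverage_rule!r}")
    keep = ~none_meth & ~all_meth & cov_ok
    return cpgs[keep].reset_index(drop=True)


def promoter_methylation(cpgs: pd.DataFrame, genes: pd.DataFrame,
                         window: int = 1000) -> pd.DataFrame:
    """Coverage-weighted promoter methylation per gene and sample.

    Uses CpGs with position in [TSS - window, TSS + window] (inclusive both
    ends) on the gene's chromosome: level = sum(cov * frac) / sum(cov).
    Genes with no CpG in the window get NaN.
    """
    frac_cols = [c for c in cpgs.columns if c.startswith("frac_")]
    samples = [c[len("frac_"):] for c in frac_cols]
    sites = tss(genes)
    out = pd.DataFrame(np.nan, index=genes["name"], columns=samples)
    by_chrom = dict(tuple(cpgs.groupby("chrom", sort=False)))
    for (_, g), t in zip(genes.iterrows(), sites):
        chrom_cpgs = by_chrom.get(g["chrom"])
        if chrom_cpgs is None:
            continue
        sel = chrom_cpgs[(chrom_cpgs["pos"] >= t - window)
                         & (chrom_cpgs["pos"] <= t + window)]
        if sel.empty:
            continue
        for s in samples:
            cov = sel[f"cov_{s}"].to_numpy(dtype=float)
            frac = sel[f"frac_{s}"].to_numpy(dtype=float)
            if cov.sum() > 0:
                out.loc[g["name"], s] = float((cov * frac).sum() / cov.sum())
    return out


def link_intervals_to_genes(intervals: pd.DataFrame, genes: pd.DataFrame,
                            extension: int = 1000,
                            containment: bool = False) -> pd.DataFrame:
    """(interval, gene) pairs where the interval overlaps the extended gene.

    Gene regions are extended by ``extension`` bp both ways (start clamped
    at 0); overlap means >= 1 shared base under half-open coordinates.
    ``containment=True`` requires the interval to lie entirely inside the
    extended region. An interval may link to several genes.
    """
    trees: Dict[str, IntervalTree] = {}
    for i, g in genes.iterrows():
        lo = max(int(g["start"]) - extension, 0)
        hi = int(g["end"]) + extension
        trees.setdefault(g["chrom"], IntervalTree()).addi(lo, hi, i)
    rows = []
    for j, iv in intervals.iterrows():
        tree = trees.get(iv["chrom"])
        if tree is None:
            continue
        for hit in sorted(tree.overlap(int(iv["start"]), int(iv["end"])),
                          key=lambda h: h.data):
            if containment and not (hit.begin <= iv["start"]
                                    and iv["end"] <= hit.end):
                continue
            rows.append(dict(interval_index=j,
                             interval_name=iv.get("name", str(j)),
                             gene=genes.loc[hit.data, "name"]))
    return pd.DataFrame(rows, columns=["interval_index", "interval_name",
                                       "gene"])


def filter_peaks(peak_stats: pd.DataFrame, fdr_max: float = 0.05,
                 min_abs_log2fc: float = 1.0) -> pd.DataFrame:
    """Differential-peak filter applied to a supplied stats table."""
    for col in ("fdr", "log2fc"):
        if col not in peak_stats.columns:
            raise ValueError(f"peak stats need column {col!r}")
    keep = (peak_stats["fdr"] < fdr_max) \
        & (peak_stats["log2fc"].abs() > min_abs_log2fc)
    return peak_stats[keep].reset_index(drop=True)


def filter_cnvs(cnvs: pd.DataFrame, min_length: int = 1000,
                max_q0: float = 0.15) -> pd.DataFrame:
    """Keep CNV calls with length strictly > min_length and q0 strictly <
    max_q0."""
    length = cnvs["end"] - cnvs["start"]
    keep = (length > min_length) & (cnvs["q0"] < max_q0)
    return cnvs[keep].reset_index(drop=True)


def modality_overlap(gene_lists: Dict[str, Iterable[str]]) -> pd.DataFrame:
    """Venn-cell counts for up to four gene lists.

    One row per non-empty combination of modalities (exclusive regions):
    the count of genes in exactly that combination. Rows ordered by
    combination size then modality order.
    """
    names = list(gene_lists)
    if not 1 <= len(names) <= 4:
        raise ValueError("needs 1-4 gene lists")
    sets = {k: set(v) for k, v in gene_lists.items()}
    rows = []
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            inside = set.intersection(*(sets[k] for k in combo))
            outside = set.union(set(), *(sets[k] for k in names
                                         if k not in combo))
            rows.append(dict(region="&".join(combo),
                             n=len(inside - outside)))
    return pd.DataFrame(rows)


def delta_correlation(delta_expression: pd.Series, delta_omics: pd.Series,
                      significant: Sequence[str] | None = None
                      ) -> Dict[str, float]:
    """Spearman correlation of per-gene expression deltas with omics deltas.

    Missing values are pairwise-deleted; ``significant`` restricts to a
    gene subset. Returns r, p and n, plus the mean of each delta.
    """
    df = pd.concat([delta_expression.rename("expr"),
                    delta_omics.rename("omics")], axis=1).dropna()
    if significant is not None:
        df = df.loc[df.index.intersection(pd.Index(significant))]
    if len(df) < 3:
        raise ValueError(f"only {len(df)} complete gene pairs (need >= 3)")
    r, p = st.spearmanr(df["expr"], df["omics"])
    return dict(r=float(r), p=float(p), n=int(len(df)),
                mean_delta_expression=float(df["expr"].mean()),
                mean_delta_omics=float(df["omics"].mean()))
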