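"""Resistance-signature construction and drug-response validation.

The signature is the top-k markers (default 18) from the FDR-ordered
marker table. A sample's signature score is the unweighted mean of the
signature genes' log-scale expression. Validation correlates the score
with log(IC50) of a drug across cell-line panels (Spearman, per tissue or
subtype, dropping groups below 10 lines) and ranks the signature's
correlation against every individual gene's.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

logger = logging.getLogger(__name__)


@dataclass
class Signature:
    """Ordered resistance-marker genes; order is selection rank."""

    genes: List[str]
    source: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class DrugPanel:
    """Cell-line drug-response panel with matched expression.

    ``response``: long table with columns line, tissue, drug, log_ic50
    (optional subtype column); ``expression``: genes x lines, log scale.
    """

    response: pd.DataFrame
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"line", "tissue", "drug", "log_ic50"}
        if not required.issubset(self.response.columns):
            raise ValueError(f"response table needs columns {sorted(required)}")
        unknown = set(self.response["line"]) - set(self.expression.columns)
        if unknown:
            raise ValueError(f"response lines missing from expression: "
                             f"{sorted(unknown)[:5]}")


def build_signature(markers: pd.DataFrame, k: int = 18) -> Signature:
    """Top-k rows of the ordered marker table (column 'gene')."""
    if "gene" not in markers.columns:
        raise ValueError("marker table needs a 'gene' column")
    if len(markers) < k:
        raise ValueError(
            f"only {len(markers)} markers available; pass k <= {len(markers)}")
    return Signature(genes=markers["gene"].head(k).tolist(),
                     source=f"top {k} of {len(markers)} markers")


def signature_score(expression: pd.DataFrame, sig: Signature) -> pd.Series:
    """Mean signature-gene expression per sample (column of ``expression``)."""
    present = [g for g in sig.genes if g in expression.index]
    if not present:
        raise ValueError("no signature gene present in the expression table")
    if len(present) < len(sig.genes):
        warnings.warn(f"{len(sig.genes) - len(present)} signature genes "
                      f"absent from expression and dropped", stacklevel=2)
    return expression.loc[present].mean(axis=0).rename("signature_score")


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman r with average ranks; exact permutation p below n=10."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    r, p_t = st.spearmanr(x, y)
    if n >= 10:
        return float(r), float(p_t)
    # exact two-sided permutation distribution of r over all y orderings
    rx = st.rankdata(x)
    ry = st.rankdata(y)
    perms = np.array(list(itertools.permutations(range(n))))
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    norm = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    rs = (ry_c[perms] @ rx_c) / norm
    p = float(np.mean(np.abs(rs) >= abs(r) - 1e-12))
    return float(r), p


def correlate_response(panel: DrugPanel, sig: Signature, drug: str,
                       group_by: str | None = "tissue",
                       min_group: int = 10) -> pd.DataFrame:
    """Per-group Spearman correlation of signature score with log(IC50).

    Groups (tissues or subtypes) with fewer than ``min_group`` cell lines
    carrying a response for ``drug`` are dropped. ``group_by=None`` pools
    all lines. Missing responses are pairwise-deleted.
    """
    resp = panel.response[panel.response["drug"] == drug].dropna(
        subset=["log_ic50"])
    if resp.empty:
        raise ValueError(f"drug {drug!r} not present in panel")
    scores = signature_score(panel.expression, sig)
    resp = resp[resp["line"].isin(scores.index)]
    if group_by is None:
        groups = [("all", resp)]
    else:
        if group_by not in resp.columns:
            raise ValueError(f"no column {group_by!r} in response table")
        groups = list(resp.groupby(group_by, sort=True))
    rows = []
    for name, g in groups:
        if len(g) < min_group:
            logger.info("group %s dropped (%d < %d lines)",
                        name, len(g), min_group)
            continue
        r, p = spearman(scores[g["line"]].to_numpy(),
                        g["log_ic50"].to_numpy())
        rows.append(dict(group=name, r=r, p=p, n=len(g)))
    if not rows:
        raise ValueError("no group reaches the minimum size")
    return pd.DataFrame(rows)


def percentile_vs_genes(panel: DrugPanel, sig: Signature, drug: str,
                        min_genes: int = 100) -> float:
    """Fraction of individual genes whose Spearman r with log(IC50) lies
    strictly below the signature's (signed comparison), as a percentage."""
    if panel.expression.shape[0] < min_genes:
        raise ValueError(f"need >= {min_genes} genes in the expression table")
    resp = panel.response[panel.response["drug"] == drug].dropna(
        subset=["log_ic50"])
    if resp.empty:
        raise ValueError(f"drug {drug!r} not present in panel")
    resp = resp[resp["line"].isin(panel.expression.columns)]
    y = resp["log_ic50"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant response; correlations undefined")
    expr = panel.expression[resp["line"]].to_numpy(dtype=float)
    # vectorized Spearman: Pearson on row-wise ranks
    ry = st.rankdata(y)
    rexpr = st.rankdata(expr, axis=1)
    ry_c = ry - ry.mean()
    rx_c = rexpr - rexpr.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c ** 2).sum(axis=1) * (ry_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        gene_r = np.where(denom > 0, rx_c @ ry_c / denom, 0.0)
    sig_r, _ = spearman(signature_score(panel.expression, sig)[resp["line"]]
                        .to_numpy(), y)
    return float(100.0 * np.mean(gene_r < sig_r))


@dataclass
class SignatureValidation:
    """Bundle of the validation outputs for one drug."""

    drug: str
    correlations: pd.DataFrame
    percentile: float
    signature: Signature = field(repr=False)

    def summary(self) -> pd.DataFrame:
        out = self.correlations.copy()
        out["percentile_vs_genes"] = self.percentile
        return out
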