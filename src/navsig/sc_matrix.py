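"""Count-matrix containers, QC filtering, normalization and gJSD.

The QC rules are the strict thresholds used throughout: keep cells with
total counts > 1000 and mitochondrial fraction < 10%, then genes detected
in > 10 of the surviving cells. Normalization is the count-per-ten-thousand
log transform ln(count / cell_total * 1e4 + 1), i.e. log(CPM/100 + 1) in
natural log. Profile similarity between cells is measured with the
generalized Jensen-Shannon divergence in bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

MITO_PREFIX = "MT-"


@dataclass
class CountMatrix:
    """Cells x genes integer counts (sparse), with ordered unique labels."""

    cells: List[str]
    genes: List[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_cells, n_genes = self.counts.shape
        if len(self.cells) != n_cells or len(self.genes) != n_genes:
            raise ValueError("label lengths do not match matrix shape")
        if len(set(self.cells)) != n_cells:
            raise ValueError("duplicate cell identifiers")
        if len(set(self.genes)) != n_genes:
            raise ValueError("duplicate gene identifiers")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def shape(self):
        return self.counts.shape

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def mito_fraction(self, prefix: str = MITO_PREFIX) -> np.ndarray:
        """Per-cell fraction of counts on mitochondrial (name-prefixed) genes."""
        mito = np.array([g.startswith(prefix) for g in self.genes])
        totals = self.cell_totals().astype(float)
        if not mito.any():
            return np.zeros(len(self.cells))
        mito_counts = np.asarray(self.counts[:, mito].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito_counts / totals, 0.0)
        return frac

    def subset(self, cell_mask: np.ndarray | None = None,
               gene_mask: np.ndarray | None = None) -> "CountMatrix":
        cm = self.counts
        cells, genes = self.cells, self.genes
        if cell_mask is not None:
            cm = cm[cell_mask]
            cells = [c for c, k in zip(cells, cell_mask) if k]
        if gene_mask is not None:
            cm = cm[:, gene_mask]
            genes = [g for g, k in zip(genes, gene_mask) if k]
        return CountMatrix(cells=cells, genes=genes, counts=sp.csr_matrix(cm))


@dataclass
class NormalizedMatrix:
    """ln(CPM/100 + 1) values on the same axes as the source counts."""

    cells: List[str]
    genes: List[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cells), len(self.genes)):
            raise ValueError("value shape does not match labels")

    @property
    def shape(self):
        return self.values.shape


def qc_filter(counts: CountMatrix, min_transcripts: int = 1000,
              max_mito_frac: float = 0.10, min_cells_per_gene: int = 10,
              mito_prefix: str = MITO_PREFIX) -> CountMatrix:
    """Apply the cell and gene quality filters, cells first.

    Cells survive with total counts strictly greater than ``min_transcripts``
    and mitochondrial fraction strictly below ``max_mito_frac``; genes then
    survive with non-zero counts in strictly more than ``min_cells_per_gene``
    of the surviving cells.
    """
    totals = counts.cell_totals()
    mito = counts.mito_fraction(mito_prefix)
    cell_keep = (totals > min_transcripts) & (mito < max_mito_frac)
    n_cells_kept = int(cell_keep.sum())
    if n_cells_kept == 0:
        raise ValueError(
            f"QC removed every cell: {int((totals > min_transcripts).sum())}"
            f"/{len(totals)} pass the transcript filter, "
            f"{int((mito < max_mito_frac).sum())}/{len(totals)} the mito filter")
    sub = counts.subset(cell_mask=cell_keep)
    detected = np.asarray((sub.counts > 0).sum(axis=0)).ravel()
    gene_keep = detected > min_cells_per_gene
    if not gene_keep.any():
        raise ValueError(
            f"QC removed every gene: {n_cells_kept} cells survived but no "
            f"gene is detected in more than {min_cells_per_gene} of them")
    out = sub.subset(gene_mask=gene_keep)
    logger.info("qc_filter: cells %d -> %d, genes %d -> %d",
                len(counts.cells), len(out.cells),
                len(counts.genes), len(out.genes))
    return out


def normalize_log_cpm(counts: CountMatrix) -> NormalizedMatrix:
    """ln(count / cell_total * 1e4 + 1) per entry."""
    totals = counts.cell_totals().astype(float)
    if (totals <= 0).any():
        bad = [c for c, t in zip(counts.cells, totals) if t <= 0]
        raise ValueError(f"cells with zero total counts (run QC first): {bad[:5]}")
    dense = np.asarray(counts.counts.todense(), dtype=float)
    values = np.log1p(dense / totals[:, None] * 1e4)
    return NormalizedMatrix(cells=list(counts.cells), genes=list(counts.genes),
                            values=values)


def _entropy_bits(p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shannon entropy in bits with the 0*log0 = 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log2(p), 0.0)
    return -t.sum(axis=axis)


def generalized_jsd(norm: NormalizedMatrix,
                    cell_subset: Sequence[str] | np.ndarray | None = None,
                    use_raw: bool = False,
                    raw_counts: CountMatrix | None = None) -> float:
    """Generalized Jensen-Shannon divergence over a set of cells, in bits.

    Each cell's expression vector is renormalized to a probability
    distribution; gJSD = H(equal-weight mixture) - mean(H(cell)). By default
    probabilities come from the normalized values; ``use_raw`` switches to
    raw counts (``raw_counts`` must then be given).
    """
    if use_raw:
        if raw_counts is None:
            raise ValueError("use_raw requires raw_counts")
        mat = np.asarray(raw_counts.counts.todense(), dtype=float)
        cells = raw_counts.cells
    else:
        mat = norm.values
        cells = norm.cells
    if cell_subset is not None:
        idx = [cells.index(c) for c in cell_subset]
        mat = mat[idx]
    if mat.shape[0] < 2:
        raise ValueError("gJSD needs at least 2 cells")
    totals = mat.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("cell with non-positive total in gJSD subset")
    p = mat / totals[:, None]
    mix = p.mean(axis=0)
    return float(_entropy_bits(mix) - _entropy_bits(p, axis=1).mean())
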