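"""Readers and writers for the plain-text formats the pipeline speaks.

Counts travel as MatrixMarket triplets with genes.tsv/barcodes.tsv side
files (genes as matrix rows, the common droplet convention) or as dense
TSV; gene sets as GMT; genomic intervals as BED-like TSV with 0-based
half-open coordinates; everything tabular as CSV/TSV through pandas.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING, Dict, List

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

if TYPE_CHECKING:  # pragma: no cover
    from .sc_matrix import CountMatrix


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path: str | os.PathLike) -> Dict[str, List[str]]:
    """Read a GMT file into ``{set_name: [gene, ...]}``.

    Column 2 (the description) is discarded; empty trailing fields are
    ignored.
    """
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, genes = fields[0], [g for g in fields[2:] if g]
            sets[name] = genes
    return sets


def write_gmt(sets: Dict[str, List[str]], path: str | os.PathLike,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# count matrices

def write_mtx_dir(counts: "CountMatrix", outdir: str | os.PathLike) -> None:
    """Write a count matrix as matrix.mtx + genes.tsv + barcodes.tsv.

    The .mtx holds genes x cells (rows = genes), matching the layout
    droplet pipelines emit.
    """
    os.makedirs(outdir, exist_ok=True)
    mat = sp.csr_matrix(counts.counts).T.astype(np.int64)
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), mat)
    pd.Series(counts.genes).to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False, header=False)
    pd.Series(counts.cells).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False, header=False)


def read_mtx_dir(indir: str | os.PathLike) -> "CountMatrix":
    from .sc_matrix import CountMatrix

    mat = scipy.io.mmread(os.path.join(indir, "matrix.mtx")).tocsr().T
    genes = pd.read_csv(os.path.join(indir, "genes.tsv"),
                        sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(os.path.join(indir, "barcodes.tsv"),
                        sep="\t", header=None)[0].astype(str).tolist()
    return CountMatrix(cells=cells, genes=genes,
                       counts=sp.csr_matrix(mat, dtype=np.int64))


def write_dense_tsv(counts: "CountMatrix", path: str | os.PathLike) -> None:
    """Dense TSV alternative: rows = cells, columns = genes."""
    df = pd.DataFrame(np.asarray(counts.counts.todense()),
                      index=counts.cells, columns=counts.genes)
    df.to_csv(path, sep="\t")


def read_dense_tsv(path: str | os.PathLike) -> "CountMatrix":
    from .sc_matrix import CountMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(cells=df.index.astype(str).tolist(),
                       genes=df.columns.astype(str).tolist(),
                       counts=sp.csr_matrix(df.to_numpy(dtype=np.int64)))


# ---------------------------------------------------------------------------
# BED-like intervals

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | os.PathLike, extra_columns: List[str] | None = None
             ) -> pd.DataFrame:
    """Read a BED-like TSV (no header). 0-based half-open.

    ``extra_columns`` names columns beyond the canonical six.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = BED_COLUMNS[: min(df.shape[1], 6)]
    if extra_columns:
        cols = cols + list(extra_columns[: df.shape[1] - len(cols)])
    df.columns = cols + [f"col{i}" for i in range(len(cols), df.shape[1])]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
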