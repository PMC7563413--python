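"""Binned-control module scoring, cell-cycle phases, resistance classes.

A cell's module score for a gene set is the mean normalized expression of
the set genes minus the mean over expression-matched control genes: genes
are placed into equal-frequency bins by their mean expression across cells
and each set gene contributes ``n_ctrl`` control genes drawn from its bin.
The same score drives cell-cycle phase calls (argmax over the five phase
sets, G0 when no score is positive) and the resistant / sensitive / other
classification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .sc_matrix import NormalizedMatrix

logger = logging.getLogger(__name__)

PHASE_ORDER = ["G1/S", "S", "G2", "G2/M", "M/G1"]
RESISTANT, SENSITIVE, OTHER = "resistant", "sensitive", "other"


@dataclass
class GeneSet:
    name: str
    genes: List[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicates")


@dataclass
class CellScores:
    """Per-cell scores for one gene set, with draw provenance."""

    set_name: str
    cells: List[str]
    scores: np.ndarray
    seed: int | None = None
    n_bins: int = 24
    control_genes: List[str] = field(default_factory=list, repr=False)

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.cells, name=self.set_name)


def _expression_bins(mean_expr: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per gene; ties broken by stable gene order."""
    order = np.argsort(mean_expr, kind="stable")
    n = len(mean_expr)
    bins = np.empty(n, dtype=int)
    # np.array_split gives near-equal chunk sizes deterministically
    for b, chunk in enumerate(np.array_split(order, min(n_bins, n))):
        bins[chunk] = b
    return bins


def module_score(norm: NormalizedMatrix, gene_set: GeneSet, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int | None = 0) -> CellScores:
    """Score each cell for one gene set against binned control genes.

    For every set gene, ``n_ctrl`` control genes are drawn uniformly without
    replacement from the non-set genes of its expression bin; when the bin
    holds at most ``n_ctrl`` candidates the whole bin is used, so the score
    is then independent of the draw seed. The score is the mean expression
    over set genes minus the mean over the pooled control draws.
    """
    gene_index = {g: i for i, g in enumerate(norm.genes)}
    present = [g for g in gene_set.genes if g in gene_index]
    missing = [g for g in gene_set.genes if g not in gene_index]
    if not present:
        raise ValueError(
            f"no gene of set {gene_set.name!r} found in the matrix; "
            f"missing: {missing[:10]}")
    if missing:
        warnings.warn(f"set {gene_set.name!r}: {len(missing)} genes absent "
                      f"from the matrix and dropped", stacklevel=2)
    mean_expr = norm.values.mean(axis=0)
    bins = _expression_bins(mean_expr, n_bins)
    set_idx = np.array([gene_index[g] for g in present])
    in_set = np.zeros(len(norm.genes), dtype=bool)
    in_set[set_idx] = True

    rng = np.random.default_rng(seed)
    ctrl_draws: List[np.ndarray] = []
    for gi in set_idx:
        pool = np.where((bins == bins[gi]) & ~in_set)[0]
        if len(pool) == 0:
            continue
        if len(pool) <= n_ctrl:
            ctrl_draws.append(pool)
        else:
            ctrl_draws.append(rng.choice(pool, size=n_ctrl, replace=False))
    if not ctrl_draws:
        raise ValueError("no control genes available in any bin")
    ctrl_idx = np.concatenate(ctrl_draws)
    scores = norm.values[:, set_idx].mean(axis=1) \
        - norm.values[:, ctrl_idx].mean(axis=1)
    return CellScores(set_name=gene_set.name, cells=list(norm.cells),
                      scores=scores, seed=seed, n_bins=n_bins,
                      control_genes=[norm.genes[i] for i in ctrl_idx])


def score_sets(norm: NormalizedMatrix, sets: Sequence[GeneSet],
               n_bins: int = 24, n_ctrl: int = 100,
               seed: int | None = 0) -> pd.DataFrame:
    """Score several gene sets; one column per set, rows = cells.

    Each set gets a deterministic child seed so single-set and batch calls
    agree.
    """
    cols = {}
    for k, gs in enumerate(sets):
        child = None if seed is None else int(
            np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        cols[gs.name] = module_score(norm, gs, n_bins, n_ctrl, child).scores
    return pd.DataFrame(cols, index=list(norm.cells))


def assign_cell_cycle(phase_scores: pd.DataFrame) -> pd.Series:
    """Phase per cell: argmax of the five phase scores if positive, else G0.

    Ties among positive maxima break by the fixed order G1/S, S, G2, G2/M,
    M/G1.
    """
    missing = [p for p in PHASE_ORDER if p not in phase_scores.columns]
    if missing:
        raise ValueError(f"missing phase score columns: {missing}")
    mat = phase_scores[PHASE_ORDER].to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError("NaN phase score")
    best = mat.argmax(axis=1)  # argmax returns the first maximum -> tie order
    phase = np.where(mat[np.arange(len(mat)), best] > 0,
                     np.array(PHASE_ORDER, dtype=object)[best], "G0")
    return pd.Series(phase, index=phase_scores.index, name="phase")


def classify_resistance(target_score: np.ndarray | pd.Series,
                        resistance_score: np.ndarray | pd.Series) -> np.ndarray:
    """Resistant / sensitive / other from the two module scores.

    resistant: resistance score positive and greater than the target score;
    sensitive: target score positive and greater than the resistance score;
    everything else (both negative, ties, zeros) falls into 'other'.
    """
    t = np.asarray(target_score, dtype=float)
    r = np.asarray(resistance_score, dtype=float)
    if np.isnan(t).any() or np.isnan(r).any():
        raise ValueError("scores must be finite")
    out = np.full(t.shape, OTHER, dtype=object)
    out[(r > 0) & (r > t)] = RESISTANT
    out[(t > 0) & (t > r)] = SENSITIVE
    return out


def balanced_accuracy_resistant(truth: Sequence[str],
                                predicted: Sequence[str]) -> float:
    """Balanced accuracy of recovering resistant cells (resistant vs rest)."""
    t = np.asarray(truth) == RESISTANT
    p = np.asarray(predicted) == RESISTANT
    sens = (t & p).sum() / max(t.sum(), 1)
    spec = (~t & ~p).sum() / max((~t).sum(), 1)
    return float((sens + spec) / 2)


def sets_from_gmt(gmt: Dict[str, List[str]]) -> List[GeneSet]:
    return [GeneSet(name=k, genes=v) for k, v in gmt.items()]
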