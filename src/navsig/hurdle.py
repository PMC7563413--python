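"""Two-part (hurdle) differential expression for zero-inflated expression.

Each gene is tested between a focal group of cells (here: resistant) and
the rest with two likelihood-ratio tests that are summed:

* a discrete part — a logistic model of detection (expression > 0) on the
  group indicator; with one binary covariate its LRT has the closed form of
  the G-test on the 2x2 detection table;
* a continuous part — a Gaussian model of normalized expression among the
  detected cells, whose group-effect LRT is n * ln(RSS0 / RSS1).

The combined statistic is the sum of the two chi-squares with summed
degrees of freedom. A degenerate component (all cells detected, or too few
detected cells for the continuous fit) drops out and the remaining one is
used alone. Complete separation in detection (a group detected in 0% or
100% of its cells) replaces the discrete LRT with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests


@dataclass
class HurdleResults:
    """Per-gene hurdle-test table plus the settings that produced it."""

    table: pd.DataFrame  # index: gene
    group_sizes: tuple[int, int]

    def summary(self, n: int = 10) -> pd.DataFrame:
        return self.table.sort_values("fdr").head(n)


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs are propagated."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _g_test_2x2(det_a: int, n_a: int, det_b: int, n_b: int) -> float:
    """Logistic group-effect LRT == G-statistic on the 2x2 detection table."""
    n = n_a + n_b
    det = det_a + det_b
    obs = np.array([[det_a, n_a - det_a], [det_b, n_b - det_b]], dtype=float)
    exp = np.outer([n_a, n_b], [det / n, (n - det) / n])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return float(2.0 * terms.sum())


def hurdle_test(norm, labels: Sequence[str] | np.ndarray,
                focal: str = "resistant") -> HurdleResults:
    """Hurdle test of every gene, focal group versus the rest.

    ``norm`` is a NormalizedMatrix (or anything with .values/.genes/.cells);
    ``labels`` gives one class per cell; cells labelled ``focal`` form group
    A. All-zero genes are flagged untestable and excluded from the FDR.
    """
    values = np.asarray(norm.values, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != values.shape[0]:
        raise ValueError("labels length does not match cell count")
    grp = labels == focal
    n_a, n_b = int(grp.sum()), int((~grp).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError(f"both groups must be non-empty (focal={focal!r})")

    a, b = values[grp], values[~grp]
    det_a = (a > 0).sum(axis=0)
    det_b = (b > 0).sum(axis=0)
    n_genes = values.shape[1]

    rows = []
    for j in range(n_genes):
        da, db = int(det_a[j]), int(det_b[j])
        n_det = da + db
        row = dict(detection_rate_diff=da / n_a - db / n_b,
                   disc_p=np.nan, disc_coef=np.nan,
                   cont_p=np.nan, cont_coef=np.nan,
                   lr_stat=np.nan, df=0, p=np.nan, testable=True)
        if n_det == 0:
            row["testable"] = False
            rows.append(row)
            continue

        lr_total, df_total = 0.0, 0

        # discrete part: skipped when detection has no variation at all
        if 0 < n_det < n_a + n_b:
            pa, pb = da / n_a, db / n_b
            # log-odds difference; +/-inf under separation
            with np.errstate(divide="ignore"):
                row["disc_coef"] = (np.log(pa / (1 - pa)) if 0 < pa < 1 else
                                    np.inf if pa == 1 else -np.inf) - \
                                   (np.log(pb / (1 - pb)) if 0 < pb < 1 else
                                    np.inf if pb == 1 else -np.inf)
            if pa in (0.0, 1.0) or pb in (0.0, 1.0):
                # separation: Fisher's exact test, mapped back to a 1-df
                # chi-square so the combination rule stays uniform
                p_disc = st.fisher_exact(
                    [[da, n_a - da], [db, n_b - db]])[1]
                lr = float(st.chi2.isf(min(p_disc, 1.0), 1))
            else:
                lr = _g_test_2x2(da, n_a, db, n_b)
                p_disc = float(st.chi2.sf(lr, 1))
            row["disc_p"] = p_disc
            lr_total += lr
            df_total += 1

        # continuous part: needs detected cells in both groups and residual df
        xa, xb = a[a[:, j] > 0, j], b[b[:, j] > 0, j]
        if len(xa) >= 1 and len(xb) >= 1 and n_det >= 3:
            n = n_det
            mu = np.concatenate([xa, xb]).mean()
            rss0 = float(((xa - mu) ** 2).sum() + ((xb - mu) ** 2).sum())
            rss1 = float(((xa - xa.mean()) ** 2).sum()
                         + ((xb - xb.mean()) ** 2).sum())
            row["cont_coef"] = float(xa.mean() - xb.mean())
            if rss1 > 0:
                lr = n * np.log(rss0 / rss1)
                row["cont_p"] = float(st.chi2.sf(lr, 1))
                lr_total += lr
                df_total += 1
            elif rss0 > 0:
                # rest variance zero but groups differ: effectively infinite LR
                row["cont_p"] = 0.0
                lr_total += np.inf
                df_total += 1

        if df_total == 0:
            row["testable"] = False
        else:
            row["lr_stat"] = lr_total
            row["df"] = df_total
            row["p"] = float(st.chi2.sf(lr_total, df_total))
        rows.append(row)

    table = pd.DataFrame(rows, index=list(norm.genes))
    table["log2fc"] = (a.mean(axis=0) - b.mean(axis=0)) / np.log(2)
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    return HurdleResults(table=table, group_sizes=(n_a, n_b))


def select_markers(result: HurdleResults, fdr_max: float = 0.01,
                   component_alpha: float = 0.05, direction: str = "up",
                   require_both: bool = False) -> pd.DataFrame:
    """Marker filter: FDR, per-component significance, and sign of change.

    Keeps genes with FDR < ``fdr_max``, a significant hurdle component at
    ``component_alpha`` (either component by default; both if
    ``require_both``), and positive log2 fold change for ``direction='up'``
    (negative for 'down'). Sorted by FDR ascending, ties by |log2FC|
    descending then gene identifier.
    """
    t = result.table
    comp = pd.concat([t["disc_p"] < component_alpha,
                      t["cont_p"] < component_alpha], axis=1)
    comp_ok = comp.all(axis=1) if require_both else comp.any(axis=1)
    keep = (t["fdr"] < fdr_max) & comp_ok & t["testable"]
    if direction == "up":
        keep &= t["log2fc"] > 0
    elif direction == "down":
        keep &= t["log2fc"] < 0
    elif direction != "both":
        raise ValueError(f"unknown direction {direction!r}")
    out = t[keep].reset_index(names="gene")
    out["abs_log2fc"] = out["log2fc"].abs()
    out = out.sort_values(["fdr", "abs_log2fc", "gene"],
                          ascending=[True, False, True], kind="stable")
    return out.drop(columns="abs_log2fc").reset_index(drop=True)
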