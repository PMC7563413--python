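"""Relative qPCR quantification: ΔCT and 2^-ΔΔCT with replicate tests.

Input is a long table of cycle-threshold values: one row per
(condition, gene, replicate). ΔCT subtracts the per-condition mean CT of
the reference gene (GAPDH by default); relative expression is reported as
-ΔCT, so higher means more transcript. Fold change between conditions is
2^-ΔΔCT, with a one-sided Welch t-test on replicate ΔCTs for an increase
in the treated condition.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd
import scipy.stats as st

REQUIRED_COLS = ["condition", "gene", "ct"]


def delta_ct(records: pd.DataFrame, reference_gene: str = "GAPDH"
             ) -> pd.DataFrame:
    """Per-(condition, gene) ΔCT replicates and summary.

    ΔCT of a replicate = its CT minus the mean reference-gene CT of the
    same condition. Returns one row per condition and gene with the ΔCT
    replicate list, mean ΔCT, its 95% CI half-width, and relative
    expression -ΔCT.
    """
    missing = [c for c in REQUIRED_COLS if c not in records.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    if not np.isfinite(records["ct"]).all() or (records["ct"] <= 0).any():
        raise ValueError("CT values must be finite and positive")
    ref_mean = (records[records["gene"] == reference_gene]
                .groupby("condition")["ct"].mean())
    conditions = records["condition"].unique()
    absent = [c for c in conditions if c not in ref_mean.index]
    if absent:
        raise ValueError(f"reference gene {reference_gene!r} missing in "
                         f"conditions: {absent}")
    rows = []
    for (cond, gene), g in records.groupby(["condition", "gene"], sort=False):
        if gene == reference_gene:
            continue
        dct = g["ct"].to_numpy(dtype=float) - ref_mean[cond]
        n = len(dct)
        half = (st.t.ppf(0.975, n - 1) * dct.std(ddof=1) / np.sqrt(n)
                if n >= 2 else np.nan)
        rows.append(dict(condition=cond, gene=gene, n_replicates=n,
                         delta_ct_reps=list(dct),
                         delta_ct_mean=float(dct.mean()),
                         ci95_half_width=float(half) if n >= 2 else np.nan,
                         relative_expression=float(-dct.mean())))
    return pd.DataFrame(rows)


def ddct_fold_change(delta_ct_table: pd.DataFrame, treated: str,
                     baseline: str, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene 2^-ΔΔCT fold change, treated versus baseline.

    ΔΔCT = mean ΔCT(treated) - mean ΔCT(baseline); fold change = 2^-ΔΔCT
    and log2FC = -ΔΔCT. The one-sided Welch t-test asks whether expression
    increased (ΔCT decreased) in the treated condition; with fewer than two
    replicates in either condition the fold change is still reported and p
    is missing.
    """
    by_cond = {c: g.set_index("gene")
               for c, g in delta_ct_table.groupby("condition")}
    for c in (treated, baseline):
        if c not in by_cond:
            raise ValueError(f"condition {c!r} absent from the ΔCT table")
    genes = by_cond[treated].index.intersection(by_cond[baseline].index)
    rows = []
    for gene in genes:
        t_reps = np.asarray(by_cond[treated].loc[gene, "delta_ct_reps"],
                            dtype=float)
        b_reps = np.asarray(by_cond[baseline].loc[gene, "delta_ct_reps"],
                            dtype=float)
        ddct = float(t_reps.mean() - b_reps.mean())
        p = np.nan
        if len(t_reps) >= 2 and len(b_reps) >= 2:
            # increase in expression == decrease in delta-CT
            p = float(st.ttest_ind(t_reps, b_reps, equal_var=False,
                                   alternative="less").pvalue)
        rows.append(dict(gene=gene, ddct=ddct, fold_change=2.0 ** -ddct,
                         log2fc=-ddct, p=p,
                         significant=bool(p < alpha) if np.isfinite(p)
                         else False))
    return pd.DataFrame(rows)


def quantify(records: pd.DataFrame, treated: str, baseline: str,
             reference_gene: str = "GAPDH") -> Dict[str, pd.DataFrame]:
    """Convenience wrapper: ΔCT table plus treated-vs-baseline fold changes."""
    dct = delta_ct(records, reference_gene)
    return {"delta_ct": dct,
            "fold_change": ddct_fold_change(dct, treated, baseline)}
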