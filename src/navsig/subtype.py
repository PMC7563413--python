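"""Receptor-status thresholds and breast-cancer subtype assignment.

Bulk expression is upper-quartile normalized and log2(x+1) transformed.
For each receptor gene (ESR1 as the estrogen-receptor surrogate, ERBB2 for
HER2) a two-component Gaussian mixture is fitted to the log expression of
all samples by EM; the positivity threshold is the intersection point of
the two weighted component densities, the unique root lying between the
component means. Subtypes are assigned from IHC when complete, otherwise
from the mRNA thresholds:

* HR+/HER2-  — ER or PR positive, HER2 negative;
* HER2+      — HER2 positive with any ER/PR;
* TNBC       — all three negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

HR_HER2_NEG, HER2_POS, TNBC = "HR+/HER2-", "HER2+", "TNBC"
_IHC_CODES = {"+": True, "-": False, "pos": True, "neg": False,
              "positive": True, "negative": False, None: None, np.nan: None}


@dataclass
class MixtureFit:
    """Two-component 1-D Gaussian mixture, components in ascending-mean order."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    threshold: float = np.nan

    def __post_init__(self) -> None:
        if not (0 < self.weights[0] < 1):
            raise ValueError("weights must lie in (0,1)")
        if not self.means[0] < self.means[1]:
            raise ValueError("means must be strictly ascending")
        if (self.sds <= 0).any():
            raise ValueError("sds must be positive")

    def density(self, x: np.ndarray) -> np.ndarray:
        from scipy.stats import norm
        x = np.asarray(x, dtype=float)
        return (self.weights[0] * norm.pdf(x, self.means[0], self.sds[0])
                + self.weights[1] * norm.pdf(x, self.means[1], self.sds[1]))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "weight": self.weights, "mean": self.means, "sd": self.sds},
            index=["negative", "positive"]).assign(
                threshold=self.threshold, loglik=self.log_likelihood,
                n_iter=self.n_iter, converged=self.converged)


def upper_quartile_log2(expression: pd.DataFrame,
                        target: float | None = None) -> pd.DataFrame:
    """Upper-quartile scale each sample (column), then log2(x+1).

    Each sample is scaled so the 75th percentile of its non-zero values
    equals ``target`` (default: the median of the per-sample upper
    quartiles). Zeros stay zero.
    """
    uq = {}
    for c in expression.columns:
        nz = expression[c][expression[c] > 0]
        if nz.empty:
            raise ValueError(f"sample {c!r} is all zero")
        uq[c] = float(np.percentile(nz, 75))
        if uq[c] <= 0:
            raise ValueError(f"sample {c!r} has non-positive upper quartile")
    if target is None:
        target = float(np.median(list(uq.values())))
    scaled = expression / pd.Series(uq) * target
    return np.log2(scaled + 1.0)


def _em_once(x: np.ndarray, mu: np.ndarray, sd: np.ndarray, w: np.ndarray,
             tol: float, max_iter: int, sd_floor: float):
    """One EM run; returns (weights, means, sds, loglik, n_iter, converged).

    The log-likelihood is non-decreasing across iterations (standard EM
    guarantee); a violation beyond round-off raises, catching bugs early.
    """
    n = len(x)
    prev_ll = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        # E step
        log_comp = np.stack([
            np.log(w[k]) - 0.5 * np.log(2 * np.pi) - np.log(sd[k])
            - 0.5 * ((x - mu[k]) / sd[k]) ** 2 for k in (0, 1)])
        m = log_comp.max(axis=0)
        ll = float((m + np.log(np.exp(log_comp - m).sum(axis=0))).sum())
        if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
            raise RuntimeError("EM log-likelihood decreased")
        resp = np.exp(log_comp - m)
        resp /= resp.sum(axis=0)
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * x).sum(axis=1) / nk
        var = (resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk
        sd = np.sqrt(np.maximum(var, sd_floor ** 2))
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return w, mu, sd, prev_ll, it, converged


def fit_gmm2(values, tol: float = 1e-8, max_iter: int = 1000,
             n_init: int = 10, seed: int | None = 0) -> MixtureFit:
    """Maximum-likelihood two-component Gaussian mixture by EM.

    Runs ``n_init`` restarts from 2-means-style splits of the data
    (thresholding at jittered quantiles) and keeps the best
    log-likelihood. Component order is ascending by mean; the intersection
    threshold is filled in by :func:`intersection_threshold`.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise ValueError("need at least 10 finite values")
    if np.ptp(x) == 0:
        raise ValueError("values have zero variance")
    rng = np.random.default_rng(seed)
    sd_floor = 1e-4 * float(x.std())
    best = None
    for i in range(n_init):
        q = 0.5 if i == 0 else float(rng.uniform(0.15, 0.85))
        cut = np.quantile(x, q)
        lo, hi = x[x <= cut], x[x > cut]
        if len(lo) < 2 or len(hi) < 2:
            continue
        mu = np.array([lo.mean(), hi.mean()])
        sd = np.maximum(np.array([lo.std(), hi.std()]), sd_floor)
        w = np.array([len(lo) / len(x), len(hi) / len(x)])
        try:
            fit = _em_once(x, mu, sd, w, tol, max_iter, sd_floor)
        except RuntimeError:
            continue
        if fit[5] and (best is None or fit[3] > best[3]):
            best = fit
    if best is None:
        raise RuntimeError("EM failed to converge in every initialization")
    w, mu, sd, ll, it, conv = best
    order = np.argsort(mu)
    fit = MixtureFit(weights=w[order], means=mu[order], sds=sd[order],
                     log_likelihood=ll, n_iter=it, converged=conv)
    fit.threshold = intersection_threshold(fit)
    return fit


def intersection_threshold(fit: MixtureFit) -> float:
    """Root of w1*N(x; m1,s1) = w2*N(x; m2,s2) strictly between the means.

    Equating the two weighted normal log-densities gives a quadratic in x;
    with equal variances it degenerates to the linear closed form
    (m1+m2)/2 + s^2 ln(w1/w2)/(m2-m1).
    """
    (w1, w2), (m1, m2), (s1, s2) = fit.weights, fit.means, fit.sds
    if not m1 < m2:
        raise ValueError("means must be distinct and ordered")
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = 2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m2**2 / s2**2 - m1**2 / s1**2 + 2.0 * np.log((w1 * s2) / (w2 * s1))
    if abs(a) < 1e-12 * (1.0 / s1**2):
        # equal variances: single crossing
        s2_ = s1 * s2  # == s^2 when truly equal
        return float((m1 + m2) / 2 + s2_ * np.log(w1 / w2) / (m2 - m1))
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("densities do not cross between the means")
    roots = np.array([(-b - np.sqrt(disc)) / (2 * a),
                      (-b + np.sqrt(disc)) / (2 * a)])
    inside = roots[(roots > m1) & (roots < m2)]
    if len(inside) == 0:
        raise ValueError(f"no intersection between the means; roots: {roots}")
    return float(inside[0])


def _parse_ihc(value) -> Optional[bool]:
    if isinstance(value, float) and np.isnan(value):
        return None
    if value is None:
        return None
    key = str(value).strip().lower()
    for k, v in _IHC_CODES.items():
        if k is not None and not (isinstance(k, float)) and key == k:
            return v
    raise ValueError(f"unknown IHC code {value!r}")


def assign_subtype(ihc_er=None, ihc_pr=None, ihc_her2=None,
                   esr1_expr: float | None = None,
                   her2_expr: float | None = None,
                   thresholds: Dict[str, float] | None = None) -> str:
    """One of HR+/HER2-, HER2+, TNBC from IHC or mRNA thresholds.

    IHC rules apply when all three stains are available. Otherwise
    positivity comes from expression strictly above the per-gene mixture
    threshold (``thresholds['ESR1']`` / ``thresholds['ERBB2']``); PR has no
    mRNA surrogate and counts as negative.
    """
    er, pr, her2 = (_parse_ihc(v) for v in (ihc_er, ihc_pr, ihc_her2))
    if er is not None and pr is not None and her2 is not None:
        pass  # complete IHC
    else:
        if esr1_expr is None or her2_expr is None or thresholds is None:
            raise ValueError("incomplete IHC needs esr1_expr, her2_expr "
                             "and thresholds")
        er = esr1_expr > thresholds["ESR1"]
        her2 = her2_expr > thresholds["ERBB2"]
        pr = False
    if her2:
        return HER2_POS
    if er or pr:
        return HR_HER2_NEG
    return TNBC


def assign_subtypes(table: pd.DataFrame,
                    thresholds: Dict[str, float]) -> pd.Series:
    """Vectorized wrapper over a samples table.

    Expected columns: ihc_er, ihc_pr, ihc_her2 (codes or missing),
    esr1_expr, erbb2_expr.
    """
    out = [assign_subtype(row.get("ihc_er"), row.get("ihc_pr"),
                          row.get("ihc_her2"), row.get("esr1_expr"),
                          row.get("erbb2_expr"), thresholds)
           for _, row in table.iterrows()]
    return pd.Series(out, index=table.index, name="subtype")
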