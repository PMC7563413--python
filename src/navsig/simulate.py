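"""Synthetic data with planted ground truth for every pipeline stage.

The single-cell generator plants three cell populations — resistant,
sensitive and other — in a gamma-Poisson (negative binomial) count matrix:
per-gene lognormal base abundances, per-cell lognormal library sizes, and
a multiplicative 2^effect_log2 shift of the resistance-set genes in
resistant cells (target-set genes in sensitive cells). Cell-cycle phases
boost one of five phase programs; a G0 remainder boosts none.
Mitochondrial genes carry the conventional "MT-" prefix. Companion
generators produce a drug-response panel whose log IC50 is linear in the
true signature score, bimodal receptor expression, and toy methylome /
CNV / qPCR tables with records planted on the filter boundaries.

Everything is deterministic given the config seed: sub-generators draw
from child seeds derived with numpy SeedSequence spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .sc_matrix import CountMatrix
from .scoring import PHASE_ORDER
from .signature import DrugPanel

PHASE_KEYS = ["G1S", "S", "G2", "G2M", "MG1"]  # file-name-safe phase tags


def child_rng(seed: int | None, *key: int) -> np.random.Generator:
    """Deterministic child generator for (seed, key...)."""
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


@dataclass
class SimConfig:
    """Study conditions for the single-cell simulation.

    Defaults follow the scale of the emulated experiment: 1500 cells per
    sample, three cell classes, resistance/target program sizes of 61 and
    81 genes, five 108-gene cell-cycle programs (540 periodic genes), and
    a log2 effect of 1 on each class's defining program.
    """

    n_cells: int = 1500
    n_genes: int = 2000
    fraction_resistant: float = 0.25
    fraction_sensitive: float = 0.25
    resistance_set_size: int = 61
    target_set_size: int = 81
    effect_log2: float = 1.0
    phase_set_size: int = 108
    phase_effect_log2: float = 1.0
    library_size_mu: float = float(np.log(5000.0))  # log-scale mean
    library_size_sigma: float = 0.3
    gene_mean_sigma: float = 1.0
    dispersion: float = 0.3  # gamma-Poisson overdispersion; 0 = Poisson
    mito_fraction: float = 0.02
    phase_proportions: tuple = (0.15, 0.15, 0.10, 0.10, 0.10)  # G0 = rest
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        for name in ("fraction_resistant", "fraction_sensitive",
                     "mito_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fraction_resistant + self.fraction_sensitive > 1:
            raise ValueError("class fractions must sum to <= 1")
        if len(self.phase_proportions) != 5:
            raise ValueError("phase_proportions needs 5 entries")
        if any(p < 0 for p in self.phase_proportions) \
                or sum(self.phase_proportions) > 1 + 1e-12:
            raise ValueError("phase proportions must be >= 0 and sum to <= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        n_special = (self.resistance_set_size + self.target_set_size
                     + 5 * self.phase_set_size
                     + int(round(self.mito_fraction * self.n_genes)))
        if n_special > self.n_genes:
            raise ValueError(
                f"gene sets need {n_special} genes but n_genes={self.n_genes}")


@dataclass
class SyntheticTruth:
    """Planted ground truth aligned to the generated identifiers."""

    cell_class: np.ndarray  # resistant | sensitive | other, per cell
    cell_phase: np.ndarray  # G0 or one of the five phases, per cell
    gene_sets: Dict[str, List[str]]
    panel_coefficients: Optional[Dict[str, float]] = None
    receptor_params: Optional[Dict[str, float]] = None


def _gene_names(config: SimConfig) -> tuple[List[str], Dict[str, List[str]]]:
    n_mito = int(round(config.mito_fraction * config.n_genes))
    sets: Dict[str, List[str]] = {
        "navitoclax_resistance":
            [f"RES-{i:04d}" for i in range(1, config.resistance_set_size + 1)],
        "navitoclax_targets":
            [f"TGT-{i:04d}" for i in range(1, config.target_set_size + 1)],
    }
    for tag, phase in zip(PHASE_KEYS, PHASE_ORDER):
        sets[phase] = [f"CC-{tag}-{i:04d}"
                       for i in range(1, config.phase_set_size + 1)]
    mito = [f"MT-{i:04d}" for i in range(1, n_mito + 1)]
    special = sets["navitoclax_resistance"] + sets["navitoclax_targets"] \
        + sum((sets[p] for p in PHASE_ORDER), []) + mito
    n_bg = config.n_genes - len(special)
    genes = special + [f"G{i:05d}" for i in range(1, n_bg + 1)]
    sets["mitochondrial"] = mito
    return genes, sets


def simulate_sc_counts(config: SimConfig,
                       resistance_genes: Sequence[str] | None = None,
                       target_genes: Sequence[str] | None = None
                       ) -> tuple[CountMatrix, SyntheticTruth,
                                  Dict[str, List[str]]]:
    """Simulate the cell x gene count matrix with planted structure.

    Returns the counts, the planted truth and the gene sets (resistance,
    targets, the five phase programs, mitochondrial). Explicit
    ``resistance_genes`` / ``target_genes`` may override the generated
    memberships; they must be disjoint.
    """
    genes, sets = _gene_names(config)
    if resistance_genes is not None:
        sets["navitoclax_resistance"] = list(resistance_genes)
    if target_genes is not None:
        sets["navitoclax_targets"] = list(target_genes)
    res_set, tgt_set = (sets["navitoclax_resistance"],
                        sets["navitoclax_targets"])
    if set(res_set) & set(tgt_set):
        raise ValueError("resistance and target sets overlap")
    for name, members in (("resistance", res_set), ("target", tgt_set)):
        unknown = set(members) - set(genes)
        if unknown:
            raise ValueError(f"{name} set genes not in the matrix: "
                             f"{sorted(unknown)[:5]}")

    n, m = config.n_cells, config.n_genes
    gene_index = {g: i for i, g in enumerate(genes)}

    # cell classes and phases, in fixed proportions
    rng_cls = child_rng(config.seed, 0)
    n_res = int(round(config.fraction_resistant * n))
    n_sen = int(round(config.fraction_sensitive * n))
    classes = np.array(["resistant"] * n_res + ["sensitive"] * n_sen
                       + ["other"] * (n - n_res - n_sen), dtype=object)
    rng_cls.shuffle(classes)
    phase_p = list(config.phase_proportions)
    phases = rng_cls.choice(PHASE_ORDER + ["G0"], size=n,
                            p=phase_p + [1.0 - sum(phase_p)])

    # gamma-Poisson counts
    rng = child_rng(config.seed, 1)
    base = rng.lognormal(0.0, config.gene_mean_sigma, size=m)
    p_gene = base / base.sum()
    lib = rng.lognormal(config.library_size_mu, config.library_size_sigma,
                        size=n)
    mult = np.ones((n, m))
    res_idx = np.array([gene_index[g] for g in res_set])
    tgt_idx = np.array([gene_index[g] for g in tgt_set])
    mult[np.ix_(classes == "resistant", res_idx)] *= 2.0 ** config.effect_log2
    mult[np.ix_(classes == "sensitive", tgt_idx)] *= 2.0 ** config.effect_log2
    for phase in PHASE_ORDER:
        idx = np.array([gene_index[g] for g in sets[phase]])
        mult[np.ix_(phases == phase, idx)] *= 2.0 ** config.phase_effect_log2
    mean = lib[:, None] * p_gene[None, :] * mult
    if config.dispersion > 0:
        lam = rng.gamma(1.0 / config.dispersion,
                        scale=mean * config.dispersion)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(np.int64)

    cells = [f"CELL-{i:05d}" for i in range(1, n + 1)]
    cm = CountMatrix(cells=cells, genes=genes,
                     counts=sp.csr_matrix(counts))
    truth = SyntheticTruth(cell_class=classes, cell_phase=np.asarray(phases),
                           gene_sets={k: list(v) for k, v in sets.items()})
    return cm, truth, {k: list(v) for k, v in sets.items()
                       if k != "mitochondrial"}


def simulate_drug_panel(tissues: Dict[str, int],
                        signature_genes: Sequence[str],
                        alpha: float = 0.0, beta: float = 1.0,
                        sigma_noise: float = 0.5,
                        n_genes: int = 1000,
                        within_signature_noise_sd: float = 0.5,
                        seed: int = 0
                        ) -> tuple[DrugPanel, Dict[str, object]]:
    """Cell-line panel whose log IC50 is linear in the true signature mean.

    Each tissue contributes the requested number of lines. A per-line
    latent resistance level shifts every signature gene; background genes
    (up to ``n_genes`` total) are independent noise. The response is
    alpha + beta * (realized mean signature expression) + N(0, sigma_noise)
    for the drug "NAVITOCLAX".
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    if any(s <= 0 for s in tissues.values()):
        raise ValueError("tissue sizes must be positive")
    signature_genes = list(signature_genes)
    rng = child_rng(seed, 10)
    lines, tissue_col = [], []
    for t, size in tissues.items():
        for i in range(size):
            lines.append(f"{t}-LINE-{i + 1:03d}")
            tissue_col.append(t)
    n_lines = len(lines)
    latent = rng.normal(0.0, 1.0, size=n_lines)
    n_bg = max(n_genes - len(signature_genes), 0)
    bg_genes = [f"BG{i:05d}" for i in range(1, n_bg + 1)]
    base_sig = rng.normal(5.0, 1.0, size=len(signature_genes))
    expr_sig = base_sig[:, None] + latent[None, :] \
        + rng.normal(0.0, within_signature_noise_sd,
                     size=(len(signature_genes), n_lines))
    base_bg = rng.normal(5.0, 1.0, size=n_bg)
    expr_bg = base_bg[:, None] + rng.normal(0.0, 1.0, size=(n_bg, n_lines))
    expression = pd.DataFrame(np.vstack([expr_sig, expr_bg]),
                              index=signature_genes + bg_genes,
                              columns=lines)
    true_score = expression.loc[signature_genes].mean(axis=0).to_numpy()
    log_ic50 = alpha + beta * true_score \
        + rng.normal(0.0, sigma_noise, size=n_lines)
    response = pd.DataFrame(dict(line=lines, tissue=tissue_col,
                                 drug="NAVITOCLAX", log_ic50=log_ic50))
    truth = dict(alpha=alpha, beta=beta, sigma_noise=sigma_noise,
                 true_score=true_score, latent=latent)
    return DrugPanel(response=response, expression=expression), truth


def simulate_receptor_expression(n: int, weight: float, mu_neg: float,
                                 mu_pos: float, sd_neg: float, sd_pos: float,
                                 seed: int = 0
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Draws from a two-component Gaussian mixture with true labels.

    ``weight`` is the negative-component proportion; labels are 0 for the
    negative (low) component, 1 for the positive.
    """
    if not 0 <= weight <= 1:
        raise ValueError("weight must lie in [0, 1]")
    if not mu_neg < mu_pos:
        raise ValueError("mu_neg must be below mu_pos")
    if sd_neg <= 0 or sd_pos <= 0:
        raise ValueError("sds must be positive")
    rng = child_rng(seed, 20)
    labels = (rng.uniform(size=n) >= weight).astype(int)
    values = np.where(labels == 0,
                      rng.normal(mu_neg, sd_neg, size=n),
                      rng.normal(mu_pos, sd_pos, size=n))
    return values, labels


@dataclass
class OmicsSimConfig:
    """Toy methylome / CNV / qPCR generation parameters.

    CNV records are planted on both sides of the downstream filter
    boundaries (length 1000 and q0 0.15 fail; longer/cleaner records
    pass); CpG tables include rows that each CpG filter clause removes.
    """

    n_cpgs: int = 200
    n_samples: int = 3
    n_unmethylated: int = 2      # fractions 0 in every sample
    n_fully_methylated: int = 2  # fractions 1 in every sample
    n_low_coverage: int = 3      # coverage below 10x in at least one sample
    coverage_mean: float = 30.0
    coverage_dispersion: float = 0.3
    n_cnvs: int = 20
    n_short_cnvs: int = 3        # length <= 1000: removed by the filter
    n_high_q0_cnvs: int = 3      # q0 >= 0.15: removed by the filter
    qpcr_genes: tuple = ("PSMC1", "PSMC3", "MARKER1", "MARKER2")
    qpcr_reference: str = "GAPDH"
    qpcr_replicates: int = 3
    qpcr_ct_shift: float = -1.0  # treated-minus-baseline CT shift
    qpcr_ct_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cpgs, self.n_samples, self.n_cnvs) < 0:
            raise ValueError("sizes must be non-negative")
        if self.n_unmethylated + self.n_fully_methylated \
                + self.n_low_coverage > self.n_cpgs and self.n_cpgs > 0:
            raise ValueError("planted CpG rows exceed n_cpgs")
        if self.n_short_cnvs + self.n_high_q0_cnvs > self.n_cnvs \
                and self.n_cnvs > 0:
            raise ValueError("planted CNV rows exceed n_cnvs")


@dataclass
class OmicsTables:
    cpgs: pd.DataFrame
    cnvs: pd.DataFrame
    qpcr: pd.DataFrame
    truth: Dict[str, object] = field(default_factory=dict)


def simulate_methylome_cnv_qpcr(config: OmicsSimConfig) -> OmicsTables:
    """Generate the CpG, CNV and qPCR tables with planted filter cases."""
    rng = child_rng(config.seed, 30)
    samples = [f"s{i + 1}" for i in range(config.n_samples)]

    # CpGs: beta-distributed fractions, negative-binomial coverage
    n = config.n_cpgs
    cols: Dict[str, np.ndarray] = {
        "chrom": np.array(["chr1"] * n, dtype=object),
        "pos": np.sort(rng.choice(np.arange(1, 10_000_000), size=n,
                                  replace=False)) if n else
        np.array([], dtype=int)}
    site_mean = rng.beta(2, 2, size=n)
    frac = {s: np.clip(rng.beta(site_mean * 10 + 1e-6,
                                (1 - site_mean) * 10 + 1e-6), 0, 1)
            for s in samples}
    r = 1.0 / config.coverage_dispersion
    cov = {s: rng.negative_binomial(
        r, r / (r + config.coverage_mean), size=n) + 10 for s in samples}
    planted = dict(unmethylated=[], fully_methylated=[], low_coverage=[])
    i = 0
    for _ in range(config.n_unmethylated):
        for s in samples:
            frac[s][i] = 0.0
        planted["unmethylated"].append(i)
        i += 1
    for _ in range(config.n_fully_methylated):
        for s in samples:
            frac[s][i] = 1.0
        planted["fully_methylated"].append(i)
        i += 1
    for _ in range(config.n_low_coverage):
        cov[samples[i % len(samples)]][i] = int(rng.integers(0, 10))
        if frac[samples[0]][i] in (0.0, 1.0):
            frac[samples[0]][i] = 0.5
        planted["low_coverage"].append(i)
        i += 1
    for s in samples:
        cols[f"frac_{s}"] = np.round(frac[s], 4)
        cols[f"cov_{s}"] = cov[s]
    cpgs = pd.DataFrame(cols)

    # CNVs spanning the filter boundaries
    rows = []
    k = config.n_cnvs
    for j in range(k):
        start = int(rng.integers(1, 50_000_000))
        if j < config.n_short_cnvs:
            length = int(rng.integers(100, 1001))  # includes exactly 1000
            q0 = float(rng.uniform(0.0, 0.1))
            fails = True
        elif j < config.n_short_cnvs + config.n_high_q0_cnvs:
            length = int(rng.integers(2000, 100_000))
            q0 = float(rng.uniform(0.15, 0.9))  # includes exactly 0.15
            fails = True
        else:
            length = int(rng.integers(2000, 100_000))
            q0 = float(rng.uniform(0.0, 0.149))
            fails = False
        rows.append(dict(chrom="chr1", start=start, end=start + length,
                         type=str(rng.choice(["deletion", "amplification"])),
                         q0=round(q0, 4), planted_fails_filter=fails))
    cnvs = pd.DataFrame(rows, columns=["chrom", "start", "end", "type",
                                       "q0", "planted_fails_filter"])

    # qPCR CT triplicates with a treatment shift on the target genes
    qrows = []
    for gene in (config.qpcr_reference, *config.qpcr_genes):
        base_ct = float(rng.uniform(18, 28))
        for cond in ("baseline", "treated"):
            shift = config.qpcr_ct_shift \
                if (cond == "treated" and gene != config.qpcr_reference) \
                else 0.0
            for rep in range(1, config.qpcr_replicates + 1):
                qrows.append(dict(
                    condition=cond, gene=gene, replicate=rep,
                    ct=round(base_ct + shift
                             + float(rng.normal(0, config.qpcr_ct_sd)), 3)))
    qpcr = pd.DataFrame(qrows, columns=["condition", "gene",
                                        "replicate", "ct"])

    truth = dict(planted_cpgs=planted,
                 ct_shift=config.qpcr_ct_shift,
                 expected_fold_change=2.0 ** -config.qpcr_ct_shift)
    return OmicsTables(cpgs=cpgs, cnvs=cnvs, qpcr=qpcr, truth=truth)


def load_builtin_sets(which: str = "all") -> Dict[str, List[str]]:
    """Packaged placeholder gene sets (synthetic stand-ins).

    ``which``: 'cell_cycle', 'navitoclax', or 'all'. The gene names match
    the ones :func:`simulate_sc_counts` plants, with the cardinalities of
    the emulated study (5 x 108 periodic genes; 81 targets; 61 resistance
    genes).
    """
    from .io import read_gmt
    files = {"cell_cycle": "synthetic_cell_cycle.gmt",
             "navitoclax": "synthetic_navitoclax_sets.gmt"}
    if which != "all" and which not in files:
        raise ValueError(f"unknown set collection {which!r}")
    out: Dict[str, List[str]] = {}
    for key, fname in files.items():
        if which in ("all", key):
            path = resources.files("navsig.data") / fname
            with resources.as_file(path) as p:
                out.update(read_gmt(p))
    return out
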