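"""End-to-end orchestration of the discovery and validation paths.

``run_discovery`` chains simulation (or loading) -> QC -> normalization ->
module scoring -> resistant/sensitive/other classification -> hurdle DE ->
marker selection -> top-k signature, writing each stage's table and a
manifest of row counts and seeds. ``run_validation`` scores a drug panel
with the signature, correlates it with log IC50 per tissue, ranks it
against all single genes, and summarizes the qPCR fold changes and
receptor-mixture thresholds. All stage defaults are the thresholds used
throughout the package (QC >1000 transcripts, <10% mito, >10 cells;
FDR < 0.01 with a 0.05 component test; k = 18; groups >= 10 lines).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import hurdle, qpcr, scoring, sc_matrix, signature as sigmod, simulate
from .scoring import GeneSet
from .subtype import fit_gmm2

logger = logging.getLogger(__name__)

DISCOVERY_STAGES = ["simulate", "qc", "normalize", "score", "classify",
                    "hurdle", "signature"]


@dataclass
class RunConfig:
    """Serializable parameters for a full pipeline run."""

    outdir: str = "navsig_run"
    seed: int = 0
    log_level: str = "INFO"
    sim: Dict = field(default_factory=dict)          # SimConfig overrides
    qc: Dict = field(default_factory=lambda: dict(
        min_transcripts=1000, max_mito_frac=0.10, min_cells_per_gene=10))
    score: Dict = field(default_factory=lambda: dict(n_bins=24, n_ctrl=100))
    de: Dict = field(default_factory=lambda: dict(
        fdr_max=0.01, component_alpha=0.05, direction="up"))
    signature: Dict = field(default_factory=lambda: dict(k=18))
    panel: Dict = field(default_factory=lambda: dict(
        tissues={"breast": 100, "lung": 100}, alpha=0.0, beta=1.0,
        sigma_noise=0.5, n_genes=1000))
    validation: Dict = field(default_factory=lambda: dict(
        drug="NAVITOCLAX", group_by="tissue", min_group=10))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _write(df: pd.DataFrame, outdir: str, name: str) -> str:
    path = os.path.join(outdir, name)
    df.to_csv(path)
    return path


def run_discovery(config: RunConfig) -> Dict[str, object]:
    """Execute the discovery path on simulated data; returns all artifacts.

    Writes per-stage CSVs and a manifest.json with per-stage row counts to
    ``config.outdir``.
    """
    os.makedirs(config.outdir, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: Dict[str, Dict] = {}
    config.to_yaml(os.path.join(config.outdir, "config.yaml"))

    sim_cfg = simulate.SimConfig(seed=config.seed, **config.sim)
    counts, truth, sets = simulate.simulate_sc_counts(sim_cfg)
    manifest["simulate"] = dict(cells=len(counts.cells),
                                genes=len(counts.genes), seed=config.seed)

    qc_counts = sc_matrix.qc_filter(counts, **config.qc)
    manifest["qc"] = dict(cells=len(qc_counts.cells),
                          genes=len(qc_counts.genes))

    norm = sc_matrix.normalize_log_cpm(qc_counts)
    manifest["normalize"] = dict(cells=norm.shape[0], genes=norm.shape[1])

    score_sets = [GeneSet("navitoclax_targets", sets["navitoclax_targets"]),
                  GeneSet("navitoclax_resistance",
                          sets["navitoclax_resistance"])]
    phase_sets = [GeneSet(p, sets[p]) for p in scoring.PHASE_ORDER]
    scores = scoring.score_sets(norm, score_sets + phase_sets,
                                seed=config.seed, **config.score)
    _write(scores, config.outdir, "scores.csv")
    manifest["score"] = dict(cells=len(scores), sets=scores.shape[1])

    labels = pd.DataFrame(index=scores.index)
    labels["resistance_class"] = scoring.classify_resistance(
        scores["navitoclax_targets"], scores["navitoclax_resistance"])
    labels["phase"] = scoring.assign_cell_cycle(
        scores[scoring.PHASE_ORDER])
    _write(labels, config.outdir, "labels.csv")
    manifest["classify"] = labels["resistance_class"].value_counts().to_dict()

    de = hurdle.hurdle_test(norm, labels["resistance_class"].to_numpy())
    _write(de.table, config.outdir, "hurdle.csv")
    markers = hurdle.select_markers(de, **config.de)
    _write(markers, config.outdir, "markers.csv")
    manifest["hurdle"] = dict(genes_tested=int(de.table["testable"].sum()),
                              markers=len(markers))

    k = config.signature["k"]
    sig = sigmod.build_signature(markers, k=min(k, max(len(markers), 1)))
    pd.Series(sig.genes, name="gene").to_csv(
        os.path.join(config.outdir, "signature.csv"), index=False)
    manifest["signature"] = dict(k=len(sig.genes))

    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(dict(stages=DISCOVERY_STAGES, counts=manifest), fh,
                  indent=2)
    return dict(counts=counts, truth=truth, sets=sets, qc=qc_counts,
                norm=norm, scores=scores, labels=labels, hurdle=de,
                markers=markers, signature=sig, manifest=manifest)


def run_validation(config: RunConfig,
                   sig: Optional[sigmod.Signature] = None
                   ) -> Dict[str, object]:
    """Execute the validation path: drug panel, qPCR and receptor mixture.

    With no signature given, a planted signature of the panel's own
    signature genes is simulated; the panel's log IC50 is linear in the
    planted score.
    """
    os.makedirs(config.outdir, exist_ok=True)
    if sig is None:
        sig = sigmod.Signature(
            genes=[f"SIG{i:02d}" for i in range(1, 19)], source="planted")
    panel, panel_truth = simulate.simulate_drug_panel(
        signature_genes=sig.genes, seed=config.seed, **config.panel)
    corr = sigmod.correlate_response(
        panel, sig, drug=config.validation["drug"],
        group_by=config.validation["group_by"],
        min_group=config.validation["min_group"])
    pct = sigmod.percentile_vs_genes(panel, sig,
                                     drug=config.validation["drug"])
    corr.to_csv(os.path.join(config.outdir, "correlations.csv"), index=False)

    omics = simulate.simulate_methylome_cnv_qpcr(
        simulate.OmicsSimConfig(seed=config.seed))
    quant = qpcr.quantify(omics.qpcr, treated="treated", baseline="baseline")
    quant["fold_change"].to_csv(
        os.path.join(config.outdir, "qpcr_fold_change.csv"), index=False)

    values, _ = simulate.simulate_receptor_expression(
        n=2000, weight=0.5, mu_neg=0.0, mu_pos=4.0, sd_neg=1.0, sd_pos=1.0,
        seed=config.seed)
    fit = fit_gmm2(values, seed=config.seed)

    report = dict(correlations=corr, percentile_vs_genes=pct,
                  qpcr=quant, receptor_fit=fit, panel=panel,
                  panel_truth=panel_truth, signature=sig)
    with open(os.path.join(config.outdir, "validation.json"), "w") as fh:
        json.dump(dict(
            percentile_vs_genes=pct,
            correlations=corr.to_dict(orient="records"),
            receptor_threshold=fit.threshold,
            receptor_means=[float(m) for m in fit.means]), fh, indent=2)
    return report
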