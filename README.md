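# navsig

Single-cell discovery and multi-omic validation of a drug-resistance
gene signature, packaged as a reusable, fully tested pipeline.

## The problem

BH3-mimetic drugs such as navitoclax (ABT-263) kill tumour cells by
inhibiting anti-apoptotic BCL2-family proteins, but a subpopulation of
cells survives treatment. Given droplet scRNA-seq of a treated
triple-negative breast-cancer line, the analysis implemented here asks:
which cells are in a resistant transcriptional state, which genes mark
that state, and does a compact signature built from those markers predict
navitoclax response in independent cell-line panels?

The pipeline:

1. **QC and normalization** — keep cells with > 1000 transcripts and
   < 10% mitochondrial reads, genes detected in > 10 cells; transform
   counts to `log(CPM/100 + 1)`. Transcriptional heterogeneity between
   cells is summarized by the generalized Jensen–Shannon divergence
   (`gJSD = H(mean profile) − mean H(profile)`, in bits).
2. **Module scoring and classification** — score each cell for a
   *navitoclax-target* set and a *navitoclax-resistance* set using
   binned-control scoring (mean expression of set genes minus the mean of
   expression-matched control genes drawn from 24 equal-frequency bins).
   A cell is *resistant* when its resistance score is positive and exceeds
   the target score, *sensitive* in the mirror case, *other* otherwise.
   Cell-cycle phase is the argmax of five phase-program scores, or G0 when
   none is positive.
3. **Marker discovery** — a two-part (hurdle) test per gene, resistant
   versus all other cells: a logistic detection component plus a Gaussian
   component on detected expression, combined by summing likelihood-ratio
   χ² statistics. Markers pass FDR < 0.01 (Benjamini–Hochberg) with a
   component significant at 0.05 and positive fold change.
4. **Signature and validation** — the top 18 markers ranked by FDR form
   the signature; a sample's score is their mean log expression. The score
   is validated by Spearman correlation with log(IC50) of navitoclax
   across cell-line panels (tissues with < 10 lines dropped) and by its
   percentile among all single-gene correlations.
5. **Supporting analyses** — receptor-status calling by two-component
   Gaussian-mixture intersection thresholds on upper-quartile/log2
   normalized expression; coverage-weighted promoter methylation within
   ±1000 bp of the TSS; peak/CNV-to-gene interval linking with 1000 bp
   gene extension; ΔCT / 2^−ΔΔCT qPCR quantification.

Because the original sequencing data are not bundled, a first-class
synthetic-data module generates every input with planted ground truth
(cell classes, marker sets, response coefficients, mixture components),
so the whole pipeline is testable end to end.

## Worked example

```python
import navsig as ns

# discovery on simulated data with a planted 2^1.0 resistance effect
res = ns.run_discovery(ns.RunConfig(outdir="example_run", seed=1))
print(res["labels"]["resistance_class"].value_counts().to_dict())
# {'other': 626, 'resistant': 450, 'sensitive': 424}
print(res["signature"].genes[:6])
# ['RES-0033', 'RES-0036', 'RES-0027', 'RES-0057', 'RES-0013', 'RES-0054']

# validate the discovered signature on a simulated drug panel
sig = res["signature"]
panel, _ = ns.simulate_drug_panel({"breast": 100, "lung": 100}, sig.genes,
                                  beta=1.0, sigma_noise=0.5, seed=1)
print(ns.correlate_response(panel, sig, "NAVITOCLAX").round(3))
#     group      r    p    n
# 0  breast  0.889  0.0  100
# 1    lung  0.894  0.0  100
print(ns.percentile_vs_genes(panel, sig, "NAVITOCLAX"))
# 100.0
```

The planted truth behind this run has 375 resistant cells out of 1500 and
a log IC50 that increases one-for-one with the true signature mean; the
discovered signature consists entirely of planted resistance genes
(`RES-*`), the per-tissue rank correlations are strongly positive, and
the signature outranks every individual gene.

The same stages are available from the shell:

```bash
navsig simulate --seed 1 --outdir sim/
navsig qc sim/ --outdir qc/
navsig run-discovery --seed 1 --outdir run/
navsig run-validation --seed 1 --outdir run/
```

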