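# Methods

This note documents the statistical procedures implemented in `navsig`,
the synthetic data they are exercised on, and the design choices made
where the analysis recipe left details open.

## Single-cell preprocessing

Counts are cells × genes non-negative integers (`CountMatrix`, sparse).
QC applies strict inequalities, cells first: a cell survives with total
counts **> 1000** and mitochondrial fraction **< 0.10** (mitochondrial
genes identified by the `MT-` name prefix); a gene then survives when
detected (count > 0) in **> 10** surviving cells. The thresholds are
parameters of `qc_filter`; errors report per-rule survivor counts.

Normalization is `ln(count / cell_total × 10⁴ + 1)` — the
log(CPM/100 + 1) transform in natural log. The log base is a convention
choice: the count-per-ten-thousand log1p form is the field's standard and
any base change is a global scale factor that does not affect rank-based
statistics, classifications or test decisions downstream.

Generalized Jensen–Shannon divergence measures between-cell profile
heterogeneity: each cell's vector is renormalized to a probability
distribution and `gJSD = H(equal-weight mixture) − mean(H(cell))` with
Shannon entropy **in bits** (the convention of the reference
implementation of gJSD in the philentropy ecosystem), `0·log 0 = 0`. It
is 0 for identical cells and log₂K for K pairwise-disjoint cells. By
default probabilities are built from normalized values, matching the
operation's position after normalization; a flag switches to raw counts.

## Module scoring and classification

`module_score` re-implements binned-control gene-set scoring (the scheme
used by Seurat's cell-cycle scorer): genes are ranked by mean normalized
expression and split into `n_bins = 24` equal-frequency bins (stable
order on ties); each set gene contributes `n_ctrl = 100` control genes
drawn uniformly **without replacement** from the non-set genes of its
bin; when a bin holds at most `n_ctrl` candidates the entire bin is used,
which makes the score independent of the draw seed in that regime. The
score is the mean over set genes minus the mean over the pooled control
draws. Both parameters are exposed; the defaults are the scorer's
conventional values.

Cell-cycle phase is the argmax over the five phase scores (G1/S, S, G2,
G2/M, M/G1) when the maximum is positive, else **G0**; ties among
positive maxima break in the fixed order listed. Because G0 requires all
five scores to be non-positive, the rule is liberal for cycling phases
and conservative G0 counts should not be over-interpreted.

Resistance classification: *resistant* iff resistance score > 0 and
> target score; *sensitive* iff target score > 0 and > resistance score;
everything else — both non-positive, ties, zeros — is *other*, the
residual category. The closure makes the rule total and mutually
exclusive.

## Hurdle differential expression

Each gene is tested resistant-vs-rest with two likelihood-ratio parts:

* **detection**: logistic regression of `expression > 0` on the group
  indicator. With a single binary covariate the LRT is available in
  closed form as the G-statistic of the 2×2 detection table, which is
  what the implementation computes (verified against iterative logistic
  fits in the tests). Complete separation (a group at 0% or 100%
  detection) replaces the LRT p-value with Fisher's exact test, mapped
  back to a 1-df χ² so combination stays uniform.
* **continuous**: Gaussian regression of normalized expression among
  detected cells; the group-effect LRT is `n·ln(RSS₀/RSS₁)` (1 df).

The combined statistic sums the two χ² values with summed df; the
combined p is its χ² tail. A degenerate component (every cell detected;
too few detected cells) drops out and the other is used alone; all-zero
genes are flagged untestable and excluded from FDR. No cellular-
detection-rate covariate is included by default — the analysis recipe
does not state one — and the continuous part is ordinary least squares.

FDR is Benjamini–Hochberg (`statsmodels` step-up; NaNs propagate).
Markers keep FDR < 0.01, **either** component p < 0.05 (switchable to
both), and positive log2 fold change, ordered by FDR then |log2FC| then
gene ID.

## Signature and drug-panel validation

The signature is the first k = 18 rows of the ordered marker table. A
sample's score is the **plain mean** of signature-gene log expression (no
weighting or z-scoring; a z-scored variant exists behind a flag for
cross-dataset use). Validation computes Spearman correlations (average
ranks on ties) of score vs log(IC50) per tissue/subtype group, dropping
groups with fewer than 10 lines; p-values use the t approximation for
n ≥ 10 and exact permutation for smaller n. `percentile_vs_genes`
compares the signature's **signed** correlation against every single
gene's and returns the percentage strictly below it — signed, because
the claim under test is a positive association with resistance.

## Receptor mixtures and subtype calls

Bulk expression is upper-quartile normalized (each sample scaled so the
75th percentile of its non-zero values equals the median of per-sample
upper quartiles) and log2(x+1) transformed. For ESR1 and ERBB2 a
two-component Gaussian mixture is fitted by EM, hand-written so the fit
is fully inspectable: 10 restarts from quantile splits of the data,
per-iteration log-likelihood monotonicity asserted, sd floored at
10⁻⁴ of the data sd, components reported in ascending mean order,
unequal variances allowed. The positivity threshold is the intersection
of the two weighted component densities — the root of the implied
quadratic lying strictly between the means (closed form under equal
variances). Subtypes use IHC when all three stains are present
(ER/PR/HER2 rules for HR+/HER2−, HER2+, TNBC); otherwise mRNA positivity
is expression strictly above the per-gene threshold, with ESR1 standing
in for ER and PR treated as negative (it has no stated mRNA surrogate).

## Interval and methylation plumbing

All coordinates are 0-based half-open (BED semantics); TSS is `start` on
'+' and `end − 1` on '−'. CpG filtering removes sites never methylated in
any sample, fully methylated in all samples, or covered below 10 reads —
applied per sample in **all** samples by default so retained sites are
comparable across conditions ('any' available via flag). Promoter
methylation is the coverage-weighted mean fraction over CpGs within
±1000 bp of the TSS, inclusive at both window ends; genes without CpGs
get a missing value. Interval→gene linking extends genes by 1000 bp both
ways (clamped at 0) and links on ≥ 1 shared base — overlap, not
containment (containment via flag). CNV filters are strict: length
> 1000 bp and q0 < 0.15. Differential statistics for external modalities
are consumed as tables (feature, log2FC, FDR) with the FDR < 0.05 and
|log2FC| > 1 peak filter applied as given.

## qPCR quantification

ΔCT subtracts the per-condition mean reference CT (GAPDH default) from
each replicate CT; relative expression is −ΔCT. Fold change between
conditions is 2^−ΔΔCT with log2FC = −ΔΔCT. Significance of an increase
uses a one-sided Welch t-test on replicate ΔCTs — chosen because
replicate pairing across plates is not modelled; with fewer than two
replicates the fold change is still reported with a missing p.

## Synthetic data

The generator is the package's study stand-in, not a dial: defaults are
fixed at the emulated experiment's scale and are the conditions all
recovery tests run under.

* **Counts**: gamma-Poisson. Per-gene relative abundance is lognormal
  (σ = 1); per-cell library size lognormal with mean 5000 (σ = 0.3),
  matching droplet libraries that comfortably clear the 1000-transcript
  QC floor; negative-binomial dispersion 0.3. 1500 cells (the per-sample
  scale of the emulated experiment) × 2000 genes.
* **Planted structure**: 25% resistant and 25% sensitive cells; the
  61-gene resistance program is multiplied by 2^effect_log2 (default 1)
  in resistant cells, the 81-gene target program likewise in sensitive
  cells — multiplicative on means, so both hurdle components carry
  signal. Five 108-gene phase programs (540 periodic genes) are boosted
  in cells of the corresponding phase (proportions 0.15/0.15/0.10/0.10/
  0.10, remainder G0); 2% of genes are mitochondrial (`MT-` prefix).
* **Drug panel**: a per-line latent resistance level shifts all
  signature genes; background genes are independent noise; log IC50 =
  α + β·(realized mean signature expression) + N(0, σ). With σ = 0 the
  response is exactly monotone in the score.
* **Receptor expression**: i.i.d. two-component Gaussian mixture with
  recorded labels.
* **Methylome/CNV/qPCR**: beta-distributed methylation with
  negative-binomial coverage and planted rows violating each CpG filter
  clause; CNVs planted on both sides of the length/q0 boundaries
  (including exactly 1000 bp and exactly q0 = 0.15); CT triplicates with
  a −1 treatment shift (fold change 2).

Determinism: one global seed drives `numpy` `SeedSequence` spawning, so
every generator is bit-reproducible and sub-generators are independent.

What the generator does **not** emulate: transcriptome-wide gene–gene
covariance, doublets, ambient RNA, batch effects, realistic CNV size
distributions or primer efficiencies. Passing recovery tests therefore
demonstrates correctness of the inference machinery under the stated
generative model, not performance on real libraries.

## Problem sizes and numerical choices

Recovery and calibration checks use: classifier balanced accuracy
(resistant vs rest) on 1500-cell simulations (375 cells per class) over
multiple seeds; hurdle null calibration on 400 cells × 2000 genes with
permuted labels; signature recovery at effect_log2 = 1.5; panels of 200
lines across two tissues. "Balanced accuracy" is the binary
resistant-versus-rest form — the quantity of interest is recovery of
resistant cells; under the classification rule's closure, symmetric
score noise necessarily spreads a fraction of true "other" cells across
the two positive classes, so three-class macro recall is structurally
bounded and is not the target metric.

Numerical details: BH q-values capped at 1; χ² tails from `scipy`;
mixture EM tolerance 1e-8 on relative log-likelihood with a 1000-
iteration cap; intersection roots from the quadratic formula with an
equal-variance fallback when the leading coefficient vanishes; Spearman
tie handling by average ranks throughout.

## Known limitations

* The hurdle test's χ² calibration relies on asymptotics; for very low
  detection rates the discrete part is conservative (Fisher fallback).
* The packaged cell-cycle/target/resistance GMT files are synthetic
  placeholders with the study's cardinalities (5×108, 81, 61); users
  should substitute curated lists for real data.
* Phase assignment under-calls G0 by construction (see above).
* The signature score assumes comparable scale across signature genes;
  the optional z-scored variant should be preferred across platforms.
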