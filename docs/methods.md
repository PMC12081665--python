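# Methods

This note documents the models and procedures implemented in `trccomics`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Coordinates and formats

All genomic intervals are BED-style: 0-based, half-open `[start, end)`.
TSS positions are 0-based. Two intervals overlap iff they share at least
one base; book-ended intervals (`end == start`) do not overlap and are not
merged. Peak files are plain BED (3–5 columns), annotations are TSV
(`gene_id, chrom, tss, strand`), expression matrices are TSV with genes as
rows, gene sets are standard GMT, survival tables are TSV
(`sample_id, time, event`).

## Core-regulon definition

A *core regulon* is the gene program inferred from binding profiled across
several cell lines. The pipeline is:

1. **Union.** All samples' peaks are pooled and merged into maximal
   non-redundant sites; an occupancy matrix records which samples
   contribute ≥ 1 overlapping peak per site.
2. **Commonly bound.** Sites occupied in ≥ `min_samples` samples are kept.
   Default: all samples, the strictest reading of "bound in every line".
3. **Motif.** Each site's sequence (± `flank` bp, default 0) is scanned for
   the M/E-box on both strands. The default pattern is the CACGTG hexamer
   with zero mismatches; the extended CLEAR-like element `GTCACGTGAC` is
   available via configuration. The hexamer is a declared approximation:
   MiT/TFE consensus definitions in the literature are PWM-based, but a
   position-weight matrix adds a score threshold with no principled default
   here, while the palindromic core is unambiguous and symmetric by
   construction. An `N` in the sequence never matches — ambiguity is not
   evidence.
4. **TSS distance.** Distance is measured TSS → site *midpoint* (summits
   are not available in generic BED), signed so that negative = upstream of
   the TSS in the gene's orientation. Classes: `proximal_500` (|d| ≤ 500),
   `promoter_1k` (500 < |d| < 1000), `distal_30k` (|d| > 30 000), else
   `intermediate`. The nearest gene minimises |d|; exact ties go to the
   lexicographically smallest `gene_id` so results are order-independent.
5. **Active chromatin.** A site is H3K27ac-marked when it overlaps (≥ 1 bp)
   a K27ac peak in ≥ `min_k27_samples` samples (default 1). The marking is
   evaluated at the site itself, not anywhere in the ±30 kb window: of the
   two readings of "an M/E-box within ±30 kb of the TSS marked by H3K27ac",
   the site-level one is the simpler and stricter, and it is the one
   implemented.
6. **Programs.** *Promoter program*: genes with a qualifying (commonly
   bound, motif-positive) site in `proximal_500`. *Extended program*: genes
   with a qualifying K27ac-marked site with |d| ≤ 30 kb.

A score-quantile filter on input peaks ("strong occupancy") exists but
defaults to keep-all: inputs are assumed to be already-called peaks, and
read-density-based strength classification is upstream of this package.

## Expression normalization and scoring

**Size factors** are median-of-ratios: factor_j = median over genes (with a
positive geometric mean across samples) of `count[g,j] / geomean_g`.
Factors are rescaled to unit geometric mean; this leaves all ratios between
samples untouched, makes normalization exactly idempotent, and pins the
hand-checkable two-sample example (columns (2,4,8) and (4,8,16) give
1/√2 and √2). Optional per-gene division by transcript length is provided
for length-biased comparisons.

**Geometric-mean score** of set S in sample j:
`exp(mean_{g∈S} log(x_gj + c)) − c` with pseudocount c = 1 by default, so a
single zero-count gene cannot annihilate a score. Scores are computed on
size-factor-normalized values; scoring raw counts is allowed but warns.
The **SignatureRatio** is the mesenchymal score divided by the epithelial
score; the literal (non-log) ratio is used, with the pseudocount applied
inside each geometric mean.

**Feature selection** ranks genes by median absolute deviation (unscaled;
the 1.4826 normal-consistency constant would not change the ranking), keeps
the top k (default 5000, or all genes when fewer), breaking ties by larger
row mean then lexicographic id, and median-centers each retained gene. If a
biotype map is supplied, only protein-coding genes enter the ranking.

**Group comparisons** use the two-sided Wilcoxon rank-sum test, exact when
the smaller group has ≤ 8 observations and no ties, tie-corrected normal
approximation otherwise.

## Consensus clustering

Monti-style consensus over subsampled hierarchical clusterings:

- base clustering: average linkage on 1 − Pearson correlation between
  samples — the defaults of the widely used consensus-clustering tools;
- per candidate k, `n_resamples` runs (default 1000; the orchestrated
  pipeline and the acceptance checks use 100–200, which is ample at n ≈ 60)
  each on a fraction `subsample` = 0.8 of samples drawn without
  replacement;
- consensus_ij = co-clustered / co-sampled; final labels cut an
  average-linkage tree of 1 − consensus;
- model selection: A(k) = area under the empirical CDF of off-diagonal
  consensus values; Δ(k) = A(2) for k = 2, else (A(k) − A(k−1))/A(k−1).
  The recommended k is the **largest** candidate with Δ(k) ≥ 0.1. The 0.1
  default reflects the qualitative "elbow" reading of the CDF curve: on
  cleanly separated data genuine splits gain ≳ 0.4 while spurious further
  splits gain ≲ 0.08 (the delta-area curve is printed by
  `ConsensusResult.summary()`), so 0.1 sits in the gap.

With `subsample = 1.0` the base clustering is deterministic and the
consensus matrix is exactly 0/1.

## Deconvolution and stratification

Per sample, `min ‖S·w − b‖²  s.t. w ≥ 0` is solved with the active-set NNLS
of scipy over the genes shared between bulk and signature matrix. Raw
weights are the "absolute" state scores; normalized weights divide by their
sum. This is a deliberate, documented stand-in for SVR-based deconvolution
services: the downstream logic only needs per-sample state scores, and NNLS
is exact on the generative model the synthetic cohorts follow. No batch
correction is attempted.

Stratification orders samples by the `state_a/state_b` fraction ratio
(descending, ties broken by sample id, denominator guarded by ε = 1e-9):
top n → `high`, bottom n → `low`, and the n samples centered on the median
rank — 1-based ranks ⌈(N−n)/2⌉+1 … ⌈(N−n)/2⌉+n — form `mid`. The rule is
deterministic and symmetric; N ≥ 3n is enforced so the strata are disjoint.

## Survival analysis

- **Kaplan–Meier** curves come from the product-limit estimator (lifelines).
- **Log-rank** is the standard observed-minus-expected statistic over
  pooled event times with hypergeometric variance, χ² with 1 df.
- **Cox** fits are univariate, maximizing the Breslow partial likelihood by
  Newton–Raphson on a standardized covariate (tolerance 1e-9, steps clipped
  to ±2). Breslow tie handling was chosen for simplicity; with continuous
  times ties are rare and the fit agrees with Efron-based references to
  ~1e-3. Standard errors come from the observed information; p-values are
  Wald. Monotone likelihood (perfect separation) is detected by runaway
  estimates, capped, and flagged.
- **Optimal cutpoint**: every midpoint between consecutive distinct score
  values whose split leaves ≥ `minprop` (default 0.1, the convention of the
  popular cutpoint tools) of samples on each side is scored by the
  standardized log-rank statistic |O − E|/√V; the argmax wins, ties going
  to the lower threshold. The selected split's log-rank p-value is reported
  **unadjusted** but every result object carries a `p_is_optimistic` flag:
  maximally selected statistics inflate significance, and downstream
  reporting should say so.

Times are in arbitrary positive units; months are assumed for labels only.

## Synthetic cohorts: what is and is not emulated

The generator plants a fully known truth so that downstream inference can
be checked exactly:

- **Genome/annotation** (`simulate_genome`): one synthetic chromosome
  (`chrS`; interval logic is chromosome-keyed, so one suffices), genes
  ~100 kb apart with jitter, uniform strands. CACGTG elements are planted
  100 bp downstream of each regulon gene's TSS; chance hexamers within
  ±1 kb of *any* TSS are scrubbed by resampling one base, which makes
  zero-noise recovery exact rather than approximate.
- **Peaks** (`simulate_peaks`): per sample, a TFE3 peak (±150 bp) covering
  each planted element — dropped with probability `noise_fn` per sample —
  plus an H3K27ac peak (±500 bp) over the promoter; edges jittered ±20 bp
  so union merging is exercised. False positives appear at rate `noise_fp`
  per gene, placed > 40 kb from every TSS so they inflate the site union
  but can never enter a gene program.
- **Counts** (`simulate_counts`): negative binomial with variance
  μ + αμ² (α default 0.1, the usual bulk RNA-seq scale; α→0 recovers
  Poisson). Expected expression is a mixture of three reference state
  profiles (epithelial / mesenchymal tumour cells and a myCAF-like
  fibroblast state) weighted by per-sample Dirichlet fractions whose
  concentration depends on the planted cluster (epithelial-dominant,
  mesenchymal-dominant, stroma-rich), multiplied by a per-sample depth
  factor (default 0.7–1.4) and per-cluster marker boosts. Signature sizes
  follow the conventions of the field's tumour signatures: 22 epithelial +
  22 mesenchymal genes, 15 fibroblast markers, 30 OxPhos genes drawn from
  the planted regulon (fusion-driven, hence high in both tumour states),
  25 markers per cluster. The deconvolution reference contains only the
  state-discriminating markers, as a signature matrix would.
- **Survival** (`simulate_survival`): exponential event times with hazard
  h₀·exp(β·score) (h₀ default 0.02 per month, β default 1 per standardized
  score unit); censoring is independent exponential with the per-subject
  rate chosen so the censoring probability is exactly `censor_rate`
  (default 0.3, a typical cohort fraction).

Not emulated: read-level data (FASTQ), fragment sizes, peak-calling
artefacts, batch effects, library-preparation biases, copy-number-driven
expression, non-proportional hazards. Passing the planted-truth tests
therefore demonstrates that the *inference chain is correct on its own
generative assumptions*, not that those assumptions capture every property
of real tumour cohorts.

## Reproducibility

Every stochastic routine takes a seed (or `numpy` Generator); the
orchestrated run derives stage seeds from the single config seed, writes a
copy of its config plus a manifest of SHA-256 hashes, and is bit-identical
across reruns. No artifact embeds timestamps.

## Known limitations

- The hexamer motif model has no affinity gradation; weak/variant E-boxes
  are invisible.
- Nearest-gene assignment by TSS distance ignores topological domains and
  enhancer–promoter maps.
- NNLS deconvolution has no collinearity regularization; highly correlated
  reference profiles will trade weight arbitrarily.
- The consensus Δ-area threshold is a heuristic; flat cluster structure
  (k = 1) is outside the candidate range by construction.
- The optimal-cutpoint p-value is not corrected for threshold selection —
  it is flagged, not fixed; use the continuous-covariate Cox fit when an
  honest p-value is needed.
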