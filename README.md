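# trccomics

Multi-omics analysis toolkit for MiT/TFE-fusion renal tumours (translocation
renal cell carcinoma, tRCC): it defines a transcription factor's **core
regulon** from multi-cell-line binding data, scores tumour transcriptomes
with gene-signature statistics, stratifies cohorts by consensus clustering
and reference deconvolution, and tests survival association with
optimal-cutpoint statistics. A synthetic-cohort generator with planted
ground truth makes every stage testable without any sequencing download.

## Who this is for

Computational biologists analysing ChIP-seq / Cut&Tag peak sets together
with bulk tumour RNA-seq, who want the individual building blocks (interval
unions, motif scanning, TSS annotation, signature scoring, NNLS
deconvolution, maximally selected log-rank cutpoints) as a tested, scripted
pipeline rather than a collection of one-off notebook cells.

## The methods at the core

**Core regulon.** Given per-sample peak sets, the non-redundant site union
is formed (intervals sharing ≥ 1 bp merge) with a site × sample occupancy
matrix. A site enters the core program when it is (1) occupied in at least
`min_samples` samples (default: all), (2) contains an M/E-box — the CACGTG
palindrome bound by MiT/TFE bHLH-LZ factors — on either strand, and (3)
lies near a TSS. Distances are signed (negative = upstream of the TSS,
strand-aware) and measured TSS → site midpoint, with classes
`proximal_500` (|d| ≤ 500 bp), `promoter_1k` (500 < |d| < 1000),
`intermediate`, and `distal_30k` (|d| > 30 kb). The *promoter program* is
the genes with a qualifying proximal site; the *extended program* requires
in addition H3K27ac co-marking of the site (active chromatin) and
|d| ≤ 30 kb.

**Signature scores.** Counts are normalized by median-of-ratios size
factors (factor *j* = median over genes of count/geometric-mean, rescaled
to unit geometric mean across samples). The score of a gene set is the
geometric mean of its member genes, `exp(mean log(x + 1)) − 1`; the
mesenchymal/epithelial **SignatureRatio** is the mesenchymal score divided
by the epithelial score. Samples are clustered by Monti-style consensus
clustering (resampled average-linkage hierarchical clustering on
1 − Pearson distance over the top-MAD, median-centered genes), with the
cluster number picked from the relative gain in consensus-CDF area.

**Deconvolution and survival.** Bulk samples are decomposed over reference
cell-state profiles by nonnegative least squares (min ‖S·w − b‖², w ≥ 0);
the epi/mes ratio of the fractions orders samples into top-n / median-n /
bottom-n strata. Survival association of a continuous score is tested by
dichotomizing at the threshold maximising the standardized log-rank
statistic (maximally selected rank statistic), then reporting Kaplan–Meier
curves, the log-rank test and a univariate Cox hazard ratio — with an
explicit flag that the selection-induced p-value is optimistic.

## Worked example

```python
import numpy as np, pandas as pd
from trccomics import *

# synthetic binding study: 200 genes, 40 with planted M/E-box elements
ann, seqs, truth = simulate_genome(n_genes=200, n_regulon=40, seed=0)
tfe3, k27 = simulate_peaks(ann, truth, n_samples=4, noise_fp=0.02, seed=1)
regulon = call_core_regulon(merge_union(tfe3), ann, seqs, k27)
print(regulon.summary())

# tumour cohort scored with the planted OxPhos signature, then stratified
counts, reference, gene_sets = simulate_counts(ann, truth, n_samples=60, seed=2)
norm = normalize(counts)
oxphos = geometric_mean_score(norm, gene_sets["oxphos"])
z = (np.log(oxphos + 1) - np.log(oxphos + 1).mean()) / np.log(oxphos + 1).std()
surv = simulate_survival(pd.Series(z, index=oxphos.index), beta=1.0,
                         censor_rate=0.3, seed=3)
cut = optimal_cutpoint(surv.join_scores(oxphos, "oxphos"), "oxphos")
print(cut.summary())
```

prints

```
Core regulon
  commonly bound M/E-box sites : 40
  promoter program genes       : 40
  extended program genes       : 40
  criteria: min_samples=4, motif=CACGTG, k27>=1 sample(s), windows 500/1000/30000 bp

Optimal cutpoint for 'oxphos' (minprop=0.1)
  threshold     : 300.227
  max |z|       : 4.0290
  group sizes   : high=34, low=26
  log-rank chi2 : 16.2332 (p=5.6e-05, optimistic: threshold maximises separation)
  Cox HR (high vs low): 3.709 [95% CI 1.891, 7.273], Wald p=0.000136
```

All 40 planted regulon genes are recovered (false-positive peaks land far
from every TSS and cannot enter a program), and the cohort whose hazard
was simulated to increase with the OxPhos score splits into a high-score
group with a hazard ratio of ≈ 3.7 — the planted effect seen through an
optimistically selected threshold.

The same analyses run from the shell:

```sh
trccomics run-all --out runs/demo --seed 7
trccomics regulon --peaks a.bed --peaks b.bed --k27 k.bed \
    --fasta genome.fa --tss tss.tsv --out runs/regulon
trccomics score --matrix counts.tsv --gmt signatures.gmt --normalize --out scores.tsv
```

Each `run-all` directory is self-describing: a copy of the YAML config plus
a manifest of SHA-256 hashes of every artifact; two runs with the same seed
are hash-identical.

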