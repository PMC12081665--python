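"""Expression normalization and gene-signature scoring.

Bulk RNA-seq counts are normalized with the median-of-ratios size factors
(the DESeq convention), optionally divided by transcript length, and scored
against gene sets with a geometric mean.  The mesenchymal/epithelial
*SignatureRatio* of a sample is the geometric-mean score of the mesenchymal
signature divided by that of the epithelial signature; a higher ratio marks
a more mesenchymal tumour.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_STATES = ("raw_counts", "size_factor_normalized", "length_adjusted")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample nonnegative expression values plus normalization state."""

    values: pd.DataFrame = field(repr=False)
    state: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        if self.values.index.duplicated().any() or self.values.columns.duplicated().any():
            raise ValueError("gene and sample ids must be unique")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read_tsv(cls, path: str | Path, state: str = "raw_counts") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(df, state=state)


@dataclass
class GeneSet:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            self.genes = [g for g in self.genes if not (g in seen or seen.add(g))]


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read gene sets from GMT (name, description, genes...; tab-separated)."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            sets[parts[0]] = GeneSet(parts[0], [g for g in parts[2:] if g])
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


def _frame(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ExpressionMatrix) else matrix


def size_factors(counts: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j the factor is the median over genes (restricted to
    genes with a positive geometric mean across samples) of
    ``count[g, j] / geomean_g``.  Dividing the matrix by these factors
    equalizes sequencing depth.
    """
    df = _frame(counts)
    if df.shape[1] < 2:
        raise ValueError("need >=2 samples to estimate size factors")
    with np.errstate(divide="ignore"):
        logs = np.log(df.to_numpy(dtype=float))
    finite = np.isfinite(logs).all(axis=1)
    if not finite.any():
        raise ValueError(
            "no gene has positive counts in every sample; add a pseudocount "
            "or filter samples"
        )
    log_geomean = logs[finite].mean(axis=1)
    log_factors = np.median(logs[finite] - log_geomean[:, None], axis=0)
    # rescale to unit geometric mean so normalization is exactly idempotent
    log_factors -= log_factors.mean()
    return pd.Series(np.exp(log_factors), index=df.columns, name="size_factor")


def normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample by its median-of-ratios size factor."""
    factors = size_factors(counts)
    return ExpressionMatrix(counts.values / factors, state="size_factor_normalized")


def length_adjust(
    matrix: ExpressionMatrix, transcript_lengths: Mapping[str, float] | pd.Series
) -> ExpressionMatrix:
    """Divide each gene's row by its (median) transcript length."""
    lengths = pd.Series(transcript_lengths, dtype=float)
    df = matrix.values
    missing = sorted(set(df.index) - set(lengths.index))
    if missing:
        raise ValueError(f"missing transcript lengths for genes: {missing[:10]}")
    if (lengths.loc[df.index] <= 0).any():
        raise ValueError("transcript lengths must be positive")
    return ExpressionMatrix(df.div(lengths.loc[df.index], axis=0), state="length_adjusted")


def geometric_mean_score(
    matrix: ExpressionMatrix | pd.DataFrame,
    gene_set: GeneSet | Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-sample geometric-mean score of a gene set.

    ``score_j = exp(mean_g log(x_gj + pseudocount)) - pseudocount`` over the
    set genes present in the matrix.  Genes absent from the matrix are
    dropped with a warning; an empty intersection is an error.  The default
    pseudocount of 1 keeps a single zero gene from annihilating the score.
    """
    df = _frame(matrix)
    if isinstance(matrix, ExpressionMatrix) and matrix.state == "raw_counts":
        warnings.warn("scoring raw counts; normalize first for cross-sample comparisons")
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else list(gene_set)
    name = gene_set.name if isinstance(gene_set, GeneSet) else "score"
    present = [g for g in genes if g in df.index]
    absent = [g for g in genes if g not in df.index]
    if absent:
        logger.warning("%d/%d genes of %s absent from matrix", len(absent), len(genes), name)
    if not present:
        raise ValueError(f"no gene of set {name!r} present in the matrix")
    vals = df.loc[present].to_numpy(dtype=float) + pseudocount
    if (vals <= 0).any():
        raise ValueError("non-positive values after pseudocount; increase pseudocount")
    score = np.exp(np.log(vals).mean(axis=0)) - pseudocount
    return pd.Series(score, index=df.columns, name=name)


def signature_ratio(
    matrix: ExpressionMatrix | pd.DataFrame,
    mes_set: GeneSet | Sequence[str],
    epi_set: GeneSet | Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Mesenchymal/epithelial SignatureRatio per sample."""
    mes = geometric_mean_score(matrix, mes_set, pseudocount)
    epi = geometric_mean_score(matrix, epi_set, pseudocount)
    if (epi == 0).any():
        raise ValueError("epithelial geometric-mean score is zero for some sample")
    return pd.Series(mes / epi, name="SignatureRatio")


def select_features(
    matrix: ExpressionMatrix | pd.DataFrame,
    k: int = 5000,
    biotypes: Mapping[str, str] | None = None,
    coding_biotype: str = "protein_coding",
) -> pd.DataFrame:
    """Top-``k`` most variable genes by MAD, median-centered.

    Genes are ranked by median absolute deviation across samples (ties:
    larger row mean, then lexicographic id), the top ``k`` retained and each
    retained gene's median subtracted.  If a biotype map is given only
    coding genes enter the ranking.  Returns a centered DataFrame (values
    may be negative, so no longer an :class:`ExpressionMatrix`).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = _frame(matrix)
    if biotypes is not None:
        keep = [g for g in df.index if biotypes.get(g) == coding_biotype]
        df = df.loc[keep]
    if k > len(df):
        raise ValueError(f"k={k} exceeds {len(df)} candidate genes")
    x = df.to_numpy(dtype=float)
    mad = np.median(np.abs(x - np.median(x, axis=1, keepdims=True)), axis=1)
    order = sorted(
        range(len(df)), key=lambda i: (-mad[i], -x[i].mean(), df.index[i])
    )
    sel = df.iloc[order[:k]]
    return sel.sub(sel.median(axis=1), axis=0)


def compare_score_groups(
    scores: pd.Series | Sequence[float],
    group_labels: Sequence,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of scores between two groups.

    Uses the exact null distribution when the smaller group has <= 8
    observations and no ties are present, otherwise the tie-corrected
    normal approximation.  Returns ``(U statistic, p value)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(group_labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two groups, got {len(uniq)}")
    a = scores[labels == uniq[0]]
    b = scores[labels == uniq[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(scores)) < len(scores)
    method = "exact" if (min(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
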