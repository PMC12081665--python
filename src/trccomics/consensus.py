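"""Consensus clustering of tumour samples by subsampled hierarchical clustering.

The resampling scheme follows the Monti consensus-clustering recipe: for
each candidate number of clusters *k*, samples are repeatedly subsampled,
clustered by average-linkage hierarchical clustering on a
1 - Pearson-correlation distance, and the consensus index of a sample pair
is the fraction of co-sampled runs in which the pair co-clustered.  The
empirical CDF of the consensus indices is summarised by its area A(k); the
relative gain Delta(k) = (A(k) - A(k-1)) / A(k-1) (A(2) itself for k = 2)
drives the choice of k: the recommended k is the largest candidate whose
relative gain still exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix, _frame


def _pearson_distance(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between columns of ``x``."""
    r = np.corrcoef(x, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)  # constant column -> maximal distance
    r = np.clip(r, -1.0, 1.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    # guard tiny negative round-off
    return squareform(np.maximum(d, 0.0), checks=False)


def _hclust_labels(x: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage hierarchical clustering of columns, cut to k groups."""
    if x.shape[1] <= k:
        return np.arange(1, x.shape[1] + 1)
    z = linkage(_pearson_distance(x), method="average")
    return fcluster(z, t=k, criterion="maxclust")


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus indices."""
    n = consensus.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = np.sort(consensus[iu])
    if len(vals) == 0:
        return 0.0
    # A = sum over the sorted support of (x_i - x_{i-1}) * CDF(x_{i-1}),
    # evaluated on a fixed [0, 1] grid of the observed values
    grid = np.concatenate(([0.0], vals, [1.0]))
    cdf = np.searchsorted(vals, grid, side="right") / len(vals)
    return float(np.sum(np.diff(grid) * cdf[:-1]))


@dataclass
class ConsensusResult:
    """Per-k consensus matrices plus the CDF-area model-selection curve."""

    k_range: list[int]
    sample_ids: list[str]
    consensus: dict[int, np.ndarray] = field(repr=False)
    labels: dict[int, np.ndarray] = field(repr=False)
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    recommended_k: int

    @property
    def final_labels(self) -> np.ndarray:
        return self.labels[self.recommended_k]

    def labels_series(self, k: int | None = None) -> pd.Series:
        k = self.recommended_k if k is None else k
        return pd.Series(self.labels[k], index=self.sample_ids, name=f"cluster_k{k}")

    def consensus_frame(self, k: int | None = None) -> pd.DataFrame:
        k = self.recommended_k if k is None else k
        return pd.DataFrame(self.consensus[k], index=self.sample_ids, columns=self.sample_ids)

    def summary(self) -> str:
        lines = ["Consensus clustering", "   k   CDF area   rel. gain"]
        for k in self.k_range:
            mark = " <- recommended" if k == self.recommended_k else ""
            lines.append(f"  {k:2d}   {self.cdf_area[k]:8.4f}   {self.delta_area[k]:9.4f}{mark}")
        return "\n".join(lines)


def consensus_cluster(
    matrix: ExpressionMatrix | pd.DataFrame,
    k_range: range | list[int] = range(2, 7),
    n_resamples: int = 1000,
    subsample: float = 0.8,
    seed: int | np.random.Generator = 0,
    delta_threshold: float = 0.1,
) -> ConsensusResult:
    """Consensus-cluster the samples (columns) of a feature matrix.

    Parameters
    ----------
    matrix : genes-by-samples values (typically MAD-selected, median-centered)
    k_range : candidate cluster numbers
    n_resamples : subsampled clustering runs per k
    subsample : fraction of samples drawn (without replacement) per run
    seed : int seed or a Generator
    delta_threshold : minimum relative CDF-area gain for a k to be retained;
        the recommended k is the largest retained candidate.
    """
    df = _frame(matrix)
    n = df.shape[1]
    ks = sorted(k_range)
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    if not (0 < subsample <= 1):
        raise ValueError("subsample must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = df.to_numpy(dtype=float)
    m = max(2, int(round(subsample * n)))

    consensus: dict[int, np.ndarray] = {}
    labels: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    for k in ks:
        co = np.zeros((n, n))
        tog = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = np.sort(rng.choice(n, size=m, replace=False)) if m < n else np.arange(n)
            lab = _hclust_labels(x[:, idx], k)
            tog[np.ix_(idx, idx)] += 1
            same = lab[:, None] == lab[None, :]
            co[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            cons = np.where(tog > 0, co / np.maximum(tog, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2
        consensus[k] = cons
        z = linkage(squareform(np.maximum(1.0 - cons, 0.0), checks=False), method="average")
        labels[k] = fcluster(z, t=k, criterion="maxclust")
        areas[k] = _cdf_area(cons)

    deltas: dict[int, float] = {}
    prev = None
    for k in ks:
        deltas[k] = areas[k] if prev is None else (areas[k] - areas[prev]) / max(areas[prev], 1e-12)
        prev = k
    retained = [k for k in ks if deltas[k] >= delta_threshold]
    recommended = max(retained) if retained else ks[0]
    return ConsensusResult(
        k_range=ks,
        sample_ids=df.columns.tolist(),
        consensus=consensus,
        labels=labels,
        cdf_area=areas,
        delta_area=deltas,
        recommended_k=recommended,
    )
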