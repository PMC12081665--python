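"""Reference-profile deconvolution of bulk transcriptomes.

Bulk samples are modelled as nonnegative mixtures of reference cell-state
profiles (e.g. epithelial / mesenchymal tumour cells, myCAF / apCAF
fibroblasts): per sample, solve ``min ||S w - b||^2, w >= 0`` by
nonnegative least squares.  Raw weights play the role of "absolute" state
scores; normalized weights sum to one.  The module also implements the
ratio-based stratification rule that picks the top-n, bottom-n and
median-n samples along a state-ratio ordering (e.g. epi/mes), and Spearman
correlation between fractions and other per-sample scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .expression import ExpressionMatrix, _frame


@dataclass
class SignatureMatrix:
    """Mean expression of marker genes per reference cell state."""

    profiles: pd.DataFrame = field(repr=False)  # genes x states

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise ValueError("need >=2 reference states")
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("reference profiles must be nonnegative")
        if self.profiles.index.duplicated().any():
            raise ValueError("duplicate gene ids in signature matrix")

    @property
    def state_ids(self) -> list[str]:
        return self.profiles.columns.tolist()

    def write_tsv(self, path: str | Path) -> None:
        self.profiles.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SignatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"))


@dataclass
class FractionEstimate:
    """Per-sample state weights from NNLS plus fit residuals."""

    raw: pd.DataFrame = field(repr=False)  # samples x states ("absolute" scores)
    residual: pd.Series = field(repr=False)
    normalized: pd.DataFrame | None = field(default=None, repr=False)
    zero_samples: list[str] = field(default_factory=list)

    @property
    def state_ids(self) -> list[str]:
        return self.raw.columns.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.raw.index.tolist()

    def frame(self) -> pd.DataFrame:
        """Normalized fractions if available, else raw weights."""
        return self.normalized if self.normalized is not None else self.raw

    def summary(self) -> str:
        df = self.frame()
        lines = [
            f"NNLS deconvolution: {len(df)} samples x {df.shape[1]} states",
            f"  mean residual norm : {self.residual.mean():.4g}",
            "  mean fractions     : "
            + ", ".join(f"{s}={df[s].mean():.3f}" for s in df.columns),
        ]
        if self.zero_samples:
            lines.append(f"  all-zero samples   : {self.zero_samples}")
        return "\n".join(lines)


def nnls_deconvolve(
    bulk: ExpressionMatrix | pd.DataFrame,
    signatures: SignatureMatrix | pd.DataFrame,
    normalize: bool = True,
) -> FractionEstimate:
    """Estimate per-sample state weights by nonnegative least squares.

    Only genes shared between bulk matrix and signature matrix are used;
    others are dropped with a warning.  All-zero bulk columns yield zero
    weights and are flagged.
    """
    bulk_df = _frame(bulk)
    sig_df = signatures.profiles if isinstance(signatures, SignatureMatrix) else signatures
    shared = bulk_df.index.intersection(sig_df.index)
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes shared between bulk and signature matrices")
    dropped = len(sig_df) - len(shared)
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "%d signature genes absent from bulk matrix; using %d shared genes",
            dropped,
            len(shared),
        )
    S = sig_df.loc[shared].to_numpy(dtype=float)
    B = bulk_df.loc[shared].to_numpy(dtype=float)
    weights = np.zeros((bulk_df.shape[1], sig_df.shape[1]))
    resid = np.zeros(bulk_df.shape[1])
    zero_samples: list[str] = []
    for j in range(bulk_df.shape[1]):
        b = B[:, j]
        if not b.any():
            zero_samples.append(bulk_df.columns[j])
            continue
        weights[j], resid[j] = nnls(S, b)
    raw = pd.DataFrame(weights, index=bulk_df.columns, columns=sig_df.columns)
    residual = pd.Series(resid, index=bulk_df.columns, name="residual")
    normalized_df = None
    if normalize:
        sums = raw.sum(axis=1)
        normalized_df = raw.div(sums.where(sums > 0, 1.0), axis=0)
    return FractionEstimate(
        raw=raw, residual=residual, normalized=normalized_df, zero_samples=zero_samples
    )


def stratify_by_ratio(
    fractions: FractionEstimate | pd.DataFrame,
    state_a: str,
    state_b: str,
    n_per_stratum: int = 20,
    eps: float = 1e-9,
) -> dict[str, list[str]]:
    """Top/bottom/median strata along the ``state_a / state_b`` ratio.

    Samples are ordered by ratio descending (ties broken by sample id); the
    top ``n`` form group ``high`` (state_a-dominant), the bottom ``n`` group
    ``low``, and the ``n`` samples centered on the median rank group ``mid``
    (1-based ranks ``ceil((N - n)/2) + 1 .. + n``).  Groups are disjoint;
    ``N >= 3 n`` is required.
    """
    df = fractions.frame() if isinstance(fractions, FractionEstimate) else fractions
    for s in (state_a, state_b):
        if s not in df.columns:
            raise ValueError(f"state {s!r} not in fractions")
    n, N = n_per_stratum, len(df)
    if N < 3 * n:
        raise ValueError(f"need >= {3 * n} samples for disjoint strata of {n}, have {N}")
    ratio = df[state_a] / (df[state_b] + eps)
    order = ratio.to_frame("ratio").assign(sample_id=ratio.index)
    order = order.sort_values(["ratio", "sample_id"], ascending=[False, True], kind="mergesort")
    ranked = order.index.tolist()
    start_mid = int(np.ceil((N - n) / 2))  # 0-based start of the median window
    groups = {
        "high": ranked[:n],
        "mid": ranked[start_mid : start_mid + n],
        "low": ranked[N - n :],
    }
    if len({g for v in groups.values() for g in v}) != 3 * n:
        raise ValueError("strata overlap; reduce n_per_stratum")
    return groups


def correlate_fractions(
    fractions: FractionEstimate | pd.DataFrame,
    scores: pd.DataFrame | pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation of state fractions against per-sample scores.

    Returns ``(rho, p)`` DataFrames (states x score columns) with
    tie-corrected p-values; constant vectors give NaN entries.
    """
    frac = fractions.frame() if isinstance(fractions, FractionEstimate) else fractions
    if isinstance(scores, pd.Series):
        scores = scores.to_frame()
    common = frac.index.intersection(scores.index)
    if len(common) < 3:
        raise ValueError("need >=3 shared samples")
    frac, scores = frac.loc[common], scores.loc[common]
    rho = pd.DataFrame(index=frac.columns, columns=scores.columns, dtype=float)
    pval = rho.copy()
    for a in frac.columns:
        for b in scores.columns:
            x, y = frac[a].to_numpy(), scores[b].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue  # rho undefined -> left as NaN
            r = stats.spearmanr(x, y)
            rho.loc[a, b], pval.loc[a, b] = r.statistic, r.pvalue
    return rho, pval
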