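"""Genomic interval handling: BED I/O, non-redundant union, occupancy matrix.

Intervals are BED-style 0-based half-open ``[start, end)`` and are carried
around as pandas DataFrames with columns ``chrom, start, end`` plus optional
``name`` and ``score``.  The central object is :class:`PeakCompendium` — the
non-redundant union of several per-sample peak sets together with a boolean
site-by-sample occupancy ("bound") matrix, the structure behind the notion of
sites "commonly bound" across cell lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BED_COLUMNS = ("chrom", "start", "end", "name", "score")


class BedParseError(ValueError):
    """A malformed BED line; message carries the 1-based line number."""


def _validate_intervals(df: pd.DataFrame, source: str = "intervals") -> pd.DataFrame:
    if (df["start"] < 0).any():
        bad = int(df.index[df["start"] < 0][0])
        raise BedParseError(f"{source}: negative start at record {bad}")
    if (df["start"] >= df["end"]).any():
        bad = int(df.index[df["start"] >= df["end"]][0])
        raise BedParseError(f"{source}: start >= end at record {bad}")
    return df


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3-6 column BED file into a sorted interval frame.

    Columns beyond ``chrom, start, end`` are interpreted as ``name`` and
    ``score``.  Output is sorted by ``(chrom, start, end)``.  Malformed lines
    raise :class:`BedParseError` naming the offending line number.
    """
    path = Path(path)
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise BedParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = parts[3] if len(parts) > 3 else "."
            try:
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else np.nan
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            rows.append((parts[0], start, end, name, score))
    df = pd.DataFrame(rows, columns=list(BED_COLUMNS))
    if df.empty:
        df = pd.DataFrame(columns=list(BED_COLUMNS)).astype(
            {"start": int, "end": int, "score": float}
        )
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write an interval frame as BED (tab-separated, no header)."""
    cols = ["chrom", "start", "end"]
    out = df.copy()
    if "name" in out.columns:
        cols.append("name")
        if "score" in out.columns and out["score"].notna().any():
            out["score"] = out["score"].fillna(0)
            cols.append("score")
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def covered_bases(df: pd.DataFrame) -> int:
    """Total number of bases covered by the union of the intervals."""
    if len(df) == 0:
        return 0
    merged = merge_intervals(df)
    return int((merged["end"] - merged["start"]).sum())


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping intervals into maximal disjoint intervals.

    A single shared base pair suffices to merge; book-ended intervals
    (``end == start``) remain separate, matching half-open semantics.
    """
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"]).astype({"start": int, "end": int})
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s < cur_e:  # strict: 1-bp overlap merges, book-ended does not
                cur_e = max(cur_e, int(e))
            else:
                out_chrom.append(chrom)
                out_start.append(cur_s)
                out_end.append(cur_e)
                cur_s, cur_e = int(s), int(e)
        out_chrom.append(chrom)
        out_start.append(cur_s)
        out_end.append(cur_e)
    return pd.DataFrame({"chrom": out_chrom, "start": out_start, "end": out_end})


def _overlaps_any(sites: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """Boolean vector: does each site overlap >=1 peak (1-bp overlap)."""
    result = np.zeros(len(sites), dtype=bool)
    if len(peaks) == 0 or len(sites) == 0:
        return result
    for chrom, peak_sub in peaks.groupby("chrom"):
        mask = (sites["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        order = np.argsort(peak_sub["start"].to_numpy(), kind="stable")
        p_start = peak_sub["start"].to_numpy()[order]
        p_end = peak_sub["end"].to_numpy()[order]
        # prefix max of peak ends: peak i overlaps site iff start_i < site.end
        # and end_i > site.start for some i with start_i < site.end
        prefix_max_end = np.maximum.accumulate(p_end)
        s_start = sites.loc[mask, "start"].to_numpy()
        s_end = sites.loc[mask, "end"].to_numpy()
        k = np.searchsorted(p_start, s_end, side="left")  # peaks starting before site end
        hit = np.zeros(mask.sum(), dtype=bool)
        nonzero = k > 0
        hit[nonzero] = prefix_max_end[k[nonzero] - 1] > s_start[nonzero]
        result[mask] = hit
    return result


@dataclass
class PeakCompendium:
    """Non-redundant union of per-sample peak sets with occupancy flags.

    Attributes
    ----------
    sample_ids : list of str
    union_sites : DataFrame with chrom/start/end, one row per merged site
    bound : boolean array, shape (n_sites, n_samples); ``bound[i, j]`` is True
        iff union site *i* overlaps at least one peak of sample *j*.
    """

    sample_ids: list[str]
    union_sites: pd.DataFrame
    bound: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.bound.shape != (len(self.union_sites), len(self.sample_ids)):
            raise ValueError("bound matrix shape mismatch")
        if len(self.union_sites) and not self.bound.any(axis=1).all():
            raise ValueError("every union site must be bound in >=1 sample")

    @property
    def n_sites(self) -> int:
        return len(self.union_sites)

    def bound_counts(self) -> np.ndarray:
        """Number of samples each union site is occupied in."""
        return self.bound.sum(axis=1)


def merge_union(peak_sets: Mapping[str, pd.DataFrame]) -> PeakCompendium:
    """Build the non-redundant site union across per-sample peak sets.

    Union sites are maximal merged intervals over all samples' peaks pooled
    together; the occupancy matrix marks which samples contribute at least
    one overlapping peak to each site.
    """
    if not peak_sets:
        raise ValueError("at least one sample required")
    sample_ids = list(peak_sets)
    for sid, df in peak_sets.items():
        _validate_intervals(df, source=f"sample {sid}")
    pooled = pd.concat(
        [df[["chrom", "start", "end"]] for df in peak_sets.values()], ignore_index=True
    )
    union = merge_intervals(pooled)
    bound = np.column_stack(
        [_overlaps_any(union, peak_sets[sid]) for sid in sample_ids]
    ) if len(union) else np.zeros((0, len(sample_ids)), dtype=bool)
    return PeakCompendium(sample_ids=sample_ids, union_sites=union, bound=bound)


def filter_commonly_bound(
    compendium: PeakCompendium, min_samples: int | None = None
) -> pd.DataFrame:
    """Retain union sites occupied in at least ``min_samples`` samples.

    ``min_samples=None`` (default) requires occupancy in *all* samples — the
    "commonly bound in all cell lines" criterion.  Returns the retained
    subset of ``union_sites`` with a ``bound_count`` column.
    """
    n = len(compendium.sample_ids)
    if min_samples is None:
        min_samples = n
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if min_samples > n:
        raise ValueError(f"min_samples={min_samples} exceeds sample count {n}")
    counts = compendium.bound_counts()
    keep = counts >= min_samples
    out = compendium.union_sites.loc[keep].copy()
    out["bound_count"] = counts[keep]
    return out.reset_index(drop=True)
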